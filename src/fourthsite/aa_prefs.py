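"""Second-codon amino-acid analyses.

Average-of-difference (AOD) scores measure, per amino-acid block, the
excess of its frequency at the second codon over its frequency across
all codon positions; a positive score marks second-position preference.
The six-fold degenerates are split into their two codon blocks
(S_A/S_T, R_A/R_C, L_C/L_T) so nucleotide-level and amino-acid-level
selection can be told apart: under purely protein-level selection the
A-starting block of a six-codon family is expected to carry one third
of the family's use (2 of 6 codons), i.e. an S_A:S_T ratio of 1:2.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .codes import a_starting_fraction, codon_blocks, iter_codons
from .records import GenomeRecord

#: GC-group bounds splitting the study cohort into three equal groups
GC_GROUP_BOUNDS = (0.4419, 0.6091)


def gc_group(gc: float, bounds=GC_GROUP_BOUNDS) -> str:
    low, high = bounds
    if gc <= low:
        return "low"
    if gc <= high:
        return "medium"
    return "high"


def expected_block_share(block_label: str, table_id: int = 11) -> float:
    """Share of a six-codon family expected for one of its blocks under
    codon-indifferent (amino-acid-level) selection: block size over
    family size, e.g. S_A -> 2/6."""
    from .codes import get_table

    blocks = codon_blocks(get_table(table_id))
    fam = block_label.split("_")[0]
    pair = [lbl for lbl in blocks if lbl.split("_")[0] == fam]
    total = sum(len(blocks[lbl]) for lbl in pair)
    return len(blocks[block_label]) / total


def block_frequencies(
    genome: GenomeRecord, exclude_first_codon: bool = False
) -> pd.DataFrame:
    """Per-block frequencies at the second codon (f) and across all
    codons (F).  F includes the start codon by default — Met's F is then
    inflated exactly as in a transcriptome-wide codon count; stops are
    never counted."""
    blocks = codon_blocks(genome.table)
    codon_to_block = {c: lbl for lbl, cs in blocks.items() for c in cs}

    second_counts: dict = {lbl: 0 for lbl in blocks}
    n_second = 0
    for c in genome.cds:
        codon = c.seq[3:6]
        lbl = codon_to_block.get(codon)
        if lbl is not None:
            second_counts[lbl] += 1
            n_second += 1

    all_counts = {lbl: 0 for lbl in blocks}
    n_all = 0
    for codon, k in genome.codon_counts().items():
        lbl = codon_to_block.get(codon)
        if lbl is None:
            continue
        all_counts[lbl] += k
        n_all += k
    if exclude_first_codon:
        for c in genome.cds:
            lbl = codon_to_block.get(c.seq[:3])
            if lbl is not None:
                all_counts[lbl] -= 1
                n_all -= 1

    rows = []
    for lbl in sorted(blocks):
        f = second_counts[lbl] / n_second if n_second else math.nan
        F = all_counts[lbl] / n_all if n_all else math.nan
        rows.append(
            dict(
                block=lbl, f_second=f, F_all=F, diff=f - F,
                n_second=second_counts[lbl], n_all=all_counts[lbl],
            )
        )
    return pd.DataFrame(rows).set_index("block")


def aod_scores(
    genomes,
    bounds=GC_GROUP_BOUNDS,
    exclude_first_codon: bool = False,
) -> pd.DataFrame:
    """AOD per block and GC group: the mean over genomes in the group of
    the per-genome (f - F) difference."""
    per_genome = []
    for g in genomes:
        if g.n_cds == 0:
            warnings.warn(f"{g.genome_id}: no filtered CDSs, excluded from AOD")
            continue
        bf = block_frequencies(g, exclude_first_codon)
        bf = bf.assign(genome_id=g.genome_id, gc_group=gc_group(g.gc, bounds))
        per_genome.append(bf.reset_index())
    if not per_genome:
        raise ValueError("no usable genomes")
    df = pd.concat(per_genome, ignore_index=True)
    out = (
        df.groupby(["block", "gc_group"])["diff"]
        .agg(aod="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan,
             n_genomes="count")
        .reset_index()
    )
    return out


def block_ratios(genome: GenomeRecord) -> pd.DataFrame:
    """Second-position enrichment of the split six-fold blocks.

    ratio = (block frequency among second codons) / (block frequency
    over all codons); expected second-position count = genome block
    frequency x n_cds, tested with the 1-df dichotomy chi-square.
    Blocks absent from the genome yield NaN sentinels.
    """
    bf = block_frequencies(genome)
    n = genome.n_cds
    rows = []
    for lbl in ("S_A", "S_T", "R_A", "R_C", "L_C", "L_T"):
        f, F = bf.loc[lbl, "f_second"], bf.loc[lbl, "F_all"]
        obs = bf.loc[lbl, "n_second"]
        if F == 0 or math.isnan(F):
            rows.append(
                dict(block=lbl, ratio=math.nan, observed=obs, expected=math.nan,
                     chi2=math.nan, p=math.nan)
            )
            continue
        exp = F * n
        ratio = f / F
        if 0 < exp < n:
            chi2 = (obs - exp) ** 2 / exp + ((n - obs) - (n - exp)) ** 2 / (n - exp)
            p = float(stats.chi2.sf(chi2, df=1))
        else:
            chi2 = p = math.nan
        rows.append(
            dict(block=lbl, ratio=ratio, observed=int(obs), expected=exp,
                 chi2=chi2, p=p)
        )
    return pd.DataFrame(rows).set_index("block")


# ---------------------------------------------------------------------------
# dipeptide expectations
# ---------------------------------------------------------------------------

def translate_cds(seq: str, table) -> str:
    """Amino-acid string, terminal stop dropped (internal stops would
    have been filtered out upstream)."""
    aas = []
    for codon in iter_codons(seq):
        if table.is_stop(codon):
            break
        aas.append(table.forward[codon])
    return "".join(aas)


def dipeptide_expectation(genome: GenomeRecord, pair: tuple) -> dict:
    """Observed vs independence-expected count of an ordered amino-acid
    pair over all adjacent positions of the translated proteome."""
    aa1, aa2 = pair
    prots = [translate_cds(c.seq, genome.table) for c in genome.cds]
    counts: dict = {}
    total_aa = 0
    total_pairs = 0
    observed = 0
    for p in prots:
        total_aa += len(p)
        total_pairs += max(0, len(p) - 1)
        for a in p:
            counts[a] = counts.get(a, 0) + 1
        observed += sum(
            1 for i in range(len(p) - 1) if p[i] == aa1 and p[i + 1] == aa2
        )
    f1 = counts.get(aa1, 0) / total_aa if total_aa else math.nan
    f2 = counts.get(aa2, 0) / total_aa if total_aa else math.nan
    expected = f1 * f2 * total_pairs
    if expected == 0 or math.isnan(expected):
        return dict(observed=observed, expected=expected, chi2=math.nan, p=math.nan,
                    n_pairs=total_pairs)
    chi2 = (observed - expected) ** 2 / expected
    if total_pairs - expected > 0:
        chi2 += (
            (total_pairs - observed) - (total_pairs - expected)
        ) ** 2 / (total_pairs - expected)
    p = float(stats.chi2.sf(chi2, df=1))
    return dict(observed=observed, expected=expected, chi2=float(chi2), p=p,
                n_pairs=total_pairs)


__all__ = [
    "GC_GROUP_BOUNDS", "gc_group", "expected_block_share", "a_starting_fraction",
    "block_frequencies", "aod_scores", "block_ratios", "dipeptide_expectation",
    "translate_cds",
]
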