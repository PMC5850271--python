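"""Codon Adaptation Index from a ribosomal-protein reference set.

Relative adaptiveness w_c = f_c / max(f over synonyms), counted over a
reference set of highly expressed genes; a gene's CAI is the geometric
mean of w over its codons.  Methionine, tryptophan and stop codons are
excluded from the geometric mean (no synonymous choice), and unseen
synonyms receive a 0.5 pseudocount before normalisation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .codes import iter_codons
from .records import GenomeRecord

#: default 20-gene ribosomal reference set (rplA-rplF, rplI-rplU, rpsB);
#: overridable wherever a reference list is accepted
DEFAULT_REFERENCE_GENES = (
    "rplA", "rplB", "rplC", "rplD", "rplE", "rplF",
    "rplI", "rplJ", "rplK", "rplL", "rplM", "rplN", "rplO",
    "rplP", "rplQ", "rplR", "rplS", "rplT", "rplU",
    "rpsB",
)

PSEUDOCOUNT = 0.5


class MissingReferenceGenes(ValueError):
    """The genome lacks annotations for part of the reference set."""


@dataclass
class CAIModel:
    w: dict                      # sense codon -> relative adaptiveness
    reference_gene_ids: tuple
    excluded_codons: frozenset = field(default_factory=frozenset)


def fit_cai(
    genome: GenomeRecord, reference_genes=DEFAULT_REFERENCE_GENES
) -> CAIModel:
    """Fit relative adaptiveness on the genome's reference genes.

    Raises :class:`MissingReferenceGenes` unless every reference gene is
    annotated among the filtered CDSs.
    """
    by_gene = {c.gene_name: c for c in genome.cds if c.gene_name}
    missing = [g for g in reference_genes if g not in by_gene]
    if missing:
        raise MissingReferenceGenes(
            f"{genome.genome_id}: missing reference genes {missing}"
        )
    ref = [by_gene[g] for g in reference_genes]

    counts: Counter = Counter()
    for c in ref:
        for codon in iter_codons(c.seq):
            if not genome.table.is_stop(codon):
                counts[codon] += 1

    families = genome.table.synonymous_families()
    w: dict = {}
    excluded = set()
    for aa, codons in families.items():
        if len(codons) == 1:
            excluded.add(codons[0])
            continue
        raw = {c: counts.get(c, 0) for c in codons}
        adj = {c: (k if k > 0 else PSEUDOCOUNT) for c, k in raw.items()}
        mx = max(adj.values())
        for c in codons:
            w[c] = adj[c] / mx
    # codons of single-codon families (Met, and Trp under table 11) never
    # enter the geometric mean
    return CAIModel(
        w=w,
        reference_gene_ids=tuple(c.id for c in ref),
        excluded_codons=frozenset(excluded),
    )


def cai(model: CAIModel, cds_or_seq, table=None) -> float:
    """CAI of one gene: geometric mean of w over its scorable codons.

    Stop codons and single-codon families are skipped; a gene with no
    scorable codon yields NaN.
    """
    seq = cds_or_seq.seq if hasattr(cds_or_seq, "seq") else cds_or_seq
    log_sum = 0.0
    n = 0
    for codon in iter_codons(seq):
        wv = model.w.get(codon)
        if wv is None:
            continue
        log_sum += math.log(wv)
        n += 1
    if n == 0:
        return math.nan
    return math.exp(log_sum / n)


def genome_cai(
    genome: GenomeRecord,
    reference_genes=DEFAULT_REFERENCE_GENES,
    model: Optional[CAIModel] = None,
) -> pd.DataFrame:
    """CAI of every CDS (model fitted on the reference set unless given);
    values are also written onto the CodingSeq records."""
    if model is None:
        model = fit_cai(genome, reference_genes)
    rows = []
    for c in genome.cds:
        v = cai(model, c)
        c.cai = v
        rows.append(dict(cds_id=c.id, cai=v, fourth_nt=c.fourth_nt,
                         is_reference=c.id in model.reference_gene_ids))
    return pd.DataFrame(rows)


def cai_fourth_site_contrast(
    genome: GenomeRecord,
    reference_genes=DEFAULT_REFERENCE_GENES,
    high_quantile: float = 0.9,
) -> Optional[dict]:
    """Both directions of the expression contrast for one genome:
    mean CAI of fourth-site-A vs other genes, and the fourth-site-A
    proportion among highly expressed (top CAI quantile) vs the rest.
    Returns None when a class is empty or the model cannot be fitted.
    """
    try:
        df = genome_cai(genome, reference_genes)
    except MissingReferenceGenes:
        return None
    df = df.dropna(subset=["cai"])
    a = df[df.fourth_nt == "A"]
    other = df[df.fourth_nt != "A"]
    if len(a) == 0 or len(other) == 0:
        return None
    cut = df.cai.quantile(high_quantile)
    high = df[df.cai >= cut]
    low = df[df.cai < cut]
    if len(high) == 0 or len(low) == 0:
        return None
    return dict(
        genome_id=genome.genome_id,
        mean_cai_A=float(a.cai.mean()),
        mean_cai_other=float(other.cai.mean()),
        cai_difference=float(a.cai.mean() - other.cai.mean()),
        prop_A_high=float((high.fourth_nt == "A").mean()),
        prop_A_low=float((low.fourth_nt == "A").mean()),
        n=len(df),
    )


def gc3_extreme_filter(genomes, low=0.2, high=0.9):
    """Genomes with extreme silent-site composition (GC3 <= low or
    >= high); the restricted cohort for the expression sensitivity
    analysis."""
    return [g for g in genomes if g.gc3 <= low or g.gc3 >= high]
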