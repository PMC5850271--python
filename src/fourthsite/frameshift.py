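"""+1 frameshift stop-codon distances.

Dropping the first nucleotide of a CDS gives its +1-frame reading.  A
CDS starting NTGA presents the ribosome with an immediate TGA in that
frame (the "fourth-site trap").  The scan deliberately starts at the
second codon of the shifted sequence, so the trap itself never counts
as the next +1 stop; distances are the 1-based position of a stop's
first nucleotide within the shifted sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .codes import TranslationTable, get_table
from .records import GenomeRecord


@dataclass
class FrameshiftProfile:
    cds_id: str
    fourth_nt: str
    d1: Optional[int]
    d2: Optional[int]
    d3: Optional[int]


def plus1_stop_positions(
    seq: str, table: TranslationTable, include_trap: bool = False
) -> list:
    """All +1-frame stop positions of a CDS, in the shifted sequence's
    1-based coordinates.  ``include_trap`` also scans the first shifted
    codon (sensitivity analysis only)."""
    if isinstance(table, int):
        table = get_table(table)
    shifted = seq[1:]
    start = 0 if include_trap else 3
    out = []
    for i in range(start, len(shifted) - 2, 3):
        if shifted[i : i + 3] in table.stops:
            out.append(i + 1)
    return out


def plus1_stop_distances(
    seq: str, table: TranslationTable, k: int = 1, include_trap: bool = False
) -> Optional[int]:
    """Position of the k-th +1-frame stop (k in 1..3 typically), or None."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = plus1_stop_positions(seq, table, include_trap)
    return hits[k - 1] if len(hits) >= k else None


def frameshift_profiles(genome: GenomeRecord, include_trap: bool = False) -> pd.DataFrame:
    rows = []
    for c in genome.cds:
        hits = plus1_stop_positions(c.seq, genome.table, include_trap)
        rows.append(
            dict(
                cds_id=c.id,
                fourth_nt=c.fourth_nt,
                d1=hits[0] if len(hits) > 0 else None,
                d2=hits[1] if len(hits) > 1 else None,
                d3=hits[2] if len(hits) > 2 else None,
            )
        )
    return pd.DataFrame(rows)


def paired_distance_contrast(
    genome: GenomeRecord, k: int = 1, include_trap: bool = False
) -> Optional[dict]:
    """Per-genome mean +1 stop distance for fourth-site-A genes vs the
    rest (genes without a defined distance are dropped).  Returns None
    (with a warning upstream) when either class is empty."""
    prof = frameshift_profiles(genome, include_trap)
    col = f"d{k}"
    prof = prof.dropna(subset=[col])
    a = prof.loc[prof.fourth_nt == "A", col].astype(float)
    other = prof.loc[prof.fourth_nt != "A", col].astype(float)
    if len(a) == 0 or len(other) == 0:
        return None
    return dict(
        genome_id=genome.genome_id,
        mean_A=float(a.mean()),
        mean_other=float(other.mean()),
        difference=float(a.mean() - other.mean()),
        n_A=len(a),
        n_other=len(other),
    )


def cohort_distance_table(genomes, k: int = 1) -> pd.DataFrame:
    rows = []
    for g in genomes:
        r = paired_distance_contrast(g, k=k)
        if r is not None:
            rows.append(r)
    return pd.DataFrame(rows)


def gc_distance_correlation(genomes, k: int = 1) -> dict:
    """Spearman correlation of genome GC with the genome-mean distance
    to the k-th +1 stop; stops are AT-rich so the expectation is a
    strong positive trend."""
    genomes = list(genomes)
    if len(genomes) < 5:
        raise ValueError("need at least 5 genomes")
    gcs, means = [], []
    for g in genomes:
        prof = frameshift_profiles(g).dropna(subset=[f"d{k}"])
        if len(prof) == 0:
            continue
        gcs.append(g.gc)
        means.append(float(prof[f"d{k}"].astype(float).mean()))
    if len(set(means)) < 2 or len(set(gcs)) < 2:
        return dict(rho=math.nan, p=math.nan, n=len(gcs))
    rho, p = stats.spearmanr(gcs, means)
    return dict(rho=float(rho), p=float(p), n=len(gcs))
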