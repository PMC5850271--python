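"""Per-site nucleotide enrichment statistics.

The central quantity is the enrichment ratio at a 1-based CDS site n
for a nucleotide B:

    ratio_B(n) = f_B(n) / F_B(x),

where f_B(n) is the proportion of CDSs carrying B at site n, F_B(x)
the proportion of all codons in the genome carrying B at intracodon
position x = ((n - 1) mod 3) + 1, so the denominator controls for the
genome's base composition at that codon position.  A ratio of 1 means
the site uses B exactly in proportion to genome-wide codon usage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .records import GenomeRecord

NUCLEOTIDES = "ACGT"


@dataclass
class EnrichmentResult:
    genome_id: str
    site: int
    nucleotide: str
    f: float            # proportion of CDSs with the nucleotide at the site
    F: float            # proportion of codons with it at intracodon position x
    ratio: float
    n_cds: int
    chi2: Optional[float] = None
    p_raw: Optional[float] = None
    p_bonf: Optional[float] = None
    significant: Optional[bool] = None

    @property
    def intracodon_position(self) -> int:
        return (self.site - 1) % 3 + 1

    @property
    def undefined(self) -> bool:
        return not math.isfinite(self.ratio)


def site_fractions(genome: GenomeRecord, site: int) -> dict:
    """Fractions of CDSs with each nucleotide at a 1-based site (CDSs
    shorter than the site are excluded)."""
    seqs = [c.seq for c in genome.cds if len(c.seq) >= site]
    if not seqs:
        raise ValueError(f"no CDS of length >= {site}")
    n = len(seqs)
    counts = {b: 0 for b in NUCLEOTIDES}
    for s in seqs:
        counts[s[site - 1]] += 1
    return {b: counts[b] / n for b in NUCLEOTIDES}


def position_fraction(
    genome: GenomeRecord, nucleotide: str, intracodon_position: int,
    exclude_terminal_codons: bool = False,
) -> float:
    """F_B(x): proportion of codons with the nucleotide at intracodon
    position x (1..3), over all filtered CDSs.  Start and stop codons are
    counted by default; ``exclude_terminal_codons`` drops them."""
    if intracodon_position not in (1, 2, 3):
        raise ValueError("intracodon position must be 1, 2 or 3")
    off = intracodon_position - 1
    total = hits = 0
    for c in genome.cds:
        s = c.seq[3:-3] if exclude_terminal_codons else c.seq
        sub = s[off::3]
        total += len(sub)
        hits += sub.count(nucleotide)
    return hits / total if total else float("nan")


def enrichment_ratio(
    genome: GenomeRecord,
    nucleotide: str = "A",
    site: int = 4,
    exclude_terminal_codons: bool = False,
) -> EnrichmentResult:
    """Enrichment ratio of ``nucleotide`` at ``site`` for one genome."""
    if nucleotide not in NUCLEOTIDES:
        raise ValueError(f"bad nucleotide {nucleotide!r}")
    fr = site_fractions(genome, site)
    f = fr[nucleotide]
    x = (site - 1) % 3 + 1
    F = position_fraction(genome, nucleotide, x, exclude_terminal_codons)
    n_cds = sum(1 for c in genome.cds if len(c.seq) >= site)
    if F == 0 or not math.isfinite(F):
        warnings.warn(
            f"{genome.genome_id}: F_{nucleotide}({x}) undefined or zero; "
            "ratio is undefined"
        )
        ratio = float("nan")
    else:
        ratio = f / F
    return EnrichmentResult(
        genome_id=genome.genome_id, site=site, nucleotide=nucleotide,
        f=f, F=F, ratio=ratio, n_cds=n_cds,
    )


def ratio_test(
    result: EnrichmentResult,
    m: int = 1,
    alpha: float = 0.01,
    four_category: bool = False,
    genome: Optional[GenomeRecord] = None,
) -> EnrichmentResult:
    """Goodness-of-fit test of the observed site count against the
    codon-position expectation, with Bonferroni correction over ``m``
    comparisons.

    Default is the 1-df dichotomy (nucleotide vs not); ``four_category``
    computes the 3-df test over all four nucleotides (requires
    ``genome`` to recover the other site fractions).
    """
    n = result.n_cds
    if n == 0:
        raise ValueError("no CDSs")
    if result.F in (0.0, 1.0) or not math.isfinite(result.F):
        result.chi2 = result.p_raw = result.p_bonf = float("nan")
        result.significant = None
        return result
    if four_category:
        if genome is None:
            raise ValueError("four-category test needs the genome")
        obs = np.array(
            [site_fractions(genome, result.site)[b] * n for b in NUCLEOTIDES]
        )
        exp = np.array(
            [position_fraction(genome, b, result.intracodon_position) * n
             for b in NUCLEOTIDES]
        )
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        p = float(stats.chi2.sf(chi2, df=3))
    else:
        obs = result.f * n
        exp = result.F * n
        chi2 = (obs - exp) ** 2 / exp + ((n - obs) - (n - exp)) ** 2 / (n - exp)
        p = float(stats.chi2.sf(chi2, df=1))
    result.chi2 = float(chi2)
    result.p_raw = p
    result.p_bonf = min(1.0, m * p)
    result.significant = bool(result.p_bonf < alpha)
    return result


def cohort_ratios(
    genomes,
    nucleotides: str = "A",
    sites=(4,),
    alpha: float = 0.01,
    m: Optional[int] = None,
) -> pd.DataFrame:
    """Enrichment ratios + ratio tests for a cohort; Bonferroni ``m``
    defaults to the number of genomes tested.  Undefined ratios are kept
    as NaN rows (and must be excluded from summaries by the caller)."""
    genomes = list(genomes)
    if m is None:
        m = len(genomes)
    rows = []
    for g in genomes:
        for site in sites:
            for b in nucleotides:
                r = enrichment_ratio(g, b, site)
                r = ratio_test(r, m=m, alpha=alpha)
                rows.append(
                    dict(
                        genome_id=r.genome_id, site=site, nucleotide=b,
                        f=r.f, F=r.F, ratio=r.ratio, n_cds=r.n_cds,
                        chi2=r.chi2, p_raw=r.p_raw, p_bonf=r.p_bonf,
                        significant=r.significant, gc=g.gc, gc3=g.gc3,
                        table=g.table.id,
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# positional GC-variance conservation profile
# ---------------------------------------------------------------------------

def gc_variance_profile(genomes, codons=range(2, 31)) -> pd.DataFrame:
    """Across-genome population variance of per-position GC proportion.

    For each site in codons 2..30, the GC proportion across CDSs is
    computed per genome; the variance of those genome-level proportions
    is the conservation signal (low variance = constrained position).
    """
    genomes = list(genomes)
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    rows = []
    for codon_i in codons:
        for pos in (1, 2, 3):
            site = (codon_i - 1) * 3 + pos
            props = []
            for g in genomes:
                fr = site_fractions(g, site)
                props.append(fr["G"] + fr["C"])
            rows.append(
                dict(
                    codon=codon_i, intracodon_position=pos, site=site,
                    gc_variance=float(np.var(props)),  # population variance
                    mean_gc=float(np.mean(props)),
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GC3 regression contrast
# ---------------------------------------------------------------------------

def z_equivalence(b1: float, se1: float, b2: float, se2: float):
    """Two-tailed Z-test that two regression slopes are equal."""
    z = (b1 - b2) / math.sqrt(se1**2 + se2**2)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def gc3_slope_contrast(genomes) -> dict:
    """OLS slopes of (i) fourth-site A fraction and (ii) genome A-starting
    codon fraction, each on GC3, with the Z-test of slope equality.

    Regressions are unweighted across genomes.  The fourth-site slope
    being less negative than the codon slope indicates fourth-site A is
    more resilient to GC pressure.
    """
    genomes = list(genomes)
    if len(genomes) < 3:
        raise ValueError("need at least 3 genomes")
    gc3 = np.array([g.gc3 for g in genomes])
    if np.var(gc3) == 0:
        raise ValueError("zero GC3 variance across genomes")
    f4 = np.array([site_fractions(g, 4)["A"] for g in genomes])
    fall = np.array([position_fraction(g, "A", 1) for g in genomes])
    X = sm.add_constant(gc3)
    fit4 = sm.OLS(f4, X).fit()
    fitall = sm.OLS(fall, X).fit()
    b1, se1 = fit4.params[1], fit4.bse[1]
    b2, se2 = fitall.params[1], fitall.bse[1]
    # positive Z when the fourth-site slope is less negative (more
    # resilient to GC pressure) than the all-codon slope
    z, p = z_equivalence(b1, se1, b2, se2)
    return dict(
        slope_fourth_site=float(b1), se_fourth_site=float(se1),
        slope_all_codons=float(b2), se_all_codons=float(se2),
        z=z, p=p,
    )
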