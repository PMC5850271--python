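"""Cohort-level statistics and orchestration.

Shared tests used by every contrast in the analysis: the paired
Wilcoxon signed-rank test for within-genome class contrasts, the
Kruskal-Wallis test with Tukey-Kramer post-hocs for multi-site ratio
comparisons, the loess-residual contrast between translation tables,
and the genome-level multivariate model of fourth-site A use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import site_stats
from .records import GenomeRecord


@dataclass
class CohortResult:
    analysis: str
    test: str
    statistic: float
    p: float
    n: int
    effect: dict
    rows: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# shared tests
# ---------------------------------------------------------------------------

def paired_location_test(x, y) -> CohortResult:
    """Two-tailed Wilcoxon signed-rank test on paired per-genome values
    (zero differences dropped; all-zero input yields the p = 1 sentinel)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need paired samples of equal length >= 5")
    diffs = x - y
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return CohortResult(
            analysis="paired", test="wilcoxon_signed_rank",
            statistic=math.nan, p=1.0, n=len(x),
            effect=dict(mean_difference=0.0),
        )
    stat, p = stats.wilcoxon(x, y)
    return CohortResult(
        analysis="paired", test="wilcoxon_signed_rank",
        statistic=float(stat), p=float(p), n=len(x),
        effect=dict(
            mean_difference=float(diffs.mean()),
            sd_difference=float(diffs.std(ddof=1)),
            mean_x=float(x.mean()), mean_y=float(y.mean()),
            sd_x=float(x.std(ddof=1)), sd_y=float(y.std(ddof=1)),
        ),
    )


def multi_group_test(
    groups: dict, log_transform: bool = False, posthoc: str = "tukey"
) -> CohortResult:
    """Kruskal-Wallis over named groups plus all pairwise post-hoc
    comparisons (Tukey-Kramer on the possibly log-transformed values, or
    Dunn-style pairwise Mann-Whitney with Bonferroni)."""
    names = list(groups)
    if len(names) < 2 or any(len(groups[g]) < 2 for g in names):
        raise ValueError("need >= 2 groups with >= 2 values each")
    vals = {g: np.asarray(groups[g], dtype=float) for g in names}
    if log_transform:
        vals = {g: np.log(v) for g, v in vals.items()}
    stat, p = stats.kruskal(*vals.values())
    flat = np.concatenate([vals[g] for g in names])
    labels = np.concatenate([[g] * len(vals[g]) for g in names])
    pairs = []
    if posthoc == "tukey":
        tk = pairwise_tukeyhsd(flat, labels)
        for row in tk.summary().data[1:]:
            pairs.append(
                dict(group1=str(row[0]), group2=str(row[1]),
                     meandiff=float(row[2]), p=float(row[3]))
            )
    elif posthoc == "dunn":
        m = len(names) * (len(names) - 1) // 2
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                u, up = stats.mannwhitneyu(
                    vals[names[i]], vals[names[j]], alternative="two-sided"
                )
                pairs.append(
                    dict(group1=names[i], group2=names[j],
                         meandiff=float(vals[names[i]].mean() - vals[names[j]].mean()),
                         p=min(1.0, float(up) * m))
                )
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return CohortResult(
        analysis="multi_group", test="kruskal_wallis",
        statistic=float(stat), p=float(p),
        n=int(sum(len(v) for v in vals.values())),
        effect=dict(
            group_means={g: float(np.asarray(groups[g], dtype=float).mean())
                         for g in names},
            posthoc=pairs,
        ),
    )


# ---------------------------------------------------------------------------
# translation-table contrast on loess residuals
# ---------------------------------------------------------------------------

def table4_residual_contrast(
    ratio_table: pd.DataFrame, span: float = 0.75
) -> CohortResult:
    """Residuals of the A4 ratio on genome GC from a loess fit over all
    genomes, compared between translation tables.

    ``ratio_table`` needs columns genome_id, ratio, gc, table (as from
    :func:`fourthsite.site_stats.cohort_ratios` at site 4, A).
    """
    df = ratio_table.dropna(subset=["ratio", "gc"]).copy()
    tables = sorted(df["table"].unique())
    if len(tables) < 2:
        raise ValueError("need genomes of both translation tables")
    if len(df) < 10:
        raise ValueError("need >= 10 genomes")
    fitted = lowess(
        df["ratio"].to_numpy(), df["gc"].to_numpy(),
        frac=span, return_sorted=False,
    )
    df["residual"] = df["ratio"].to_numpy() - fitted
    grp = {int(t): df.loc[df["table"] == t, "residual"].to_numpy() for t in tables}
    stat, p = stats.kruskal(*grp.values())
    return CohortResult(
        analysis="table4_residual_contrast", test="kruskal_wallis",
        statistic=float(stat), p=float(p), n=len(df),
        effect={f"mean_residual_table{t}": float(v.mean()) for t, v in grp.items()},
        rows=df,
    )


# ---------------------------------------------------------------------------
# genome-level multivariate model
# ---------------------------------------------------------------------------

SUMMARY_PREDICTORS = [
    "prop_A_start_codons", "A6", "A7", "A9", "A10", "A12",
    "prop_leader", "table4",
]


def genome_summary(genome: GenomeRecord, leader_ids: Optional[set] = None) -> dict:
    """One genome's row for the multivariate model: fourth-site A
    proportion, A content at sites 6/7/9/10/12, the A-starting codon
    proportion, leader-gene proportion and the translation table."""
    row = dict(genome_id=genome.genome_id)
    row["prop_fourth_A"] = site_stats.site_fractions(genome, 4)["A"]
    for s in (6, 7, 9, 10, 12):
        row[f"A{s}"] = site_stats.site_fractions(genome, s)["A"]
    row["prop_A_start_codons"] = site_stats.position_fraction(genome, "A", 1)
    if leader_ids is None:
        leader_ids = {c.id for c in genome.cds if c.has_leader}
    row["prop_leader"] = len(leader_ids) / genome.n_cds if genome.n_cds else math.nan
    row["table4"] = 1 if genome.table.id == 4 else 0
    row["gc"] = genome.gc
    return row


def multivariate_summary(
    genome_table: pd.DataFrame,
    response: str = "prop_fourth_A",
    predictors=SUMMARY_PREDICTORS,
) -> dict:
    """OLS of genome fourth-site A use on its candidate explanations;
    complete cases only, machine-collinear columns dropped with a
    warning."""
    cols = [response] + list(predictors)
    df = genome_table[cols].dropna()
    X = df[list(predictors)].astype(float)
    # drop exactly collinear columns
    keep = []
    for c in X.columns:
        trial = X[keep + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(c)
        else:
            import warnings

            warnings.warn(f"dropping collinear predictor {c!r}")
    X = sm.add_constant(X[keep])
    fit = sm.OLS(df[response].astype(float), X).fit()
    return dict(
        r_squared=float(fit.rsquared),
        r_squared_adj=float(fit.rsquared_adj),
        n=int(fit.nobs),
        coefficients=fit.params.to_dict(),
        pvalues=fit.pvalues.to_dict(),
        conf_int=fit.conf_int().apply(tuple, axis=1).to_dict(),
    )
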