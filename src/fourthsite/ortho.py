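"""First-position substitution profiles between ortholog pairs.

Pairs are compared positionally from the start codon (no realignment):
for each of the first 11 codons, the focal genome's first-position
nucleotide is noted and the proportion of comparator sequences that
differ from it is computed, per focal nucleotide.  A fourth site under
purifying selection shows a codon-2 focal-A change proportion below the
downstream codons'.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

N_CODONS = 11
MIN_LEN = 3 * N_CODONS  # 33 nt in both members

from .codes import NTG_STARTS


def substitution_profile(pairs, n_codons: int = N_CODONS) -> pd.DataFrame:
    """Proportion of pairs whose comparator differs from the focal
    nucleotide, per codon (1..n_codons) and focal first-position base.

    Pairs shorter than ``3 * n_codons`` in either member, or whose
    comparator lacks an NTG start, are skipped and counted.
    """
    min_len = 3 * n_codons
    changed = np.zeros((n_codons, 4), dtype=int)
    total = np.zeros((n_codons, 4), dtype=int)
    nt_idx = {b: i for i, b in enumerate("ACGT")}
    skipped_short = skipped_start = 0
    for focal, comp in pairs:
        fseq = focal.seq if hasattr(focal, "seq") else focal
        cseq = comp.seq if hasattr(comp, "seq") else comp
        if len(fseq) < min_len or len(cseq) < min_len:
            skipped_short += 1
            continue
        if cseq[:3] not in NTG_STARTS:
            skipped_start += 1
            continue
        for codon_i in range(n_codons):
            pos = 3 * codon_i
            fi = nt_idx.get(fseq[pos])
            if fi is None:
                continue
            total[codon_i, fi] += 1
            if cseq[pos] != fseq[pos]:
                changed[codon_i, fi] += 1
    rows = []
    for codon_i in range(n_codons):
        for b, bi in nt_idx.items():
            t = total[codon_i, bi]
            rows.append(
                dict(
                    codon=codon_i + 1,
                    focal_nt=b,
                    n_pairs=int(t),
                    n_changed=int(changed[codon_i, bi]),
                    proportion=changed[codon_i, bi] / t if t else math.nan,
                )
            )
    df = pd.DataFrame(rows)
    df.attrs["skipped_short"] = skipped_short
    df.attrs["skipped_start"] = skipped_start
    return df


def fourth_site_resilience_test(
    profile: pd.DataFrame, focal_nt: str = "A", downstream=range(3, 12)
) -> dict:
    """One-sample two-tailed t-test of the downstream codons' focal-A
    change proportions against the codon-2 value (treated as the fixed
    reference).  A positive t means codon 2 changes less than its
    neighbours."""
    sub = profile[profile.focal_nt == focal_nt].set_index("codon")["proportion"]
    codon2 = sub.get(2, math.nan)
    vals = sub.reindex(list(downstream)).dropna().to_numpy()
    if math.isnan(codon2) or len(vals) < 3:
        raise ValueError("need codon-2 and >= 3 downstream proportions")
    if np.ptp(vals) == 0:  # degenerate: no downstream variance
        t = 0.0 if vals[0] == codon2 else math.copysign(math.inf, vals[0] - codon2)
        p = 1.0 if t == 0.0 else 0.0
    else:
        t, p = stats.ttest_1samp(vals, popmean=codon2)
    return dict(
        codon2_proportion=float(codon2),
        downstream_mean=float(vals.mean()),
        t=float(t),
        p=float(p),
        n_downstream=int(len(vals)),
    )
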