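#!/usr/bin/env python
"""Amino-acid preference model tests.

AOD scores per GC group, the serine/arginine coding-block contrasts,
and the Met-Met / Met-Ile dipeptide expectations.  Under nucleotide-
level selection the A-starting blocks (K, N, T, S_A, R_A) should be
preferred at the second position with S_A above S_T — the pattern that
rules out purely protein-level selection.

Writes results/03_aod.tsv, results/03_block_ratios.tsv and
results/03_dipeptides.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from cohort import ensure_results, study_cohort  # noqa: E402

from fourthsite import aa_prefs, pipeline


def main() -> None:
    cohort = study_cohort()
    genomes = [g for g, _ in cohort]
    res = ensure_results()

    aod = aa_prefs.aod_scores(genomes)
    aod.to_csv(res / "03_aod.tsv", sep="\t", index=False)
    wide = aod.pivot(index="block", columns="gc_group", values="aod").round(4)
    print("AOD by GC group (positive = second-position preference):")
    print(wide.to_string())

    blocks = []
    for g in genomes:
        br = aa_prefs.block_ratios(g).reset_index()
        br.insert(0, "genome_id", g.genome_id)
        blocks.append(br)
    bdf = pd.concat(blocks, ignore_index=True)
    bdf.to_csv(res / "03_block_ratios.tsv", sep="\t", index=False)

    sa = bdf[bdf.block == "S_A"].set_index("genome_id").ratio
    st = bdf[bdf.block == "S_T"].set_index("genome_id").ratio
    pt = pipeline.paired_location_test(sa, st.loc[sa.index])
    print(f"\nS_A ratio {sa.mean():.3f} vs S_T ratio {st.mean():.3f} "
          f"(paired Wilcoxon p={pt.p:.3g}, N={pt.n})")

    dips = []
    for g in genomes:
        for pair in (("M", "M"), ("M", "I")):
            out = aa_prefs.dipeptide_expectation(g, pair)
            dips.append(dict(genome_id=g.genome_id, pair="".join(pair), **out))
    ddf = pd.DataFrame(dips)
    ddf.to_csv(res / "03_dipeptides.tsv", sep="\t", index=False)
    summary = ddf.groupby("pair")[["observed", "expected"]].mean().round(2)
    print("\nmean dipeptide counts (observed vs independence expectation):")
    print(summary.to_string())


if __name__ == "__main__":
    main()
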