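#!/usr/bin/env python
"""Genome-level multivariate model of fourth-site A use.

Regresses the per-genome fourth-site A proportion on the genome's
A-starting codon proportion, A content at sites 6/7/9/10/12, leader
gene proportion and translation table, reporting the coefficient table
and R^2.

Writes results/07_genome_table.tsv and results/07_model.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from cohort import ensure_results, study_cohort  # noqa: E402

from fourthsite import genome_io, pipeline


def main() -> None:
    cohort = study_cohort()
    res = ensure_results()

    rows = []
    for genome, _ in cohort:
        # leader detection runs on the actual intergenic regions
        leaders = {
            c.id
            for c in genome.cds
            if 200 < len(c.seq) < 10_000
            and 100 < len(genome.intergenic.get(c.id, "")) < 1400
            and genome_io.find_leader(genome.intergenic[c.id], genome.table)
        }
        rows.append(pipeline.genome_summary(genome, leader_ids=leaders))
    tab = pd.DataFrame(rows)
    tab.to_csv(res / "07_genome_table.tsv", sep="\t", index=False)

    model = pipeline.multivariate_summary(tab)
    coef = pd.DataFrame(
        dict(coefficient=model["coefficients"], p=model["pvalues"])
    ).round(4)
    coef.to_csv(res / "07_model.tsv", sep="\t")
    print(coef.to_string())
    print(f"\nR^2 = {model['r_squared']:.3f} "
          f"(adjusted {model['r_squared_adj']:.3f}, N = {model['n']})")


if __name__ == "__main__":
    main()
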