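# fourthsite

Bacterial coding sequences carry a striking compositional signal
immediately after the start codon: the fourth nucleotide — the first
base of the second codon — is adenine far more often than genome codon
usage predicts.  A CDS beginning `NTGA` turns into the stop codon `TGA`
the moment a ribosome slips into the +1 frame, so this enrichment may
be an error-proofing signal ("frameshift correction") rather than a
protein- or mRNA-level preference.

`fourthsite` is an analysis toolkit for this question, aimed at
researchers in molecular evolution and codon-usage bias.  It measures
the enrichment, and tests the three candidate explanations — amino-acid
preference at the second peptide position, 5′ mRNA destabilisation, and
+1 frameshift correction — on any collection of annotated genomes, with
a fully labelled synthetic-genome generator so every estimator is
testable without external data.

## The central statistic

For nucleotide *B* at 1-based CDS site *n* (site 1 = first base of the
start codon):

```
ratio_B(n) = f_B(n) / F_B(x),    x = ((n − 1) mod 3) + 1
```

where `f_B(n)` is the proportion of CDSs with *B* at site *n* and
`F_B(x)` the proportion of all genome codons with *B* at intracodon
position *x*.  A ratio of 1 means the site simply reflects codon usage;
`ratio_A(4) > 1` is the fourth-site signal.  Significance comes from a
1-df Pearson χ² on the observed site count against the codon-position
expectation, Bonferroni-corrected across genomes.

Around it the package implements CDS filtering under translation
tables 11 and 4, start-codon censuses, leader-ORF detection, 4-nt
overlap screening, average-of-difference (AOD) second-position
amino-acid scores, serine/arginine coding-block contrasts,
Shine–Dalgarno identification by anti-SD hybridization free-energy
scanning, the Codon Adaptation Index from a ribosomal reference set,
+1-frame stop-distance profiles, ortholog substitution profiles, and
the cohort statistics tying them together (paired Wilcoxon,
Kruskal–Wallis with Tukey–Kramer post-hocs, loess-residual
translation-table contrast, a genome-level multivariate model).
See `docs/methods.md` for the full model descriptions.

## Worked example

```python
from fourthsite import site_stats
from fourthsite.syn_genomes import GeneratorConfig, generate_genome

# a genome with a known 1.8-fold fourth-site A excess
genome, truth = generate_genome(
    GeneratorConfig(n_cds=2000, seed=11, fourth_site_A_excess=1.8,
                    sd_prob=0, leader_prob=0, ref_gene_w=0)
)
r = site_stats.ratio_test(site_stats.enrichment_ratio(genome, "A", site=4))
print(f"f_A(4)={r.f:.3f}  F_A(1)={r.F:.3f}  ratio={r.ratio:.3f}  "
      f"chi2={r.chi2:.1f}  p={r.p_raw:.3g}")
```

prints

```
f_A(4)=0.506  F_A(1)=0.271  ratio=1.867  chi2=559.6  p=1.03e-123
```

51 % of CDSs carry fourth-site A against a 27 % codon-usage baseline:
the injected 1.8-fold excess is recovered (ratio 1.87) and is
overwhelmingly significant.

The `analysis/` directory holds the numbered study drivers, each
regenerating the same seeded 24-genome cohort and writing its tables
under `results/`:

```bash
python analysis/01_simulate_cohort.py      # cohort + truth labels
python analysis/02_enrichment_ratios.py    # ratios, χ² counts, GC3 slopes
python analysis/03_amino_acid_model.py     # AOD scores, S_A/S_T blocks, dipeptides
python analysis/04_sd_and_expression.py    # SD and CAI contrasts
python analysis/05_frameshift_model.py     # +1 stop distances, table-4 residuals
python analysis/06_ortholog_conservation.py
python analysis/07_multivariate.py
```

On the default cohort these report, e.g., 20/24 genomes with a
significantly elevated A₄ ratio (mean 1.74 ± 0.27) while C₄/G₄/T₄ show
0/24; an S_A:S_T second-position reversal (ratios 1.83 vs 0.68, paired
Wilcoxon p = 6 × 10⁻⁷); depressed loess residuals for the table-4
genomes (−0.68 vs −0.01, Kruskal–Wallis p = 0.002); and a GC–stop-
distance correlation of ρ = 0.96.

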