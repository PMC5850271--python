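# Methods

`fourthsite` analyses adenine enrichment at the fourth nucleotide of
bacterial coding sequences (the first base of the second codon) and the
three candidate explanations for it: amino-acid preference at the
second peptide position, 5′ mRNA destabilisation, and +1 frameshift
correction (a CDS starting NTG**A** presents a +1-shifted ribosome with
an immediate TGA stop).  This note records the models, the defaults,
the numerical choices, and what the synthetic data do and do not show.

## Enrichment ratios and the ratio test

For nucleotide *B* at 1-based CDS site *n* (site 1 = first base of the
start codon),

    ratio_B(n) = f_B(n) / F_B(x),   x = ((n − 1) mod 3) + 1,

where *f* is the fraction of CDSs carrying *B* at site *n* and *F* the
fraction of all codons carrying *B* at intracodon position *x*.  The
denominator *F* counts **all** codons of all filtered CDSs, start and
stop codons included; `exclude_terminal_codons=True` provides the
alternative.  Both conventions are exact with respect to the toy
examples in the test suite; the inclusive default is the one all
reported numbers use.

Significance is a one-degree-of-freedom Pearson goodness-of-fit on the
dichotomy (*B* at the site vs not), observed count `n·f` against
expectation `n·F`, Bonferroni-corrected with `m` = number of genomes in
the run and judged at 0.01.  A four-category (3 df) variant is
available behind a flag.  Undefined ratios (`F = 0`) become NaN
sentinels and are excluded from cohort summaries, never imputed.

## CDS filtering and annotation screens

A CDS is accepted iff its length is a multiple of three, it is
ACGT-only, has no internal stop and ends in a stop of its translation
table (11: TAA/TAG/TGA; 4: TAA/TAG, TGA = Trp).  Analyses additionally
require an NTG start (ATG/GTG/TTG); `require_atg` gives the stricter
variant.  Ambiguity codes are rejected, never converted.  Minus-strand
CDSs are reverse-complemented at read time; everything downstream
operates on sense-strand sequences.

Leader ORFs are searched in upstream intergenic regions of length in
(100, 1400) for structural CDSs of length in (200, 10 000); an ORF
qualifies with a regular NTG start, length a multiple of three, no
internal stop, a legal stop, and at least 7 codons ("longer than six
codons").  The longest qualifying ORF wins, ties going to the most 5′.
On random intergenic sequence this rule fires very frequently — a
(100, 1400)-nt random region almost always contains some 7-codon ORF —
so on synthetic data leader *detection* saturates and parameter
recovery for leader insertion uses the generator's truth labels, not
the detector.  Real intergenic sequence is not random, so saturation
is a property of the synthetic null, not of the method.

4-nt overlaps: a CDS whose start lies exactly 4 nt inside an upstream
TGA-terminated CDS on the same strand mechanically receives a
fourth-site A.  The screen is same-strand only by default (the
opposite-strand variant is exposed but off), and the enrichment
analysis can be rerun after excluding flagged CDSs.

Best hits from tabular alignments (outfmt-6 column order): minimal
E-value, ties by higher percent identity, then lexicographic subject
id; malformed rows are skipped and counted.

## Amino-acid preferences (AOD and coding blocks)

Average-of-difference scores per amino-acid block are the mean, over
the genomes of a GC group, of (second-codon frequency − frequency
across all codons).  The published formula sums (f − F)/n over CDSs,
which reduces to the per-genome difference; the group mean is the only
reading consistent with per-group scores, and is what is implemented.
GC groups: low ≤ 44.19 % < medium ≤ 60.91 % < high.  The six-fold
degenerates are split by first base (S_A = AGC/AGT vs S_T = TCN,
R_A = AGA/AGG vs R_C = CGN, and the leucine split L_T = TTA/TTG vs
L_C = CTN, reported for completeness).  `F` includes the start codon by
default, so methionine's background is inflated exactly as in a
transcriptome-wide count (flag to exclude).  Blocks are weighted by
codon count, i.e. genes contribute proportionally to length.
Dipeptide expectations are independence products of proteome amino-acid
frequencies times the number of adjacent ordered pairs.

## +1 frameshift stop distances

The shifted sequence is the CDS minus its first nucleotide.  Scanning
starts at the *second* shifted codon, so the fourth-site trap itself
never counts as the "next" +1 stop (`include_trap` reverses this for
sensitivity analysis).  Distances are 1-based positions of a stop's
first nucleotide in the shifted sequence; incomplete terminal codons
are never matched, and the whole shifted sequence (including the region
overlapping the native stop) is scanned.  Distances are contrasted
within genomes between fourth-site-A and other genes; the cohort-level
paired test is the Wilcoxon signed-rank.  The synthetic generator
induces no dependence of downstream stop placement on the fourth site,
so on synthetic cohorts this contrast is a null check — a significant
cohort result there would indicate a bug, not biology.

## Shine–Dalgarno scanning

The anti-SD tail is taken from the last 5′-GAT-3′ motif of a 16S
sequence through its 3′ end (inclusive; the inclusive convention makes
the canonical 13-nt E. coli-like tail fall inside the 8–15 nt bound);
across multiple 16S copies the most frequent accepted tail wins.  Each
CDS is scanned over a 60-nt window with the start A at position 30
(29 nt of upstream context; shortfalls padded with unbindable N).  At
every alignment of the tail the free energy is the sum of Watson–Crick
and G:U nearest-neighbour stack terms over the single best contiguous
helix, plus 4.09 kcal/mol duplex initiation and 0.45 kcal/mol per
terminal A:U/G:U pair (Turner-lineage RNA:RNA parameters at 37 °C; no
dangling ends in v1).  Non-negative totals are "no binding" (0).  The
model is calibrated, not bit-identical: it reproduces the three
published core-motif energies (GGAG −3.60793, GAGG −3.60793, AGGA
−3.144505 kcal/mol) within ±0.5 kcal/mol.  SD presence: minimal ΔG° ≤
−3.4535 kcal/mol (the mean of those three); strong SD: ≤ −8.4 kcal/mol
(the GGAGGT exemplar).  Offsets are reported with the binding site's
5′ end relative to the start A at 0, negative upstream.  Random
sequence frequently clears the presence threshold (weak SD-like motifs
are common), which attenuates — but does not flip — coupling contrasts
classified by detected SD.

## CAI

Relative adaptiveness `w_c = f_c / max(f over synonyms)` is fitted on a
20-gene ribosomal reference set (default rplA–rplF, rplI–rplU, rpsB;
overridable), with a 0.5 pseudocount for unseen synonyms; genomes
missing any reference annotation are skipped.  A gene's CAI is the
geometric mean of `w` over its codons, excluding stops and single-codon
families (Met; Trp under table 11).  "Highly expressed" in the reverse
contrast is the top CAI decile by default (configurable quantile).  The
GC3-restricted rerun interprets the extreme-composition cohort as
GC3 ≤ 20 % or ≥ 90 %.

## Ortholog substitution profiles

Pairs are compared positionally from the start codon with no
realignment (pairs shorter than 33 nt or with a non-NTG comparator
start are skipped and counted).  For codons 1–11 the proportion of
comparators differing from the focal first-position base is tabulated
per focal nucleotide.  The resilience test is a two-tailed one-sample
t of the downstream codons' focal-A proportions against the codon-2
value treated as fixed.  Because that reference value is itself an
estimate with the same sampling variance as each downstream value,
the test is anticonservative under the null — it mirrors the framing
of the original analysis and should be read as descriptive; the
injected-rate recovery checks use binomial intervals instead.

## Cohort statistics

"Paired Wilcoxon" is implemented as the Wilcoxon signed-rank test (the
only paired Wilcoxon procedure), two-tailed, zero differences dropped,
all-zero input yielding a p = 1 sentinel.  Multi-site ratio contrasts
use Kruskal–Wallis on (optionally log-transformed) values with
Tukey–Kramer post-hocs on the same transformed values (a Dunn-style
pairwise Mann–Whitney/Bonferroni alternative is available).  The
translation-table contrast fits a locally weighted regression (lowess,
span 0.75, locally linear) of the A4 ratio on genome GC over all
genomes and compares residuals between tables by Kruskal–Wallis.  The
genome-level multivariate model is OLS of the fourth-site A proportion
on the A-starting codon proportion, A content at sites 6/7/9/10/12,
the leader-gene proportion and a table-4 indicator; exactly collinear
columns are dropped with a warning.

## Synthetic genomes

The generator emulates the statistical structure the analyses estimate
and nothing more.  Per genome: codon usage with independent
per-position base composition calibrated so expected codon GC equals
`gc_target` exactly; internal codons i.i.d. from that table; CDS length
70 + Gamma(2) codons with mean 300 (structural leader bounds need
> 200 nt); NTG starts at the observed bacterial mix
(ATG/GTG/TTG ≈ 81.2/13.1/5.7 % after renormalising within NTG); stops
uniform over the table's legal stops.  The fourth-site lever scales the
probability that the second codon starts with A by δ
(`fourth_site_A_excess`), rescaling the non-A mass to 1 − δ·p so the
injected enrichment ratio equals δ up to denominator contamination
from start/stop codons (≈ 0.3 %); `fourth_site_A_target` instead pins
the A-start probability at an absolute value, the mode that reproduces
GC-pressure resilience (a flat fourth-site slope against GC3 while the
codon baseline falls).  Optional couplings: SD-bearing CDSs get their
fourth-site A probability reduced by `sd_fourth_A_shift`; fourth-site-A
CDSs draw internal codons from a preferred-codon admixture
(`cai_coupling_w`); 20 CDSs are tagged with the ribosomal reference
names and drawn at `ref_gene_w = 0.9` preferred-codon weight so CAI is
estimable.  SD insertion writes a GGAGGT hexamer ending 7 nt upstream
of the start; leader insertion writes an 8–28-codon ORF into the
intergenic region; overlap insertion rewrites the upstream neighbour to
end ...N-TGA and starts the next CDS 4 nt inside it (table 11 only —
under table 4 TGA is not a stop and the configuration is rejected).
16S genes are 163-nt stubs ending in the canonical GATCACCTCCTTA tail.

Defaults are deliberately neutral: `fourth_site_A_excess = 1`,
`overlap_prob = 0`, no couplings — the null construction used for
type-I calibration.  The study cohort in `analysis/cohort.py` switches
on the effects (δ = 1.8 matching the reported cohort-mean ratio scale,
7.61 % overlaps, SD/leader insertion, a table-4 minority with δ reduced
by 0.4).

What the generator does **not** emulate: realistic intergenic
composition (hence leader/SD detection saturation and spurious-motif
attenuation, above), reverse-strand genes (the readers handle strand;
the generator does not exercise it), within-CDS codon autocorrelation,
amino-acid-level selection, or any dependence of downstream +1 stop
placement on the fourth site.  Passing tests therefore demonstrate
estimator correctness and calibrated error rates under controlled
conditions — not that real genomes behave this way.

## Problem sizes and reproducibility

Everything is seeded through `numpy.random.default_rng`; identical
config + seed gives byte-identical FASTA output.  The test suite uses
2000-CDS genomes for recovery checks (the injected δ = 1.8 is recovered
within ±0.1; at this size the ratio's Monte-Carlo sd is ≈ 0.04), 1000
replicate 200-CDS genomes for the 1 %-level type-I calibration of the
ratio test, 1000 random CDSs for the +1-scan oracle equivalence and 500
random regions for the leader-ORF oracle.  The analysis drivers use a
24-genome cohort of 400-CDS genomes across GC 0.30–0.70.  These sizes
are the package's own choices for routine runs; all are configurable.

## Known limitations

- The SD energy model omits dangling ends and intramolecular folding;
  it is a hybridization scan, not an RNA structure prediction.
- Loess is locally linear (degree 1), span 0.75.
- The ortholog resilience t-test is anticonservative by construction
  (see above).
- The AOD reading of the published formula, the CAI reference list
  expansion, and the inclusive-tail convention are documented choices
  where the original descriptions are ambiguous.
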