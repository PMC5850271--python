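"""Enrichment ratios, the ratio test, GC-variance profile and the GC3
slope contrast."""

import math

import numpy as np
import pytest

from fourthsite import site_stats
from fourthsite.site_stats import (
    cohort_ratios,
    enrichment_ratio,
    gc3_slope_contrast,
    gc_variance_profile,
    ratio_test,
    site_fractions,
    z_equivalence,
)
from fourthsite.syn_genomes import GeneratorConfig, generate_genome

from conftest import make_genome


# ---------------------------------------------------------------------------
# enrichment ratio on hand-enumerable toys
# ---------------------------------------------------------------------------

def test_ratio_balanced_toy_is_one():
    """f_A(4) = 2/4 and F_A(1) = 6/12 by direct enumeration of the 12
    codon first positions."""
    g = make_genome(["ATGAAATAA", "ATGCCCTAA", "ATGAGTTAA", "ATGGGGTAA"])
    r = enrichment_ratio(g, "A", 4)
    assert r.f == pytest.approx(0.5)
    assert r.F == pytest.approx(0.5)
    assert r.ratio == pytest.approx(1.0)


def test_ratio_identical_cds_toy():
    """'ATGAAATAA': f_A(4) = 1, F_A(1) = 2/3 (codons ATG, AAA, TAA),
    ratio 1.5 — start and stop codons are counted in the denominator."""
    g = make_genome(["ATGAAATAA"] * 5)
    r = enrichment_ratio(g, "A", 4)
    assert r.ratio == pytest.approx(1.5)


def test_site_fractions_sum_to_one(small_genome):
    genome, _ = small_genome
    for site in (4, 5, 6, 7):
        fr = site_fractions(genome, site)
        assert sum(fr.values()) == pytest.approx(1.0)


def test_ratio_invariant_to_duplication_and_order(small_genome):
    genome, _ = small_genome
    base = enrichment_ratio(genome, "A", 4).ratio
    doubled = make_genome([c.seq for c in genome.cds] + [c.seq for c in genome.cds])
    shuffled = make_genome([c.seq for c in reversed(genome.cds)])
    assert enrichment_ratio(doubled, "A", 4).ratio == pytest.approx(base)
    assert enrichment_ratio(shuffled, "A", 4).ratio == pytest.approx(base)


def test_exclude_terminal_codons_flag():
    g = make_genome(["ATGAAATAA"] * 3)
    r = enrichment_ratio(g, "A", 4, exclude_terminal_codons=True)
    # only the internal codon AAA remains in the denominator
    assert r.F == pytest.approx(1.0)
    assert r.ratio == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# ratio test
# ---------------------------------------------------------------------------

def test_ratio_test_null_is_zero():
    g = make_genome(["ATGAAATAA", "ATGCCCTAA", "ATGAGTTAA", "ATGGGGTAA"])
    r = ratio_test(enrichment_ratio(g, "A", 4), m=1)
    assert r.chi2 == pytest.approx(0.0)
    assert r.p_raw == pytest.approx(1.0)


def test_ratio_test_textbook_chi2():
    """Observed 60 of 100 against F = 0.5: chi2 = 100/50 + 100/50 = 4."""
    r = site_stats.EnrichmentResult(
        genome_id="t", site=4, nucleotide="A", f=0.6, F=0.5, ratio=1.2, n_cds=100
    )
    r = ratio_test(r, m=1)
    assert r.chi2 == pytest.approx(4.0)


def test_bonferroni_arithmetic():
    r = site_stats.EnrichmentResult(
        genome_id="t", site=4, nucleotide="A", f=0.6, F=0.5, ratio=1.2, n_cds=100
    )
    r = ratio_test(r, m=646)
    assert r.p_bonf == pytest.approx(min(1.0, 646 * r.p_raw))
    # correction arithmetic: p_raw 1e-5 over a 646-genome cohort stays
    # significant at 0.01
    assert min(1.0, 646 * 1e-5) == pytest.approx(6.46e-3)
    assert min(1.0, 646 * 1e-5) < 0.01


def test_undefined_ratio_sentinel():
    g = make_genome(["TTGTTTTAA"] * 4)  # no A at intracodon position 1
    with pytest.warns(UserWarning):
        r = enrichment_ratio(g, "A", 4)
    assert math.isnan(r.ratio)
    r = ratio_test(r, m=1)
    assert r.significant is None


def test_cohort_table_bonferroni_monotone(small_genome):
    genome, _ = small_genome
    t1 = cohort_ratios([genome], "A", (4,), m=1)
    t100 = cohort_ratios([genome], "A", (4,), m=100)
    assert t100.p_bonf.iloc[0] >= t1.p_bonf.iloc[0]


# ---------------------------------------------------------------------------
# GC variance profile
# ---------------------------------------------------------------------------

def test_gc_variance_identical_genomes_zero():
    g = make_genome(["ATGAAACCCGGGTTTAAACCCGGGTTTAAACCCGGGTTTAAACCCGGGTTTAAACCCGGGTTTAAACCCGGGTTTAAACCCGGGTTTAAACCCGGGTAA"])
    prof = gc_variance_profile([g, g, g], codons=range(2, 6))
    assert (prof.gc_variance == 0).all()


def test_gc_variance_hand_arithmetic():
    """Two genomes with site-4 GC proportions 0.2 and 0.4: population
    variance 0.01."""
    g1 = make_genome(["ATGGAAATTAAATAA"] * 1 + ["ATGAAAATTAAATAA"] * 4)  # GC4 = 0.2
    g2 = make_genome(["ATGGAAATTAAATAA"] * 2 + ["ATGAAAATTAAATAA"] * 3)  # GC4 = 0.4
    prof = gc_variance_profile([g1, g2], codons=[2])
    row = prof[(prof.codon == 2) & (prof.intracodon_position == 1)].iloc[0]
    assert row.gc_variance == pytest.approx(0.01)


def test_gc_variance_needs_two_genomes():
    g = make_genome(["ATGAAATAA"])
    with pytest.raises(ValueError):
        gc_variance_profile([g])


def test_no_positional_outlier_on_iid_cohort():
    """On i.i.d. synthetic genomes no position's variance should stand
    out beyond sampling scatter."""
    genomes = []
    for s in range(8):
        g, _ = generate_genome(
            GeneratorConfig(n_cds=250, seed=400 + s, sd_prob=0, leader_prob=0,
                            mean_cds_len_codons=100, min_cds_len_codons=40)
        )
        genomes.append(g)
    prof = gc_variance_profile(genomes, codons=range(2, 11))
    v = prof.gc_variance.to_numpy()
    assert v.max() < 10 * np.median(v)


# ---------------------------------------------------------------------------
# GC3 slope contrast
# ---------------------------------------------------------------------------

def test_z_equivalence_plugin_arithmetic():
    z, p = z_equivalence(-0.245, 0.005, -0.160, 0.008)
    assert abs(z) == pytest.approx(9.0, abs=0.05)
    assert p < 1e-15


def test_equal_slopes_give_zero_z():
    z, p = z_equivalence(-0.2, 0.01, -0.2, 0.01)
    assert z == 0.0
    assert p == pytest.approx(1.0)


def test_pinned_fourth_site_yields_slope_gap():
    """Fourth-site A pinned at 0.45 while the A-start codon fraction
    tracks GC: the all-codon slope must be significantly more negative."""
    genomes = []
    for i, gc in enumerate(np.linspace(0.3, 0.7, 14)):
        g, _ = generate_genome(
            GeneratorConfig(n_cds=400, gc_target=float(gc), seed=900 + i,
                            fourth_site_A_target=0.45, sd_prob=0, leader_prob=0,
                            mean_cds_len_codons=100, min_cds_len_codons=40)
        )
        genomes.append(g)
    out = gc3_slope_contrast(genomes)
    assert out["slope_all_codons"] < out["slope_fourth_site"]
    assert out["z"] > 3
    assert out["p"] < 0.01


def test_slope_contrast_needs_gc3_variance():
    g = make_genome(["ATGAAATAA"] * 3)
    with pytest.raises(ValueError):
        gc3_slope_contrast([g, g, g])
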