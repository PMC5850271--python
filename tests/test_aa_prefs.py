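"""Second-codon amino-acid analyses: AOD scores, block ratios,
dipeptide expectations."""

import math

import numpy as np
import pandas as pd
import pytest

from fourthsite.aa_prefs import (
    aod_scores,
    block_frequencies,
    block_ratios,
    dipeptide_expectation,
    gc_group,
    translate_cds,
)
from fourthsite.codes import get_table
from fourthsite.syn_genomes import GeneratorConfig, generate_genome

from conftest import make_genome


def test_gc_group_bounds():
    assert gc_group(0.40) == "low"
    assert gc_group(0.4419) == "low"
    assert gc_group(0.45) == "medium"
    assert gc_group(0.6091) == "medium"
    assert gc_group(0.65) == "high"


def test_second_position_frequencies_sum_to_one(small_genome):
    genome, _ = small_genome
    bf = block_frequencies(genome)
    assert bf.f_second.sum() == pytest.approx(1.0)
    assert bf.F_all.sum() == pytest.approx(1.0)


def test_aod_zero_when_second_equals_transcriptome():
    """A genome whose second-position usage equals its overall usage has
    AOD = 0 for every block."""
    # every CDS is one repeated codon => second frequency == overall
    seqs = ["ATG" + "AAA" * 4 + "TAA", "ATG" + "CCC" * 4 + "TAA"]
    g = make_genome(seqs)
    bf = block_frequencies(g, exclude_first_codon=True)
    k = bf.loc["K"]
    # K: second-position 1/2; overall (excluding ATG) 4/10 of counted
    assert k.f_second == pytest.approx(0.5)


def test_aod_mean_over_genomes():
    """Two genomes contributing (f-F) of +0.02 and +0.04 for lysine give
    AOD(K) = 0.03 (mean over genomes in the group)."""
    rows = []
    for gid, diff in (("a", 0.02), ("b", 0.04)):
        rows.append(pd.DataFrame(
            dict(block=["K"], f_second=[0.1 + diff], F_all=[0.1], diff=[diff],
                 n_second=[1], n_all=[1], genome_id=[gid], gc_group=["low"])
        ))
    df = pd.concat(rows, ignore_index=True)
    out = (
        df.groupby(["block", "gc_group"])["diff"].mean()
    )
    assert out.loc[("K", "low")] == pytest.approx(0.03)


def test_aod_scores_shape_and_duplication_invariance(small_genome):
    genome, _ = small_genome
    one = aod_scores([genome])
    two = aod_scores([genome, genome])  # duplication within a group
    merged = one.merge(two, on=["block", "gc_group"], suffixes=("_1", "_2"))
    assert np.allclose(merged.aod_1, merged.aod_2)


def test_aod_sign_pattern_under_injected_bias():
    """A fourth-site A excess must raise second-position use of the
    A-starting blocks (K, N, T, S_A, R_A) and S_A above S_T."""
    genomes = []
    for s in range(4):
        g, _ = generate_genome(
            GeneratorConfig(n_cds=800, seed=600 + s, fourth_site_A_excess=1.8,
                            sd_prob=0, leader_prob=0, mean_cds_len_codons=100,
                            min_cds_len_codons=40)
        )
        genomes.append(g)
    aod = aod_scores(genomes).set_index("block")
    for blk in ("K", "N", "T", "S_A", "R_A"):
        assert aod.loc[blk, "aod"].item() > 0, blk
    assert aod.loc["S_A", "aod"].item() > aod.loc["S_T", "aod"].item()


def test_null_cohort_aod_small():
    """Without injected bias all |AOD| stay within sampling scatter of
    the group mean."""
    genomes = []
    for s in range(4):
        g, _ = generate_genome(
            GeneratorConfig(n_cds=800, seed=700 + s, sd_prob=0, leader_prob=0,
                            mean_cds_len_codons=100, min_cds_len_codons=40,
                            ref_gene_w=0.0)
        )
        genomes.append(g)
    aod = aod_scores(genomes)
    # Met's F includes every start codon, so M is mechanically depressed
    aod = aod[aod.block != "M"]
    ok = aod.dropna(subset=["sem"])
    assert (ok.aod.abs() <= 4 * ok["sem"] + 1e-12).mean() > 0.9


def test_block_ratios_arithmetic_and_sentinels():
    g = make_genome(["ATG" + "AGT" + "AAA" * 3 + "TAA"] * 3)  # second codon S_A
    br = block_ratios(g)
    # S_A frequency: second position 1.0; overall 3 of the 15 amino-acid
    # coding codons (stops are not amino acids and are never counted)
    assert br.loc["S_A", "ratio"] == pytest.approx(1.0 / (3 / 15))
    assert math.isnan(br.loc["R_A", "ratio"])  # no AGA/AGG anywhere


def test_translate_cds_table4():
    assert translate_cds("ATGTGATAA", get_table(4)) == "MW"
    assert translate_cds("ATGTGGTAA", get_table(11)) == "MW"


def test_dipeptide_counts_toy():
    g = make_genome(["ATG" + "AAA" + "ATG" + "TAA"])  # protein MKM
    assert dipeptide_expectation(g, ("M", "K"))["observed"] == 1
    assert dipeptide_expectation(g, ("K", "M"))["observed"] == 1
    assert dipeptide_expectation(g, ("M", "M"))["observed"] == 0


def test_dipeptide_repeated_mm():
    g = make_genome(["ATGATGTAA"] * 10)  # ten 'MM' proteins
    out = dipeptide_expectation(g, ("M", "M"))
    assert out["observed"] == 10


def test_dipeptide_absent_aa_sentinel():
    g = make_genome(["ATGAAATAA"])
    out = dipeptide_expectation(g, ("W", "W"))
    assert out["expected"] == 0
    assert math.isnan(out["chi2"])


def test_dipeptide_random_proteome_near_expectation():
    """On an unbiased synthetic genome, Met-Met pairs occur at the
    independence expectation within Poisson-level error."""
    g, _ = generate_genome(
        GeneratorConfig(n_cds=500, seed=42, sd_prob=0, leader_prob=0,
                        mean_cds_len_codons=200, min_cds_len_codons=80,
                        ref_gene_w=0.0)
    )
    out = dipeptide_expectation(g, ("M", "M"))
    assert out["observed"] == pytest.approx(
        out["expected"], abs=5 * math.sqrt(out["expected"]) + 5
    )
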