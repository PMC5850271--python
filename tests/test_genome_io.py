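"""CDS filtering, leader ORFs, overlap screening, best hits, readers."""

import numpy as np
import pytest

from fourthsite import genome_io
from fourthsite.codes import get_table
from fourthsite.genome_io import (
    best_hits,
    filter_cds,
    find_leader,
    flag_4nt_overlaps,
    read_genome,
    start_codon_census,
)
from fourthsite.records import CodingSeq, GenomeRecord
from fourthsite.syn_genomes import GeneratorConfig, generate_genome, write_genome

from conftest import make_genome, random_filtered_cds

T11 = get_table(11)
T4 = get_table(4)


# ---------------------------------------------------------------------------
# filter_cds
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seq,table,kwargs,accept,reason", [
    ("ATGAGTTAA", T11, dict(require_ntg=True), True, None),
    ("ATGAGTTGA", T4, {}, False, "no_terminal_stop"),
    ("ATGTGACCCTAA", T11, {}, False, "internal_stop"),
    ("ATGAGTTA", T11, {}, False, "length_not_multiple_of_3"),
    ("ATGANTTAA", T11, {}, False, "non_canonical_nucleotide"),
    ("ATGAGRTAA", T11, {}, False, "non_canonical_nucleotide"),
    ("CTGAGTTAA", T11, dict(require_ntg=True), False, "not_ntg_start"),
    ("GTGAGTTAA", T11, dict(require_atg=True), False, "not_atg_start"),
    ("GTGAGTTAA", T11, dict(require_ntg=True), True, None),
    ("ATGTGAAGTTAA", T4, {}, True, None),  # TGA internal is Trp under table 4
])
def test_filter_cds_cases(seq, table, kwargs, accept, reason):
    ok, why = filter_cds(seq, table, **kwargs)
    assert ok is accept
    assert why == reason


def test_filter_idempotence(small_genome):
    genome, _ = small_genome
    once = genome_io.apply_filters(genome)
    twice = genome_io.apply_filters(once)
    assert [c.id for c in once.cds] == [c.id for c in twice.cds]


def test_accepted_cds_recheck_independently(rng):
    """Property: every accepted random string satisfies all four criteria
    when re-verified with independent string operations."""
    alphabet = np.array(list("ACGTN"))
    stops = ("TAA", "TAG", "TGA")
    n_accepted = 0
    for k in range(3000):
        L = int(rng.integers(3, 31))
        p = [0.24, 0.24, 0.24, 0.24, 0.04]
        seq = "".join(alphabet[rng.choice(5, size=L, p=p)])
        if k % 2:  # half the draws get a plausible terminus
            seq = seq[: max(0, L - L % 3 - 3)] + stops[k % 3]
        ok, _ = filter_cds(seq, T11)
        if not ok:
            continue
        n_accepted += 1
        assert len(seq) % 3 == 0
        assert set(seq) <= set("ACGT")
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        assert codons[-1] in {"TAA", "TAG", "TGA"}
        assert not any(c in {"TAA", "TAG", "TGA"} for c in codons[:-1])
    # the generator makes ~ACGT-only short strings, some must be accepted
    assert n_accepted > 10


# ---------------------------------------------------------------------------
# start codon census
# ---------------------------------------------------------------------------

def test_start_codon_census_toy():
    g = make_genome(["ATGAAATAA", "ATGCCCTAA", "GTGAAATAA"])
    freqs, ntg = start_codon_census(g)
    assert freqs == {"ATG": pytest.approx(2 / 3), "GTG": pytest.approx(1 / 3)}
    assert ntg == 1.0


def test_start_codon_census_empty_errors():
    with pytest.raises(ValueError):
        start_codon_census(make_genome([]))


# ---------------------------------------------------------------------------
# leader ORFs
# ---------------------------------------------------------------------------

def _brute_force_leaders(region, table):
    """Exhaustive enumeration of all qualifying ORFs (criteria checked
    one by one, independent of the scanning implementation)."""
    out = []
    n = len(region)
    for start in range(n):
        for end in range(start + 3, n + 1, 3):
            orf = region[start:end]
            if len(orf) % 3 != 0 or len(orf) // 3 < 7:
                continue
            if orf[:3] not in {"ATG", "GTG", "TTG"}:
                continue
            codons = [orf[i:i + 3] for i in range(0, len(orf), 3)]
            if codons[-1] not in table.stops:
                continue
            if any(c in table.stops for c in codons[:-1]):
                continue
            out.append((orf, start))
    return out


def test_find_leader_minimal_orf():
    region = "CC" + "ATG" + "AAA" * 5 + "TAA" + "GG"  # 7 codons total
    got = find_leader(region, T11)
    assert got == ("ATG" + "AAA" * 5 + "TAA", 2)


def test_find_leader_too_short_rejected():
    assert find_leader("ATGAAATAA", T11) is None  # 3 codons


def test_find_leader_prefers_longest():
    short = "ATG" + "CCC" * 5 + "TAG"           # 7 codons
    long = "GTG" + "AAA" * 8 + "TAA"            # 10 codons
    region = "TT" + short + "CC" + long + "AA"
    orf, off = find_leader(region, T11)
    assert orf == long


def test_find_leader_rejects_bad_alphabet():
    with pytest.raises(ValueError):
        find_leader("ATGNNNTAA", T11)


def test_find_leader_matches_brute_force(rng):
    """The scanner equals exhaustive ORF enumeration on 500 random
    intergenic regions."""
    alphabet = np.array(list("ACGT"))
    for _ in range(500):
        L = int(rng.integers(30, 220))
        region = "".join(alphabet[rng.integers(0, 4, size=L)])
        expected = _brute_force_leaders(region, T11)
        got = find_leader(region, T11)
        if not expected:
            assert got is None
        else:
            best_len = max(len(o) for o, _ in expected)
            candidates = [(o, s) for o, s in expected if len(o) == best_len]
            assert got in candidates
            assert len(got[0]) == best_len


# ---------------------------------------------------------------------------
# 4-nt overlaps
# ---------------------------------------------------------------------------

def _coords_genome(entries):
    cds = [
        CodingSeq(id=f"c{i}", seq=seq, coords=coords, passed_filter=True)
        for i, (seq, coords) in enumerate(entries)
    ]
    return GenomeRecord(genome_id="toy", table=T11, cds=cds)


def test_overlap_flagged_only_at_exactly_4nt_and_tga():
    up = "ATG" + "AAA" * 3 + "TGA"      # ends at 15
    down = "ATGAAATAA"
    g = _coords_genome([
        (up, (1, 15, "+")),
        (down, (12, 20, "+")),          # overlap 4
    ])
    assert flag_4nt_overlaps(g) == {"c1"}

    g1 = _coords_genome([
        (up, (1, 15, "+")),
        (down, (15, 23, "+")),          # overlap 1
    ])
    assert flag_4nt_overlaps(g1) == set()

    up_taa = "ATG" + "AAA" * 3 + "TAA"  # TAA stop: not flagged
    g2 = _coords_genome([
        (up_taa, (1, 15, "+")),
        (down, (12, 20, "+")),
    ])
    assert flag_4nt_overlaps(g2) == set()


def test_overlap_synthetic_truth_agreement():
    g, truth = generate_genome(
        GeneratorConfig(n_cds=1000, overlap_prob=0.1, seed=21, sd_prob=0,
                        leader_prob=0)
    )
    flagged = flag_4nt_overlaps(g)
    truth_set = {k for k, v in truth.per_cds_labels.items() if v["has_overlap"]}
    assert flagged == truth_set
    assert abs(len(flagged) / g.n_cds - 0.1) < 0.03


def test_overlap_without_coordinates_warns():
    g = make_genome(["ATGAAATAA"])
    with pytest.warns(UserWarning):
        assert flag_4nt_overlaps(g) == set()


# ---------------------------------------------------------------------------
# best hits
# ---------------------------------------------------------------------------

def test_best_hits_selection_rules():
    rows = [
        ("q1", "s_weak", 90.0, 1e-10),
        ("q1", "s_strong", 85.0, 1e-50),
        ("q2", "s_only", 99.0, 1e-5),
        ("q3", "s_lowid", 91.0, 1e-30),
        ("q3", "s_highid", 98.0, 1e-30),   # E tie -> higher identity
        ("q4", "s_b", 95.0, 1e-20),
        ("q4", "s_a", 95.0, 1e-20),        # full tie -> lexicographic
    ]
    hits = best_hits(rows)
    assert hits == {
        "q1": "s_strong", "q2": "s_only", "q3": "s_highid", "q4": "s_a",
    }


def test_best_hits_skips_malformed_rows():
    rows = [("q1", "s1", 90.0, 1e-10), ("q1", "s2", "bad", "xx")]
    with pytest.warns(UserWarning):
        hits = best_hits(rows)
    assert hits == {"q1": "s1"}


def test_best_hits_outfmt6_file(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text(
        "q1\ts1\t98.0\t300\t5\t0\t1\t300\t1\t300\t1e-40\t500\n"
        "q1\ts2\t99.0\t300\t2\t0\t1\t300\t1\t300\t1e-60\t550\n"
    )
    assert best_hits(p) == {"q1": "s2"}


# ---------------------------------------------------------------------------
# round trip through files
# ---------------------------------------------------------------------------

def test_write_read_round_trip(tmp_path):
    cfg = GeneratorConfig(n_cds=80, seed=17, sd_prob=0.5, leader_prob=0.3,
                          overlap_prob=0.05)
    g, truth = generate_genome(cfg)
    paths = write_genome(g, truth, tmp_path)
    back = read_genome(paths["genome_fasta"], paths["gff3"], table_id=11)
    assert back.n_cds == g.n_cds
    assert {c.id for c in back.cds} == {c.id for c in g.cds}
    orig = {c.id: c.seq for c in g.cds}
    for c in back.cds:
        assert c.seq == orig[c.id]
    # intergenic context is recovered where present
    for c in g.cds:
        if g.intergenic.get(c.id):
            assert back.intergenic[c.id].endswith(g.intergenic[c.id][-50:])
    # rRNA stubs recovered
    assert back.rrna_16s == g.rrna_16s
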