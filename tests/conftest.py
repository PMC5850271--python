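import numpy as np
import pytest

from fourthsite.codes import get_table
from fourthsite.records import CodingSeq, GenomeRecord
from fourthsite.syn_genomes import GeneratorConfig, generate_genome


def make_genome(seqs, table_id=11, genome_id="toy", **cds_kwargs):
    """GenomeRecord from bare CDS strings (no coordinates)."""
    cds = [
        CodingSeq(id=f"cds_{i}", seq=s, passed_filter=True, ntg_start=True,
                  **cds_kwargs)
        for i, s in enumerate(seqs)
    ]
    return GenomeRecord(genome_id=genome_id, table=get_table(table_id), cds=cds)


def random_filtered_cds(rng, table, n_codons=None):
    """One random CDS guaranteed to pass the filters (NTG start, sense
    internals, legal stop)."""
    sense = table.sense_codons
    n = n_codons or int(rng.integers(10, 60))
    start = ("ATG", "GTG", "TTG")[int(rng.integers(3))]
    body = "".join(sense[i] for i in rng.integers(0, len(sense), size=n))
    stop = sorted(table.stops)[int(rng.integers(len(table.stops)))]
    return start + body + stop


@pytest.fixture(scope="session")
def null_genome():
    """2000 CDSs, no injected fourth-site bias, a single codon-usage
    table for every internal codon."""
    cfg = GeneratorConfig(
        n_cds=2000, seed=11, fourth_site_A_excess=1.0, overlap_prob=0.0,
        sd_prob=0.0, leader_prob=0.0, ref_gene_w=0.0,
    )
    return generate_genome(cfg)


@pytest.fixture(scope="session")
def biased_genome():
    """2000 CDSs with a 1.8-fold fourth-site A excess injected."""
    cfg = GeneratorConfig(
        n_cds=2000, seed=11, fourth_site_A_excess=1.8, overlap_prob=0.0,
        sd_prob=0.0, leader_prob=0.0, ref_gene_w=0.0,
    )
    return generate_genome(cfg)


@pytest.fixture(scope="session")
def small_genome():
    """300 CDSs with SD hexamers, leaders and overlaps present."""
    cfg = GeneratorConfig(
        n_cds=300, seed=3, sd_prob=0.5, leader_prob=0.2, overlap_prob=0.05,
    )
    return generate_genome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
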