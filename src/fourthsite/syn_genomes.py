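"""Synthetic bacterial genomes with controllable fourth-site structure.

The generator emits genomes as filtered CDS collections embedded in a
linear genome sequence, with the statistical handles the downstream
analyses estimate: overall GC content, a codon-usage table, a
multiplicative excess of A-starting second codons, the translation
table (11 or 4), the NTG start-codon mix, upstream Shine-Dalgarno
hexamers, leader ORFs in intergenic regions, and 4-nt ATGA-style
overlaps with an upstream TGA-terminated CDS.  A truth record preserves
every per-CDS label so parameter-recovery tests can compare estimates
against what was injected.

No claim of biological realism is made beyond these controlled
marginals: codons are drawn i.i.d. within a CDS, intergenic sequence is
i.i.d. nucleotides, and 16S genes are short stubs carrying a canonical
anti-SD tail.  See docs/methods.md for what this does and does not
emulate.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .cai import DEFAULT_REFERENCE_GENES
from .codes import get_table, NTG_STARTS
from .records import CodingSeq, GenomeRecord

#: NTG start-codon mix; the ATG/GTG/TTG shares reported across bacterial
#: genomes (80.97/13.02/5.72 % of all CDSs), renormalised within NTG.
DEFAULT_START_PROBS = {"ATG": 0.80970, "GTG": 0.13020, "TTG": 0.05720}
_s = sum(DEFAULT_START_PROBS.values())
DEFAULT_START_PROBS = {k: v / _s for k, v in DEFAULT_START_PROBS.items()}

SD_HEXAMER = "GGAGGT"  # strong-binding exemplar written upstream of SD CDSs
#: 3' end of the 16S stub; its last GAT motif starts the 13-nt anti-SD tail
CANONICAL_16S_TAIL = "GATCACCTCCTTA"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic genome.

    ``fourth_site_A_excess`` is the multiplicative factor delta applied to
    the probability that the second codon starts with A; the non-A mass is
    rescaled so the injected Eq.-1-style ratio equals delta.
    ``fourth_site_A_target``, when set, pins the A-start probability of the
    second codon at an absolute value instead (used to emulate
    GC-independent fourth-site maintenance).
    """

    n_cds: int = 1000
    gc_target: float = 0.5
    codon_usage: Optional[dict] = None  # sense codon -> probability
    fourth_site_A_excess: float = 1.0
    fourth_site_A_target: Optional[float] = None
    translation_table: int = 11
    start_codon_probs: dict = field(default_factory=lambda: dict(DEFAULT_START_PROBS))
    sd_prob: float = 0.7
    leader_prob: float = 0.15
    overlap_prob: float = 0.0
    mean_cds_len_codons: int = 300
    min_cds_len_codons: int = 70
    sd_fourth_A_shift: float = 0.0  # subtracted from the A-start prob of SD CDSs
    cai_coupling_w: float = 0.0  # preferred-codon weight of fourth-site-A CDSs
    ref_gene_w: float = 0.9  # preferred-codon weight of the ribosomal reference set
    n_rrna: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cds < 1:
            raise ConfigurationError("n_cds must be >= 1")
        if self.translation_table not in (11, 4):
            raise ConfigurationError("translation_table must be 11 or 4")
        for name in ("gc_target", "sd_prob", "leader_prob", "overlap_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.fourth_site_A_excess < 0:
            raise ConfigurationError("fourth_site_A_excess must be >= 0")
        if self.fourth_site_A_target is not None and not (
            0.0 <= self.fourth_site_A_target <= 1.0
        ):
            raise ConfigurationError("fourth_site_A_target outside [0, 1]")
        ps = np.array(list(self.start_codon_probs.values()), dtype=float)
        if (ps < 0).any() or abs(ps.sum() - 1.0) > 1e-9:
            raise ConfigurationError("start_codon_probs must be a distribution")
        if not set(self.start_codon_probs) <= NTG_STARTS:
            raise ConfigurationError("start codons must be ATG/GTG/TTG")
        if self.translation_table == 4 and self.overlap_prob > 0:
            raise ConfigurationError(
                "4-nt TGA overlaps are impossible under table 4 (TGA is Trp)"
            )
        if self.codon_usage is not None:
            table = get_table(self.translation_table)
            if set(self.codon_usage) != set(table.sense_codons):
                raise ConfigurationError(
                    "codon_usage must cover exactly the table's sense codons"
                )
            tot = sum(self.codon_usage.values())
            if abs(tot - 1.0) > 1e-9 or min(self.codon_usage.values()) < 0:
                raise ConfigurationError("codon_usage must sum to 1")


@dataclass
class SyntheticTruth:
    config: GeneratorConfig
    realized_fourth_site_A_fraction: float
    realized_gc: float
    per_cds_labels: dict  # cds id -> {"has_sd","has_leader","has_overlap"}
    anti_sd_tail: str = CANONICAL_16S_TAIL


# ---------------------------------------------------------------------------
# codon usage
# ---------------------------------------------------------------------------

def codon_usage_from_gc(gc_target: float, table_id: int = 11) -> dict:
    """Sense-codon distribution with independent per-position base
    composition, calibrated so the expected GC of a drawn codon equals
    ``gc_target`` (stop exclusion otherwise skews it)."""
    table = get_table(table_id)
    sense = table.sense_codons
    gc_counts = np.array([sum(nt in "GC" for nt in c) for c in sense], dtype=float)

    def dist(g: float) -> np.ndarray:
        p_nt = {"G": g / 2, "C": g / 2, "A": (1 - g) / 2, "T": (1 - g) / 2}
        w = np.array([p_nt[c[0]] * p_nt[c[1]] * p_nt[c[2]] for c in sense])
        return w / w.sum()

    def excess(g: float) -> float:
        p = dist(g)
        return float(p @ gc_counts) / 3.0 - gc_target

    if gc_target <= 0.0 or gc_target >= 1.0:
        raise ConfigurationError("gc_target must be strictly inside (0, 1)")
    g = brentq(excess, 1e-6, 1 - 1e-6, xtol=1e-12)
    p = dist(g)
    return dict(zip(sense, p.tolist()))


def _preferred_usage(base: dict, table_id: int) -> dict:
    """Concentrate each synonymous family on its most frequent codon;
    stands in for a translationally optimal codon repertoire."""
    table = get_table(table_id)
    pref = {c: 0.0 for c in base}
    for aa, codons in table.synonymous_families().items():
        best = max(codons, key=lambda c: (base[c], c))
        pref[best] = sum(base[c] for c in codons)
    return pref


def _mix(base: dict, pref: dict, w: float) -> dict:
    return {c: (1 - w) * base[c] + w * pref[c] for c in base}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_codons(rng, codons, probs, size):
    idx = rng.choice(len(codons), size=size, p=probs)
    return [codons[i] for i in idx]


def _iid_dna(rng, length: int, gc: float) -> str:
    p = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    return "".join(np.array(["G", "C", "A", "T"])[rng.choice(4, size=length, p=p)])


def _leader_orf(rng, codons, probs, table) -> str:
    n_internal = int(rng.integers(6, 26))  # total 8..28 codons, comfortably >6
    body = "".join(_draw_codons(rng, codons, probs, n_internal))
    stop = table.stops_sorted[int(rng.integers(len(table.stops_sorted)))]
    return "ATG" + body + stop


def generate_genome(config: GeneratorConfig, genome_id: str = "synthetic"):
    """Generate one genome; returns ``(GenomeRecord, SyntheticTruth)``.

    Every emitted CDS is a multiple of three, ACGT-only, free of internal
    stops under the configured table, NTG-started and closed by a legal
    stop, so the whole set passes the CDS filters unchanged.
    """
    table = get_table(config.translation_table)
    # sorted stop list cached on the table object for stable draws
    if not hasattr(table, "stops_sorted"):
        object.__setattr__(table, "stops_sorted", tuple(sorted(table.stops)))
    rng = np.random.default_rng(config.seed)

    base = config.codon_usage or codon_usage_from_gc(
        config.gc_target, config.translation_table
    )
    sense = tuple(sorted(base))
    p_base = np.array([base[c] for c in sense])
    p_base = p_base / p_base.sum()
    base = dict(zip(sense, p_base.tolist()))

    pref = _preferred_usage(base, config.translation_table)
    ref_usage = _mix(base, pref, config.ref_gene_w)
    coupled_usage = _mix(base, pref, config.cai_coupling_w)
    p_ref = np.array([ref_usage[c] for c in sense])
    p_coupled = np.array([coupled_usage[c] for c in sense])

    a_mask = np.array([c[0] == "A" for c in sense])
    p_a = float(p_base[a_mask].sum())
    # second-codon conditionals
    p_second_a = np.where(a_mask, p_base, 0.0)
    p_second_a /= p_second_a.sum()
    p_second_not = np.where(a_mask, 0.0, p_base)
    p_second_not /= p_second_not.sum()

    if config.fourth_site_A_target is not None:
        q0 = config.fourth_site_A_target
    else:
        q0 = config.fourth_site_A_excess * p_a
    if q0 > 1.0:
        raise ConfigurationError(
            f"fourth-site A excess {config.fourth_site_A_excess} infeasible: "
            f"delta * P(A-start)={q0:.3f} > 1"
        )

    n = config.n_cds
    has_sd = rng.random(n) < config.sd_prob
    has_leader = rng.random(n) < config.leader_prob
    has_overlap = rng.random(n) < config.overlap_prob
    has_overlap[0] = False

    q = np.clip(q0 - config.sd_fourth_A_shift * has_sd, 0.0, 1.0)
    second_is_a = rng.random(n) < q

    starts_list = sorted(config.start_codon_probs)
    p_starts = np.array([config.start_codon_probs[s] for s in starts_list])
    start_idx = rng.choice(len(starts_list), size=n, p=p_starts)

    lens = config.min_cds_len_codons + rng.gamma(
        2.0, (config.mean_cds_len_codons - config.min_cds_len_codons) / 2.0, size=n
    ).astype(int)

    # reference (ribosomal) genes: 20 CDSs tagged with the rpl/rps names
    ref_ids = {}
    if n >= len(DEFAULT_REFERENCE_GENES) * 2:
        chosen = rng.choice(n, size=len(DEFAULT_REFERENCE_GENES), replace=False)
        ref_ids = {int(i): DEFAULT_REFERENCE_GENES[k] for k, i in enumerate(chosen)}

    # codons ending A/G/T (legal third bases shared with a following NTG start)
    agt_mask = np.array([c[2] in "AGT" for c in sense])
    p_agt = np.where(agt_mask, p_base, 0.0)
    p_agt /= p_agt.sum()

    cds_list: list[CodingSeq] = []
    intergenic: dict[str, str] = {}
    labels: dict[str, dict] = {}
    genome_parts: list[str] = []
    gff_rows: list[tuple] = []
    cur_end = 0  # 1-based end of assembled genome sequence

    # 16S stubs up front, spaced by neutral sequence
    rrna_16s = []
    for r in range(config.n_rrna):
        stub = _iid_dna(rng, 150, config.gc_target) + CANONICAL_16S_TAIL
        spacer = _iid_dna(rng, 120, config.gc_target)
        genome_parts.append(spacer)
        cur_end += len(spacer)
        start = cur_end + 1
        genome_parts.append(stub)
        cur_end += len(stub)
        gff_rows.append(("rRNA", start, cur_end, f"rrna16s_{r}", "16S ribosomal RNA"))
        rrna_16s.append(stub)

    stops_sorted = table.stops_sorted
    for i in range(n):
        cid = f"cds_{i}"
        gene_name = ref_ids.get(i)
        if gene_name is not None:
            p_internal = p_ref
        elif second_is_a[i] and config.cai_coupling_w > 0:
            p_internal = p_coupled
        else:
            p_internal = p_base

        internal = _draw_codons(rng, sense, p_internal, int(lens[i]))
        if second_is_a[i] or has_overlap[i]:
            second = sense[int(rng.choice(len(sense), p=p_second_a))]
        else:
            second = sense[int(rng.choice(len(sense), p=p_second_not))]

        overlap = bool(has_overlap[i]) and i > 0
        if overlap:
            # rewrite upstream neighbourhood: previous CDS must end
            # <sense codon ending A/G/T> TGA and we start 4 nt inside it
            prev = cds_list[-1]
            prev_last = sense[int(rng.choice(len(sense), p=p_agt))]
            new_prev_seq = prev.seq[:-6] + prev_last + "TGA"
            delta_tail = new_prev_seq[-6:]
            genome_parts[-1] = genome_parts[-1][: -6] + delta_tail
            prev.seq = new_prev_seq
            start_codon = prev_last[2] + "TG"
        else:
            start_codon = starts_list[int(start_idx[i])]

        stop = stops_sorted[int(rng.integers(len(stops_sorted)))]
        seq = start_codon + second + "".join(internal) + stop

        if overlap:
            cds_start = cur_end - 3
            genome_parts.append(seq[4:])
            cur_end += len(seq) - 4
            intergenic[cid] = ""
        else:
            u_len = int(rng.integers(101, 1400))
            u = _iid_dna(rng, u_len, config.gc_target)
            if has_leader[i]:
                orf = _leader_orf(rng, sense, p_base, table)
                max_off = u_len - len(orf) - 40
                if max_off < 1:
                    pad = _iid_dna(rng, len(orf) + 41 - u_len, config.gc_target)
                    u = pad + u
                    u_len = len(u)
                    max_off = u_len - len(orf) - 40
                off = int(rng.integers(0, max_off))
                u = u[:off] + orf + u[off + len(orf):]
                gff_rows.append(
                    ("leader", cur_end + 1 + off, cur_end + off + len(orf), f"leader_{i}", None)
                )
            if has_sd[i]:
                u = u[: u_len - 12] + SD_HEXAMER + u[u_len - 6:]
            genome_parts.append(u)
            cur_end += u_len
            cds_start = cur_end + 1
            genome_parts.append(seq)
            cur_end += len(seq)
            intergenic[cid] = u

        cds = CodingSeq(
            id=cid,
            seq=seq,
            gene_name=gene_name,
            coords=(cds_start, cds_start + len(seq) - 1, "+"),
            passed_filter=True,
            ntg_start=True,
            has_sd=bool(has_sd[i]),
            has_leader=bool(has_leader[i]),
            has_4nt_overlap=overlap,
        )
        gff_rows.append(("CDS", cds_start, cds_start + len(seq) - 1, cid, gene_name))
        cds_list.append(cds)
        labels[cid] = {
            "has_sd": bool(has_sd[i]),
            "has_leader": bool(has_leader[i]),
            "has_overlap": overlap,
        }

    genome = GenomeRecord(
        genome_id=genome_id,
        table=table,
        cds=cds_list,
        rrna_16s=rrna_16s,
        intergenic=intergenic,
    )
    genome._sequence = "".join(genome_parts)  # full assembled genome
    genome._gff_rows = gff_rows
    truth = SyntheticTruth(
        config=config,
        realized_fourth_site_A_fraction=float(
            np.mean([c.fourth_nt == "A" for c in cds_list])
        ),
        realized_gc=genome.gc,
        per_cds_labels=labels,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# ortholog pairs
# ---------------------------------------------------------------------------

_NT = np.array(list("ACGT"))
_NT_IDX = {c: k for k, c in enumerate("ACGT")}


def generate_ortholog_pairs(
    genome: GenomeRecord,
    sub_rate: float,
    fourth_site_rate: float,
    seed: int,
):
    """One mutated comparator per focal CDS.

    Substitutions are drawn per site at ``sub_rate`` (uniform over the
    three alternative nucleotides), except CDS site 4 which uses
    ``fourth_site_rate``; the start and stop codons are exempt so the
    comparator keeps an NTG start and a legal terminus.
    """
    if not 0 <= sub_rate <= 1 or not 0 <= fourth_site_rate <= 1:
        raise ValueError("substitution rates must lie in [0, 1]")
    if genome.n_cds == 0:
        raise ValueError("empty genome")
    rng = np.random.default_rng(seed)
    pairs = []
    for c in genome.cds:
        arr = np.array([_NT_IDX[nt] for nt in c.seq], dtype=np.int8)
        rates = np.full(len(arr), sub_rate)
        rates[:3] = 0.0
        rates[-3:] = 0.0
        if len(arr) > 3:
            rates[3] = fourth_site_rate
        hit = rng.random(len(arr)) < rates
        shift = rng.integers(1, 4, size=len(arr))
        arr = np.where(hit, (arr + shift) % 4, arr).astype(np.int8)
        comp_seq = "".join(_NT[arr])
        comp = CodingSeq(id=c.id + "_ortholog", seq=comp_seq)
        pairs.append((c, comp))
    return pairs


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def generate_cohort(
    n_genomes: int,
    seed: int,
    gc_range: tuple = (0.3, 0.7),
    table4_every: int = 0,
    table4_excess_penalty: float = 0.0,
    **config_overrides,
):
    """A cohort of genomes along an even GC gradient.

    ``table4_every`` > 0 switches every k-th genome to translation table 4;
    such genomes have their fourth-site excess reduced by
    ``table4_excess_penalty`` (the relaxed-selection scenario).
    Returns a list of ``(GenomeRecord, SyntheticTruth)``.
    """
    gcs = np.linspace(gc_range[0], gc_range[1], n_genomes)
    out = []
    for i, gc in enumerate(gcs):
        is_t4 = table4_every > 0 and i % table4_every == table4_every - 1
        overrides = dict(config_overrides)
        if is_t4:
            overrides["translation_table"] = 4
            overrides["overlap_prob"] = 0.0
            delta = overrides.get("fourth_site_A_excess", 1.0)
            overrides["fourth_site_A_excess"] = max(
                0.0, delta - table4_excess_penalty
            )
        cfg = GeneratorConfig(gc_target=float(gc), seed=seed + i, **overrides)
        out.append(generate_genome(cfg, genome_id=f"g{i:03d}_t{cfg.translation_table}"))
    return out


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def write_genome(genome: GenomeRecord, truth: SyntheticTruth, outdir) -> dict:
    """Write the genome as text artifacts.

    Emits ``cds.fasta`` (one record per CDS), ``genome.fasta`` (assembled
    sequence), ``features.gff3`` (CDS, rRNA and leader features, 1-based
    inclusive, + strand), ``truth.tsv`` and ``config.txt`` (flat
    key=value).  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    lines = []
    for c in genome.cds:
        lines.append(f">{c.id}\n{c.seq}\n")
    paths["cds_fasta"] = outdir / "cds.fasta"
    paths["cds_fasta"].write_text("".join(lines))

    paths["genome_fasta"] = outdir / "genome.fasta"
    paths["genome_fasta"].write_text(
        f">{genome.genome_id}\n{getattr(genome, '_sequence', '')}\n"
    )

    gff = ["##gff-version 3\n"]
    for ftype, start, end, fid, gene in getattr(genome, "_gff_rows", []):
        attrs = f"ID={fid}"
        if gene:
            attrs += f";gene={gene}"
        if ftype == "rRNA":
            attrs += ";product=16S ribosomal RNA"
        gff.append(
            f"{genome.genome_id}\tfourthsite\t{ftype}\t{start}\t{end}\t.\t+\t"
            f"{0 if ftype == 'CDS' else '.'}\t{attrs}\n"
        )
    paths["gff3"] = outdir / "features.gff3"
    paths["gff3"].write_text("".join(gff))

    rows = ["# fourthsite v0.1\ncds_id\thas_sd\thas_leader\thas_overlap\tfourth_nt\n"]
    for c in genome.cds:
        lab = truth.per_cds_labels[c.id]
        rows.append(
            f"{c.id}\t{int(lab['has_sd'])}\t{int(lab['has_leader'])}\t"
            f"{int(lab['has_overlap'])}\t{c.fourth_nt}\n"
        )
    paths["truth"] = outdir / "truth.tsv"
    paths["truth"].write_text("".join(rows))

    cfg_lines = []
    for f in dataclasses.fields(truth.config):
        v = getattr(truth.config, f.name)
        if isinstance(v, dict):
            v = ",".join(f"{k}:{x}" for k, x in sorted(v.items()))
        cfg_lines.append(f"{f.name}={v}\n")
    paths["config"] = outdir / "config.txt"
    paths["config"].write_text("".join(cfg_lines))
    return paths
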