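"""Genome reading, CDS filtering and annotation-level screens.

Filtering admits a CDS iff it (i) has length a multiple of three,
(ii) contains only canonical A/C/G/T, (iii) has no internal stop codon
under the genome's translation table, and (iv) terminates in a legal
stop of that table; analyses additionally restrict to NTG starts
(ATG/GTG/TTG).  Site numbering is 1-based from the first nucleotide of
the start codon.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO

from .codes import TranslationTable, get_table, iter_codons
from .records import CodingSeq, GenomeRecord

logger = logging.getLogger(__name__)

_CANONICAL = frozenset("ACGT")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_cds(
    seq: str,
    table: TranslationTable,
    require_ntg: bool = False,
    require_atg: bool = False,
) -> tuple[bool, Optional[str]]:
    """Classify one CDS; returns ``(accepted, reason)`` where ``reason``
    names the first failed criterion (or None on acceptance).

    ``require_atg`` is the stricter eukaryote-style start restriction and
    implies ``require_ntg``.
    """
    if not seq:
        raise ValueError("empty sequence")
    if isinstance(table, int):
        table = get_table(table)
    if len(seq) % 3 != 0:
        return False, "length_not_multiple_of_3"
    if not _CANONICAL.issuperset(seq):
        return False, "non_canonical_nucleotide"
    codons = list(iter_codons(seq))
    for codon in codons[:-1]:
        if table.is_stop(codon):
            return False, "internal_stop"
    if not table.is_stop(codons[-1]):
        return False, "no_terminal_stop"
    if require_atg and codons[0] != "ATG":
        return False, "not_atg_start"
    if require_ntg and codons[0] not in table.start_codons:
        return False, "not_ntg_start"
    return True, None


def apply_filters(
    genome: GenomeRecord, require_ntg: bool = True, require_atg: bool = False
) -> GenomeRecord:
    """New GenomeRecord holding only the CDSs passing ``filter_cds``;
    flags are set on the retained records."""
    kept = []
    for c in genome.cds:
        ok, _ = filter_cds(c.seq, genome.table, require_ntg, require_atg)
        if ok:
            c.passed_filter = True
            c.ntg_start = c.start_codon in genome.table.start_codons
            kept.append(c)
    out = GenomeRecord(
        genome_id=genome.genome_id,
        table=genome.table,
        cds=kept,
        rrna_16s=list(genome.rrna_16s),
        intergenic={c.id: genome.intergenic.get(c.id, "") for c in kept},
    )
    return out


# ---------------------------------------------------------------------------
# start codons
# ---------------------------------------------------------------------------

def start_codon_census(genome: GenomeRecord) -> tuple[dict, float]:
    """Frequency table over observed start codons and the NTG fraction."""
    if genome.n_cds == 0:
        raise ValueError("empty genome")
    counts = Counter(c.start_codon for c in genome.cds)
    total = sum(counts.values())
    freqs = {k: v / total for k, v in sorted(counts.items())}
    ntg = sum(v for k, v in counts.items() if k in genome.table.start_codons) / total
    return freqs, ntg


# ---------------------------------------------------------------------------
# leader ORFs
# ---------------------------------------------------------------------------

MIN_LEADER_CODONS = 7  # "longer than six codons"


def find_leader(
    intergenic: str, table: TranslationTable
) -> Optional[tuple[str, int]]:
    """Longest qualifying ORF in an upstream intergenic region.

    An ORF qualifies iff it starts with a regular NTG codon, is a
    multiple of three, has no internal stop, ends in a legal stop and is
    at least ``MIN_LEADER_CODONS`` codons long.  Returns ``(orf, offset)``
    (0-based offset into the region) or None.  Ties on length keep the
    most 5' ORF.
    """
    if isinstance(table, int):
        table = get_table(table)
    if not _CANONICAL.issuperset(intergenic):
        raise ValueError("non-ACGT characters in intergenic region")
    best: Optional[tuple[str, int]] = None
    n = len(intergenic)
    for off in range(n - 2):
        if intergenic[off : off + 3] not in table.start_codons:
            continue
        # extend in-frame until the first stop
        for j in range(off + 3, n - 2, 3):
            codon = intergenic[j : j + 3]
            if table.is_stop(codon):
                orf = intergenic[off : j + 3]
                if len(orf) // 3 >= MIN_LEADER_CODONS and (
                    best is None or len(orf) > len(best[0])
                ):
                    best = (orf, off)
                break
    return best


# ---------------------------------------------------------------------------
# 4-nt overlaps
# ---------------------------------------------------------------------------

def flag_4nt_overlaps(
    genome: GenomeRecord, include_opposite_strand: bool = False
) -> set:
    """CDS ids whose start lies exactly 4 nt inside an upstream
    TGA-terminated CDS on the same strand (the ...NTGA arrangement that
    mechanically places A at the downstream fourth site)."""
    with_coords = [c for c in genome.cds if c.coords is not None]
    if len(with_coords) < len(genome.cds):
        warnings.warn("CDSs without coordinates cannot be overlap-screened")
    flagged = set()
    if include_opposite_strand:
        groups = [with_coords]
    else:
        by_strand: dict = {}
        for c in with_coords:
            by_strand.setdefault(c.coords[2], []).append(c)
        groups = list(by_strand.values())
    for cds_list in groups:
        cds_sorted = sorted(cds_list, key=lambda c: c.coords[0])
        for up, down in zip(cds_sorted, cds_sorted[1:]):
            overlap = up.coords[1] - down.coords[0] + 1
            if overlap == 4 and up.seq[-3:] == "TGA":
                flagged.add(down.id)
                down.has_4nt_overlap = True
    return flagged


# ---------------------------------------------------------------------------
# best hits from tabular alignments
# ---------------------------------------------------------------------------

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def best_hits(alignment_rows) -> dict:
    """One subject per query from BLAST outfmt-6 style records.

    ``alignment_rows`` is a DataFrame with outfmt-6 columns, a path to a
    tab-separated file in that column order, or an iterable of rows.
    Selection: minimal E-value, ties broken by highest percent identity,
    then lexicographic subject id.  Malformed rows are skipped with a
    warning carrying the count.
    """
    if isinstance(alignment_rows, (str, Path)):
        df = pd.read_csv(
            alignment_rows, sep="\t", comment="#", header=None,
            names=OUTFMT6_COLUMNS,
        )
    elif isinstance(alignment_rows, pd.DataFrame):
        df = alignment_rows.copy()
    else:
        rows = list(alignment_rows)
        ncol = len(rows[0]) if rows else len(OUTFMT6_COLUMNS)
        if ncol == 4:  # compact (query, subject, pident, evalue) tuples
            df = pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident", "evalue"])
        else:
            df = pd.DataFrame(rows, columns=OUTFMT6_COLUMNS[:ncol])
    n_raw = len(df)
    df["evalue"] = pd.to_numeric(df["evalue"], errors="coerce")
    df["pident"] = pd.to_numeric(df["pident"], errors="coerce")
    df = df.dropna(subset=["qseqid", "sseqid", "evalue", "pident"])
    if len(df) < n_raw:
        warnings.warn(f"skipped {n_raw - len(df)} malformed alignment rows")
    df = df.sort_values(
        ["qseqid", "evalue", "pident", "sseqid"],
        ascending=[True, True, False, True],
    )
    first = df.groupby("qseqid", sort=False).first()
    return dict(zip(first.index, first["sseqid"]))


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def read_genome(
    genome_fasta,
    gff3,
    table_id: int = 11,
    genome_id: Optional[str] = None,
    require_ntg: bool = True,
) -> GenomeRecord:
    """Build a filtered GenomeRecord from a genome FASTA plus GFF3.

    GFF3 coordinates are 1-based inclusive; minus-strand CDSs are
    reverse-complemented so every stored sequence is sense-strand with
    the start codon first.  Upstream intergenic regions are the sequence
    between the previous annotated feature and the CDS start.
    """
    import gffutils

    rec = next(SeqIO.parse(str(genome_fasta), "fasta"))
    seq = str(rec.seq).upper()
    gid = genome_id or rec.id
    table = get_table(table_id)

    db = gffutils.create_db(
        str(gff3), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    cds_feats = sorted(db.features_of_type("CDS"), key=lambda f: f.start)
    rrna = []
    for f in db.features_of_type("rRNA"):
        s = seq[f.start - 1 : f.end]
        rrna.append(s if f.strand != "-" else _revcomp(s))

    # feature spans for intergenic extraction (CDS and rRNA)
    spans = sorted(
        [(f.start, f.end) for f in cds_feats]
        + [(f.start, f.end) for f in db.features_of_type("rRNA")]
    )

    cds_list = []
    intergenic = {}
    for f in cds_feats:
        s = seq[f.start - 1 : f.end]
        if f.strand == "-":
            s = _revcomp(s)
        cid = f.attributes.get("ID", [f.id])[0]
        gene = f.attributes.get("gene", [None])[0]
        cds_list.append(
            CodingSeq(
                id=cid, seq=s, gene_name=gene, coords=(f.start, f.end, f.strand or "+")
            )
        )
        if f.strand != "-":
            prev_end = 0
            for s0, e0 in spans:
                if e0 < f.start:
                    prev_end = max(prev_end, e0)
            intergenic[cid] = seq[prev_end : f.start - 1]
        else:
            nxt = len(seq) + 1
            for s0, e0 in spans:
                if s0 > f.end:
                    nxt = min(nxt, s0)
            intergenic[cid] = _revcomp(seq[f.end : nxt - 1])

    raw = GenomeRecord(
        genome_id=gid, table=table, cds=cds_list, rrna_16s=rrna,
        intergenic=intergenic,
    )
    return apply_filters(raw, require_ntg=require_ntg)


def read_cds_fasta(path, table_id: int = 11, genome_id: str = "genome",
                   require_ntg: bool = True) -> GenomeRecord:
    """GenomeRecord from a CDS multi-FASTA alone (no coordinates,
    intergenic context or rRNA)."""
    cds = [
        CodingSeq(id=r.id, seq=str(r.seq).upper())
        for r in SeqIO.parse(str(path), "fasta")
    ]
    raw = GenomeRecord(genome_id=genome_id, table=get_table(table_id), cds=cds)
    return apply_filters(raw, require_ntg=require_ntg)


def read_genbank(path, table_id: int = 11, require_ntg: bool = True) -> GenomeRecord:
    """Convenience GenBank/EMBL-dialect reader (annotation trusted)."""
    rec = next(SeqIO.parse(str(path), "genbank"))
    table = get_table(table_id)
    cds_list = []
    for i, feat in enumerate(f for f in rec.features if f.type == "CDS"):
        s = str(feat.extract(rec.seq)).upper()
        gene = feat.qualifiers.get("gene", [None])[0]
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        cds_list.append(
            CodingSeq(id=f"cds_{i}", seq=s, gene_name=gene, coords=(start, end, strand))
        )
    rrna = [
        str(f.extract(rec.seq)).upper()
        for f in rec.features
        if f.type == "rRNA"
        and "16S" in " ".join(f.qualifiers.get("product", [""]))
    ]
    raw = GenomeRecord(genome_id=rec.id, table=table, cds=cds_list, rrna_16s=rrna)
    return apply_filters(raw, require_ntg=require_ntg)
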