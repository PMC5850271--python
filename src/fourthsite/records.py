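"""In-memory containers for genomes and coding sequences."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .codes import TranslationTable, gc_content, get_table, iter_codons


@dataclass
class CodingSeq:
    """One CDS on its sense strand, start codon first.

    Site numbering is 1-based with site 1 = the first nucleotide of the
    start codon, so ``fourth_nt`` is ``seq[3]``.
    """

    id: str
    seq: str
    gene_name: Optional[str] = None
    coords: Optional[tuple] = None  # (start, end, strand), annotation convention
    passed_filter: bool = False
    ntg_start: bool = False
    has_sd: Optional[bool] = None
    strong_sd: Optional[bool] = None
    has_leader: Optional[bool] = None
    has_4nt_overlap: Optional[bool] = None
    cai: Optional[float] = None

    @property
    def start_codon(self) -> str:
        return self.seq[:3]

    @property
    def fourth_nt(self) -> str:
        return self.seq[3]

    def nt_at(self, site: int) -> str:
        """Nucleotide at 1-based CDS site."""
        return self.seq[site - 1]


@dataclass
class GenomeRecord:
    """A genome as its filtered CDS collection plus the context the
    analyses need (16S copies for the anti-SD tail, upstream intergenic
    regions for SD/leader scanning)."""

    genome_id: str
    table: TranslationTable
    cds: list = field(default_factory=list)
    rrna_16s: list = field(default_factory=list)
    intergenic: dict = field(default_factory=dict)  # cds id -> upstream DNA

    def __post_init__(self) -> None:
        if isinstance(self.table, int):
            self.table = get_table(self.table)
        self._codon_counts: Optional[Counter] = None

    # -- composition ------------------------------------------------------
    @property
    def gc(self) -> float:
        total = sum(len(c.seq) for c in self.cds)
        if total == 0:
            return float("nan")
        gcs = sum(c.seq.count("G") + c.seq.count("C") for c in self.cds)
        return gcs / total

    @property
    def gc3(self) -> float:
        """GC at synonymous third codon positions (single-codon families
        and stops excluded)."""
        fams = self.table.synonymous_families()
        degenerate = {c for cods in fams.values() if len(cods) > 1 for c in cods}
        n = gc = 0
        for counts in self.codon_counts().items():
            codon, k = counts
            if codon in degenerate:
                n += k
                if codon[2] in "GC":
                    gc += k
        return gc / n if n else float("nan")

    def codon_counts(self) -> Counter:
        """Counts of all codons (start and stop included) over all CDSs."""
        if self._codon_counts is None:
            counts: Counter = Counter()
            for c in self.cds:
                counts.update(iter_codons(c.seq))
            self._codon_counts = counts
        return self._codon_counts

    def invalidate_caches(self) -> None:
        self._codon_counts = None

    @property
    def n_cds(self) -> int:
        return len(self.cds)

    def subset(self, keep_ids: set, genome_id: Optional[str] = None) -> "GenomeRecord":
        """New record restricted to the given CDS ids (caches rebuilt)."""
        return GenomeRecord(
            genome_id=genome_id or self.genome_id,
            table=self.table,
            cds=[c for c in self.cds if c.id in keep_ids],
            rrna_16s=list(self.rrna_16s),
            intergenic={k: v for k, v in self.intergenic.items() if k in keep_ids},
        )


def gc3_of_seq(seq: str, table: TranslationTable) -> float:
    """GC3 of a single CDS (same definition as GenomeRecord.gc3)."""
    fams = table.synonymous_families()
    degenerate = {c for cods in fams.values() if len(cods) > 1 for c in cods}
    n = gc = 0
    for codon in iter_codons(seq):
        if codon in degenerate:
            n += 1
            if codon[2] in "GC":
                gc += 1
    return gc / n if n else float("nan")


__all__ = ["CodingSeq", "GenomeRecord", "gc3_of_seq", "gc_content"]
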