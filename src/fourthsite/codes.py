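"""Genetic-code tables and codon bookkeeping.

Everything downstream is parameterised by an NCBI translation table: the
bacterial/archaeal standard (table 11, stops TAA/TAG/TGA) or the
Mycoplasma/Spiroplasma variant (table 4, stops TAA/TAG, TGA = Trp).
Start codons are restricted to the NTG triplet the analyses assume
(ATG/GTG/TTG), not the full permissive NCBI initiator set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable as _BioCodonTable

NUCLEOTIDES = "ACGT"
ALL_CODONS = tuple("".join(p) for p in product(NUCLEOTIDES, repeat=3))

#: start codons treated as "regular" NTG initiators throughout
NTG_STARTS = frozenset({"ATG", "GTG", "TTG"})

SUPPORTED_TABLES = (11, 4)


@dataclass(frozen=True)
class TranslationTable:
    """A genetic code restricted to what the analyses need.

    Attributes
    ----------
    id : int
        NCBI table number (11 or 4).
    stops : frozenset[str]
        Stop codons of the table.
    start_codons : frozenset[str]
        Codons accepted as regular initiators (ATG/GTG/TTG).
    forward : dict[str, str]
        Sense codon -> one-letter amino acid.
    """

    id: int
    stops: frozenset = field(repr=False)
    start_codons: frozenset = field(repr=False)
    forward: dict = field(repr=False)

    @property
    def sense_codons(self) -> tuple:
        return tuple(c for c in ALL_CODONS if c not in self.stops)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def translate_codon(self, codon: str) -> str:
        """One-letter amino acid, '*' for a stop."""
        if codon in self.stops:
            return "*"
        return self.forward[codon]

    def synonymous_families(self) -> dict:
        """Map amino acid -> tuple of its sense codons."""
        fams: dict = {}
        for codon, aa in self.forward.items():
            fams.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(cs)) for aa, cs in fams.items()}


@lru_cache(maxsize=None)
def get_table(table_id: int) -> TranslationTable:
    if table_id not in SUPPORTED_TABLES:
        raise ValueError(f"unsupported translation table {table_id!r}; use 11 or 4")
    bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
    return TranslationTable(
        id=table_id,
        stops=frozenset(bio.stop_codons),
        start_codons=NTG_STARTS,
        forward=dict(bio.forward_table),
    )


# ---------------------------------------------------------------------------
# Codon blocks for the second-amino-acid analyses.
#
# The six-fold degenerate amino acids (Ser, Arg, Leu) occupy two codon
# blocks whose first nucleotide differs; the split is the lever for
# separating amino-acid-level from nucleotide-level selection.
# ---------------------------------------------------------------------------

SERINE_A = ("AGC", "AGT")                      # A-starting serine, S_A
SERINE_T = ("TCA", "TCC", "TCG", "TCT")        # T-starting serine, S_T
ARGININE_A = ("AGA", "AGG")                    # A-starting arginine, R_A
ARGININE_C = ("CGA", "CGC", "CGG", "CGT")      # C-starting arginine, R_C
LEUCINE_C = ("CTA", "CTC", "CTG", "CTT")       # C-starting leucine
LEUCINE_T = ("TTA", "TTG")                     # T-starting leucine


def codon_blocks(table: TranslationTable) -> dict:
    """Amino-acid blocks with the six-fold degenerates split by first base.

    Returns a mapping block label -> tuple of codons.  Labels are the
    one-letter amino acid, with 'S_A'/'S_T', 'R_A'/'R_C' and 'L_C'/'L_T'
    replacing 'S', 'R' and 'L'.
    """
    blocks = {}
    for aa, codons in table.synonymous_families().items():
        if aa == "S":
            blocks["S_A"] = SERINE_A
            blocks["S_T"] = SERINE_T
        elif aa == "R":
            blocks["R_A"] = ARGININE_A
            blocks["R_C"] = ARGININE_C
        elif aa == "L":
            blocks["L_C"] = LEUCINE_C
            blocks["L_T"] = LEUCINE_T
        else:
            blocks[aa] = codons
    return blocks


#: block labels whose codons start with A
A_STARTING_BLOCKS = ("K", "N", "T", "I", "M", "S_A", "R_A")


def a_starting_fraction(block_pair: tuple) -> float:
    """Fraction of A-starting codons in a six-codon family given as
    (A-starting block, alternative block)."""
    a_block, other = block_pair
    return len(a_block) / (len(a_block) + len(other))


def gc_content(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)


def iter_codons(seq: str):
    """Yield successive complete triplets of ``seq``."""
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield seq[i : i + 3]
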