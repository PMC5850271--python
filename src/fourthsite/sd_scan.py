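"""Shine-Dalgarno identification by anti-SD hybridization scanning.

The 3' tail of the 16S rRNA (anti-SD) is slid across a 60-nt window
centred on the start codon (the start A is window position 30) and a
nearest-neighbour RNA:RNA duplex free energy at 37 degC is computed at
every alignment; the minimum is the optimal binding site.  A CDS has an
SD if that minimum is at or below -3.4535 kcal/mol (the mean of the
published core-motif energies for GGAG, GAGG and AGGA) and a strong SD
at or below -8.4 kcal/mol (the GGAGGT hexamer energy).

The energy model sums Watson-Crick and G:U wobble stack terms over the
single best contiguous helix of each alignment, plus duplex initiation
and terminal A:U / G:U penalties (Turner-lineage parameters; no
dangling ends).  It is calibrated against the three published motif
energies to within +/-0.5 kcal/mol rather than claiming bit-equality
with any particular scanning tool.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .records import GenomeRecord

# -- published calibration values (kcal/mol) --------------------------------
CORE_MOTIF_DG = {"GGAG": -3.60793, "GAGG": -3.60793, "AGGA": -3.144505}
SD_THRESHOLD = -3.4535          # mean of the three core-motif energies
STRONG_SD_THRESHOLD = -8.4      # GGAGGT exemplar
WINDOW = 60                     # nt, start A at position 30 (1-based)
UPSTREAM_IN_WINDOW = 29         # nt of window upstream of the start A

# -- nearest-neighbour parameters (kcal/mol, 37 degC) ------------------------
# Stack energy for helix pairs p1 then p2 (5'->3' on the mRNA strand);
# looked up as M[p1][reverse(p2)] in the conventional 6x6 pair matrix.
_PAIRS = ("CG", "GC", "GU", "UG", "AU", "UA")
_STACK_MATRIX = {
    "CG": (-2.40, -3.30, -2.10, -1.40, -2.10, -2.10),
    "GC": (-3.30, -3.40, -2.50, -1.50, -2.20, -2.40),
    "GU": (-2.10, -2.50, +1.30, -0.50, -1.40, -1.30),
    "UG": (-1.40, -1.50, -0.50, +0.30, -0.60, -1.00),
    "AU": (-2.10, -2.20, -1.40, -0.60, -1.10, -0.90),
    "UA": (-2.10, -2.40, -1.30, -1.00, -0.90, -1.30),
}
DUPLEX_INITIATION = 4.09
TERMINAL_AU_PENALTY = 0.45

_CAN_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_STACK = {
    (p1, p2): _STACK_MATRIX[p1][_PAIRS.index(p2[::-1])]
    for p1 in _PAIRS
    for p2 in _PAIRS
}


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class AntiSDTail:
    tail: str          # DNA alphabet as in the input, GAT motif first
    length: int
    source_count: int  # how many 16S copies yielded it

    def __post_init__(self) -> None:
        assert self.tail.upper().replace("U", "T").startswith("GAT")
        assert 8 <= self.length <= 15


@dataclass
class SDResult:
    cds_id: str
    dg_min: float      # kcal/mol at the optimal offset; 0 = no binding
    offset: Optional[int]  # binding-site 5' end relative to start A (=0)
    has_sd: bool
    strong_sd: bool


def extract_tail(rrna_16s) -> Optional[AntiSDTail]:
    """Anti-SD tail from one 16S sequence or a list of copies.

    The tail runs from the last 5'-GAT-3' motif through the 3' terminus
    (inclusive); tails outside 8-15 nt are rejected.  Across multiple
    copies the most frequent accepted tail wins (ties alphabetically).
    """
    seqs = [rrna_16s] if isinstance(rrna_16s, str) else list(rrna_16s)
    tails = []
    for s in seqs:
        su = s.upper().replace("U", "T")
        pos = su.rfind("GAT")
        if pos == -1:
            continue
        tail = su[pos:]
        if 8 <= len(tail) <= 15:
            tails.append(tail)
    if not tails:
        return None
    counts = Counter(tails)
    best = min(counts, key=lambda t: (-counts[t], t))
    return AntiSDTail(tail=best, length=len(best), source_count=counts[best])


# ---------------------------------------------------------------------------
# duplex energy
# ---------------------------------------------------------------------------

def _best_helix_dg(paired_pairs: list) -> float:
    """Minimal free energy over contiguous helices in an alignment.

    ``paired_pairs`` lists, position by position along the alignment,
    either an mRNA:tail pair string like "GC" (mRNA base first, RNA
    alphabet) or None where the bases cannot pair.
    """
    best = 0.0
    i = 0
    n = len(paired_pairs)
    while i < n:
        if paired_pairs[i] is None:
            i += 1
            continue
        j = i
        while j + 1 < n and paired_pairs[j + 1] is not None:
            j += 1
        run = paired_pairs[i : j + 1]
        if len(run) >= 2:
            dg = DUPLEX_INITIATION
            for a, b in zip(run, run[1:]):
                dg += _STACK[(a, b)]
            for terminal in (run[0], run[-1]):
                if "U" in terminal:  # A:U or G:U closing pair
                    dg += TERMINAL_AU_PENALTY
            best = min(best, dg)
        i = j + 1
    return best


def duplex_dg(mrna_segment: str, tail, offset: int = 0) -> float:
    """Duplex free energy of the anti-SD tail aligned antiparallel to the
    mRNA with its 3' end at ``offset`` (0-based index into the segment).

    Positions falling outside the segment, non-ACGU characters and
    non-pairable bases are unpaired; non-negative totals are reported as
    0 (no binding).
    """
    tail_seq = _rna(tail.tail if isinstance(tail, AntiSDTail) else tail)
    m = _rna(mrna_segment)
    if not set(m) <= set("ACGUN") or not set(tail_seq) <= set("ACGU"):
        raise ValueError("sequences must be nucleic acid strings")
    pairs = []
    L = len(tail_seq)
    for i in range(L):
        mi = offset + i
        t = tail_seq[L - 1 - i]  # antiparallel: tail 3' end pairs first
        if 0 <= mi < len(m) and (m[mi], t) in _CAN_PAIR:
            pairs.append(m[mi] + t)
        else:
            pairs.append(None)
    return _best_helix_dg(pairs)


def _best_site(window: str, tail: AntiSDTail):
    """(dg_min, 5'-end window index of the best helix) over all offsets."""
    tail_seq = _rna(tail.tail)
    L = len(tail_seq)
    best = (0.0, None)
    for offset in range(-L + 2, len(window) - 1):
        dg = duplex_dg(window, tail, offset)
        if dg < best[0]:
            # locate the 5' end of the best run for reporting
            m = _rna(window)
            first = None
            for i in range(L):
                mi = offset + i
                if 0 <= mi < len(m) and (m[mi], tail_seq[L - 1 - i]) in _CAN_PAIR:
                    first = mi
                    break
            best = (dg, first)
    return best


def scan_window(
    cds_seq: str,
    upstream: str,
    tail: Optional[AntiSDTail],
    cds_id: str = "",
    threshold: float = SD_THRESHOLD,
    strong_threshold: float = STRONG_SD_THRESHOLD,
) -> SDResult:
    """SD classification of one CDS from its 60-nt start-codon window.

    ``upstream`` is the intergenic context immediately 5' of the start
    codon; short context is padded with N (unbindable).  Offsets are
    reported with the start A at 0, negative = upstream.
    """
    if tail is None:
        return SDResult(cds_id=cds_id, dg_min=math.nan, offset=None,
                        has_sd=False, strong_sd=False)
    up = upstream[-UPSTREAM_IN_WINDOW:] if upstream else ""
    up = "N" * (UPSTREAM_IN_WINDOW - len(up)) + up
    window = up + cds_seq[: WINDOW - UPSTREAM_IN_WINDOW]
    window = window + "N" * (WINDOW - len(window))
    dg, first_idx = _best_site(window, tail)
    offset = None if first_idx is None else first_idx - UPSTREAM_IN_WINDOW
    return SDResult(
        cds_id=cds_id, dg_min=dg, offset=offset,
        has_sd=dg <= threshold, strong_sd=dg <= strong_threshold,
    )


def scan_genome(genome: GenomeRecord, tail: Optional[AntiSDTail] = None) -> pd.DataFrame:
    """SD scan of every CDS; the tail defaults to the genome's own 16S
    copies.  CDSs of a genome without a usable tail are flagged
    sd-unknown (NaN energies)."""
    if tail is None:
        tail = extract_tail(genome.rrna_16s) if genome.rrna_16s else None
    rows = []
    for c in genome.cds:
        r = scan_window(c.seq, genome.intergenic.get(c.id, ""), tail, cds_id=c.id)
        c.has_sd = r.has_sd if tail is not None else None
        c.strong_sd = r.strong_sd if tail is not None else None
        rows.append(
            dict(cds_id=c.id, dg_min=r.dg_min, offset=r.offset,
                 has_sd=r.has_sd, strong_sd=r.strong_sd,
                 fourth_nt=c.fourth_nt)
        )
    return pd.DataFrame(rows)


def sd_fourth_site_contrast(genomes) -> pd.DataFrame:
    """Per-genome fourth-site-A proportions for SD vs non-SD CDSs
    (paired rows; genomes with an empty class are dropped)."""
    rows = []
    for g in genomes:
        scan = scan_genome(g)
        if scan.has_sd.isna().any():
            continue
        sd = scan[scan.has_sd]
        nosd = scan[~scan.has_sd]
        if len(sd) == 0 or len(nosd) == 0:
            continue
        rows.append(
            dict(
                genome_id=g.genome_id,
                prop_A_sd=float((sd.fourth_nt == "A").mean()),
                prop_A_nosd=float((nosd.fourth_nt == "A").mean()),
                n_sd=len(sd), n_nosd=len(nosd),
            )
        )
    return pd.DataFrame(rows)
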