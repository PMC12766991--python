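"""Read-structure parsing, restructuring, tag correction and trimming.

A raw pair carries its technical sequence up front:

* R1: ``[barcode A (8)][mosaic end (19)][insert from the A-proximal end]``
* R2: ``[barcode B (8)][UMI (6)][mosaic end (19)][insert from the
  B-proximal end, reverse-complement strand]``

The published preprocessing moves barcode B and the UMI from read 2 onto
the front of read 1 and deletes the 33-bp technical prefix (8 + 6 + 19)
from the 5' end of read 2; :func:`restructure_pair` mirrors that exactly.
Tag extraction works on either layout, and the two routes agree (a tested
equivalence).

Barcode correction is unique-nearest-neighbour at Hamming distance <= 1.
Against whitelists with pairwise distance >= 3 this is sound: a read whose
barcode suffered at most one substitution can never be corrected to the
wrong whitelist entry.  UMIs are never corrected — with only 4096 possible
6-mers, merging near-neighbours would collapse genuinely distinct
fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from .barcodes import BarcodeSet
from .seqs import (
    BARCODE_LENGTH,
    MOSAIC_END,
    R2_TECH_PREFIX,
    UMI_LENGTH,
    hamming,
    revcomp,
)

PHRED_OFFSET = 33


@lru_cache(maxsize=16)
def _exact_lookup(whitelist: BarcodeSet) -> dict:
    return {bc: i for i, bc in enumerate(whitelist.barcodes)}


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class TagBundle:
    """Raw and (optionally) corrected tags extracted from one pair."""

    barcode_a_raw: str
    barcode_b_raw: str
    umi: str
    barcode_a_corrected: Optional[int] = None
    barcode_b_corrected: Optional[int] = None
    correction_dist_a: Optional[int] = None
    correction_dist_b: Optional[int] = None


def extract_tags(pair: ReadPair, restructured: bool = False) -> Optional[TagBundle]:
    """Positional tag slicing; ``None`` signals a structurally short pair.

    Raw layout: A = r1[0:8], B = r2[0:8], UMI = r2[8:14].  After
    :func:`restructure_pair` the same information sits at the front of the
    new r1: B = r1[0:8], UMI = r1[8:14], A = r1[14:22].
    """
    bu = BARCODE_LENGTH + UMI_LENGTH
    if restructured:
        if len(pair.r1_seq) < bu + BARCODE_LENGTH:
            return None
        return TagBundle(
            barcode_a_raw=pair.r1_seq[bu : bu + BARCODE_LENGTH],
            barcode_b_raw=pair.r1_seq[:BARCODE_LENGTH],
            umi=pair.r1_seq[BARCODE_LENGTH:bu],
        )
    if len(pair.r1_seq) < BARCODE_LENGTH or len(pair.r2_seq) < R2_TECH_PREFIX:
        return None
    return TagBundle(
        barcode_a_raw=pair.r1_seq[:BARCODE_LENGTH],
        barcode_b_raw=pair.r2_seq[:BARCODE_LENGTH],
        umi=pair.r2_seq[BARCODE_LENGTH:bu],
    )


def restructure_pair(pair: ReadPair) -> Optional[ReadPair]:
    """Move barcode B + UMI onto read 1; delete read 2's 33-bp prefix.

    Information-preserving up to the discarded bases 14..33 of read 2 (the
    mosaic end, a constant).  Returns ``None`` for pairs whose read 2 is
    shorter than the 33-bp technical prefix.
    """
    bu = BARCODE_LENGTH + UMI_LENGTH
    if len(pair.r2_seq) < R2_TECH_PREFIX:
        return None
    return ReadPair(
        read_id=pair.read_id,
        r1_seq=pair.r2_seq[:bu] + pair.r1_seq,
        r1_qual=pair.r2_qual[:bu] + pair.r1_qual,
        r2_seq=pair.r2_seq[R2_TECH_PREFIX:],
        r2_qual=pair.r2_qual[R2_TECH_PREFIX:],
    )


def correct_barcode(
    observed: str,
    whitelist: BarcodeSet,
    max_dist: int = 1,
    max_n: int = 2,
) -> tuple[Optional[int], Optional[int]]:
    """Unique-nearest-neighbour whitelist correction.

    Returns ``(index, distance)``, or ``(None, None)`` when no entry lies
    within ``max_dist``, when two or more entries tie at the minimum, or
    when the observed barcode carries more than ``max_n`` N calls.  An exact
    match always wins at distance 0; N counts as a mismatch to every letter.
    """
    if len(observed) != whitelist.length:
        return None, None
    if observed.count("N") > max_n:
        return None, None
    exact = _exact_lookup(whitelist)
    hit = exact.get(observed)
    if hit is not None:
        return hit, 0
    best_idx: Optional[int] = None
    best_dist = whitelist.length + 1
    tie = False
    for i, bc in enumerate(whitelist.barcodes):
        d = hamming(observed, bc)
        if d < best_dist:
            best_idx, best_dist, tie = i, d, False
            if d == 0:
                return i, 0
        elif d == best_dist:
            tie = True
    if best_dist > max_dist or tie:
        return None, None
    return best_idx, best_dist


def trim_polya(seq: str, qual: str, min_run: int = 6, max_mismatch: int = 1) -> tuple[str, str]:
    """Remove the longest 3'-terminal suffix that is >= ``min_run`` long and
    contains at most ``max_mismatch`` non-A bases; no-op when none exists.

    The trim point must itself be an A — a tail never starts on a mismatch,
    so ``ACGT`` + 20 A leaves the T in place."""
    n = len(seq)
    if n < min_run:
        return seq, qual
    non_a = 0
    cut = n
    # walk in from the 3' end; the leftmost admissible start wins (longest suffix)
    for i in range(n - 1, -1, -1):
        if seq[i] != "A":
            non_a += 1
            if non_a > max_mismatch:
                break
        elif n - i >= min_run:
            cut = i
    return seq[:cut], qual[:cut]


def trim_me_readthrough(
    seq: str,
    qual: str,
    me: str = MOSAIC_END,
    max_mismatch: int = 1,
    min_terminal_match: int = 8,
) -> tuple[str, str]:
    """Truncate a read at the opposite adapter seen through a short insert.

    A fragment shorter than the read length reads through into the opposite
    Tn5 adapter, whose first visible bases are the reverse complement of the
    mosaic end.  The leftmost full-length occurrence of rc(ME) with at most
    ``max_mismatch`` mismatches — or an exact terminal partial match of at
    least ``min_terminal_match`` nt — marks the end of the insert.
    """
    target = revcomp(me)
    t = len(target)
    n = len(seq)
    for i in range(0, n - t + 1):
        mm = 0
        for j in range(t):  # early-exit mismatch count; hot path
            if seq[i + j] != target[j]:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            return seq[:i], qual[:i]
    lo = max(0, n - t + 1)
    for i in range(lo, n - min_terminal_match + 1):
        if seq[i:] == target[: n - i]:
            return seq[:i], qual[:i]
    return seq, qual


def quality_filter_tags(pair: ReadPair, min_q: int = 10, restructured: bool = False) -> bool:
    """Pass iff every barcode/UMI base has Phred quality >= ``min_q``."""
    bu = BARCODE_LENGTH + UMI_LENGTH
    if restructured:
        tag_quals = pair.r1_qual[: bu + BARCODE_LENGTH]
    else:
        tag_quals = pair.r1_qual[:BARCODE_LENGTH] + pair.r2_qual[:bu]
    return all(ord(q) - PHRED_OFFSET >= min_q for q in tag_quals)


def me_structure_ok(pair: ReadPair, me: str = MOSAIC_END, max_mismatch: int = 3) -> bool:
    """Optional structure check of the mosaic-end window at r2[14:33]."""
    bu = BARCODE_LENGTH + UMI_LENGTH
    window = pair.r2_seq[bu : bu + len(me)]
    if len(window) < len(me):
        return False
    return hamming(window, me) <= max_mismatch
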