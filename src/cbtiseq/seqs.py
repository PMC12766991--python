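"""Shared DNA-sequence primitives and the read-architecture constants.

The library molecule produced by combinatorial barcoded-Tn5 tagmentation has
a fixed technical layout on each mate:

* Read 1: ``[8-nt barcode A][19-nt mosaic end][cDNA insert ...]``
* Read 2: ``[8-nt barcode B][6-nt UMI][19-nt mosaic end][cDNA insert ...]``

so the read-2 technical prefix is 8 + 6 + 19 = 33 nt and the read-1 prefix
is 8 + 19 = 27 nt.  Those arithmetic facts are the constants below; every
other module derives positions from them rather than hard-coding offsets.
"""

from __future__ import annotations

import numpy as np

#: Canonical 19-nt Tn5 mosaic-end recognition sequence.
MOSAIC_END = "AGATGTGTATAAGAGACAG"

BARCODE_LENGTH = 8
UMI_LENGTH = 6

#: Technical prefix lengths visible on each mate of a raw pair.
R1_TECH_PREFIX = BARCODE_LENGTH + len(MOSAIC_END)             # 27
R2_TECH_PREFIX = BARCODE_LENGTH + UMI_LENGTH + len(MOSAIC_END)  # 33

DNA_ALPHABET = "ACGT"

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, N-preserving."""
    return seq.translate(_RC_TABLE)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance where an ``N`` mismatches every symbol, itself included.

    Raises ``ValueError`` on unequal lengths: the distance is undefined there
    and silently truncating would mask structural errors upstream.
    """
    if len(a) != len(b):
        raise ValueError(f"hamming distance undefined for lengths {len(a)} != {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("gc_fraction of empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1 if seq else 0
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=length))


def ints_to_kmers(codes: np.ndarray, length: int) -> list[str]:
    """Decode base-4 integers into DNA strings of a fixed length (vectorised)."""
    out = np.empty((len(codes), length), dtype="U1")
    c = np.asarray(codes, dtype=np.int64).copy()
    for pos in range(length - 1, -1, -1):
        out[:, pos] = np.array(list(DNA_ALPHABET))[c % 4]
        c //= 4
    return ["".join(row) for row in out]
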