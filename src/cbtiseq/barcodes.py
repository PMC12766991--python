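"""Orthogonal barcode whitelist design and the combinatorial sample space.

A multiplexed tagmentation run labels every sample with a pair of 8-nt
indices, one carried on the A-side Tn5 adapter and one on the B-side
adapter.  Because every sequenceable fragment carries one A end and one B
end, ``m`` A-barcodes and ``n`` B-barcodes address ``m x n`` samples with
only ``m + n`` reagents.

Whitelists are designed with a minimum pairwise Hamming distance of 3 so
that correcting a single sequencing substitution is unambiguous: at
distance >= 3, the Hamming-1 ball around each barcode is disjoint from
every other barcode's ball.  Both barcodes are sequenced in 8-cycle
windows, so a combined A+B validation enforces the same floor across the
union of the two lists (a corrupted B barcode must never be correctable to
an A barcode).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqs import (
    BARCODE_LENGTH,
    DNA_ALPHABET,
    gc_fraction,
    hamming,
    max_homopolymer_run,
    random_dna,
)

#: Design floor guaranteeing unambiguous single-substitution correction.
DESIGN_MIN_DIST = 3
DEFAULT_GC_RANGE = (0.25, 0.75)
DEFAULT_MAX_HOMOPOLYMER = 3


class BarcodeDesignError(ValueError):
    """Raised when a whitelist satisfying the constraints cannot be built."""


@dataclass(frozen=True)
class BarcodeSet:
    """A named whitelist of fixed-length DNA barcodes.

    ``min_pairwise_dist`` is computed at construction by an all-pairs scan;
    for a singleton set it is defined (vacuously) as the barcode length.
    """

    name: str
    barcodes: tuple[str, ...]
    min_pairwise_dist: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("BarcodeSet requires at least one barcode")
        object.__setattr__(self, "barcodes", tuple(self.barcodes))
        length = len(self.barcodes[0])
        for bc in self.barcodes:
            if len(bc) != length:
                raise ValueError("barcodes must share one length")
            if any(c not in DNA_ALPHABET for c in bc):
                raise ValueError(f"barcode {bc!r} contains non-ACGT symbols")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes in whitelist")
        object.__setattr__(self, "min_pairwise_dist", _min_pairwise_distance(self.barcodes))

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def length(self) -> int:
        return len(self.barcodes[0])

    def __getitem__(self, i: int) -> str:
        return self.barcodes[i]


def _min_pairwise_distance(barcodes: Sequence[str]) -> int:
    if len(barcodes) == 1:
        return len(barcodes[0])
    return min(hamming(a, b) for a, b in itertools.combinations(barcodes, 2))


def generate_barcode_set(
    k: int,
    length: int = BARCODE_LENGTH,
    min_dist: int = DESIGN_MIN_DIST,
    gc_range: tuple[float, float] = DEFAULT_GC_RANGE,
    max_homopolymer: int = DEFAULT_MAX_HOMOPOLYMER,
    seed: int = 0,
    name: str = "A",
    exclude: Iterable[str] = (),
    max_attempts_per_code: int = 100_000,
) -> BarcodeSet:
    """Greedy randomized search for ``k`` barcodes meeting all constraints.

    ``exclude`` holds barcodes from a partner whitelist that the new codes
    must also keep ``min_dist`` away from (cross-set orthogonality).
    Deterministic for a fixed seed; raises :class:`BarcodeDesignError` when a
    code cannot be placed within ``max_attempts_per_code`` draws, never
    returning a silently shorter set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if 4**length < k:
        raise BarcodeDesignError(f"design infeasible: 4^{length} < {k}")
    if min_dist > length:
        raise BarcodeDesignError("design infeasible: min_dist exceeds barcode length")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    constraints = list(exclude)
    while len(accepted) < k:
        for _ in range(max_attempts_per_code):
            cand = random_dna(rng, length)
            lo, hi = gc_range
            if not (lo <= gc_fraction(cand) <= hi):
                continue
            if max_homopolymer_run(cand) > max_homopolymer:
                continue
            if all(hamming(cand, other) >= min_dist for other in constraints):
                accepted.append(cand)
                constraints.append(cand)
                break
        else:
            raise BarcodeDesignError(
                f"design infeasible: placed {len(accepted)}/{k} codes of length "
                f"{length} at min_dist {min_dist} within {max_attempts_per_code} "
                "attempts per code"
            )
    return BarcodeSet(name=name, barcodes=tuple(accepted))


@dataclass(frozen=True)
class BarcodeValidationReport:
    n: int
    length: int
    min_distance: int
    gc_min: float
    gc_max: float
    max_homopolymer: int
    has_duplicates: bool
    cross_min_distance: int | None
    passed: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def validate_barcode_set(
    bset: BarcodeSet,
    design_floor: int = DESIGN_MIN_DIST,
    gc_range: tuple[float, float] = DEFAULT_GC_RANGE,
    max_homopolymer: int = DEFAULT_MAX_HOMOPOLYMER,
    combine_with: BarcodeSet | None = None,
) -> BarcodeValidationReport:
    """Independent O(k^2 * L) re-check of a whitelist; reports, never raises.

    With ``combine_with`` set, the pairwise floor is additionally enforced
    across the union of the two lists.
    """
    codes = list(bset.barcodes)
    min_distance = _min_pairwise_distance(codes)
    gcs = [gc_fraction(bc) for bc in codes]
    homo = max(max_homopolymer_run(bc) for bc in codes)
    dup = len(set(codes)) != len(codes)
    cross = None
    if combine_with is not None:
        # a barcode shared verbatim between the two lists is distance 0
        cross = min(hamming(a, b) for a in codes for b in combine_with.barcodes)
    passed = (
        min_distance >= design_floor
        and not dup
        and gc_range[0] <= min(gcs)
        and max(gcs) <= gc_range[1]
        and homo <= max_homopolymer
        and (cross is None or cross >= design_floor)
    )
    return BarcodeValidationReport(
        n=len(codes),
        length=bset.length,
        min_distance=min_distance,
        gc_min=min(gcs),
        gc_max=max(gcs),
        max_homopolymer=homo,
        has_duplicates=dup,
        cross_min_distance=cross,
        passed=passed,
    )


def combinatorial_capacity(set_a: BarcodeSet, set_b: BarcodeSet) -> int:
    """Number of addressable samples: |A| x |B|."""
    return len(set_a) * len(set_b)


@dataclass(frozen=True)
class SampleEntry:
    a_index: int
    b_index: int
    sample_id: str


@dataclass(frozen=True)
class SampleSheet:
    """The (A_m, B_n) -> sample_id combinatorial map."""

    entries: tuple[SampleEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if not self.entries:
            raise ValueError("empty sample sheet")
        pairs = [(e.a_index, e.b_index) for e in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (a_index, b_index) pair in sample sheet")
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in sample sheet")
        if any(e.a_index < 0 or e.b_index < 0 for e in self.entries):
            raise ValueError("negative barcode index")

    @property
    def m(self) -> int:
        """Distinct A barcodes in use."""
        return len({e.a_index for e in self.entries})

    @property
    def n(self) -> int:
        """Distinct B barcodes in use."""
        return len({e.b_index for e in self.entries})

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def lookup(self) -> dict[tuple[int, int], str]:
        return {(e.a_index, e.b_index): e.sample_id for e in self.entries}

    def validate_against(self, set_a: BarcodeSet, set_b: BarcodeSet) -> None:
        for e in self.entries:
            if e.a_index >= len(set_a):
                raise ValueError(f"sample {e.sample_id}: a_index {e.a_index} outside whitelist A")
            if e.b_index >= len(set_b):
                raise ValueError(f"sample {e.sample_id}: b_index {e.b_index} outside whitelist B")
        if len(self.entries) > combinatorial_capacity(set_a, set_b):
            raise ValueError("more samples than combinatorial capacity")

    @classmethod
    def full(cls, m: int, n: int, prefix: str = "S") -> "SampleSheet":
        """All m x n combinations, row-major, ids ``S01_01`` .. ``S{m}_{n}``."""
        entries = [
            SampleEntry(a, b, f"{prefix}{a + 1:02d}_{b + 1:02d}")
            for a in range(m)
            for b in range(n)
        ]
        return cls(tuple(entries))

    @classmethod
    def diagonal(cls, s: int, prefix: str = "S") -> "SampleSheet":
        """``s`` samples on unique (A_i, B_i) pairs — one reagent pair each."""
        return cls(tuple(SampleEntry(i, i, f"{prefix}{i + 1:02d}") for i in range(s)))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(e.a_index, e.b_index, e.sample_id) for e in self.entries],
            columns=["a_index", "b_index", "sample_id"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path)
        required = {"a_index", "b_index", "sample_id"}
        if not required.issubset(df.columns):
            raise ValueError(f"sample sheet missing columns {sorted(required - set(df.columns))}")
        return cls(
            tuple(
                SampleEntry(int(r.a_index), int(r.b_index), str(r.sample_id))
                for r in df.itertuples()
            )
        )


def write_whitelist(bset: BarcodeSet, path: str | Path) -> None:
    """Plain-text whitelist: one barcode per line, '#' comments allowed."""
    with open(path, "w") as fh:
        fh.write(f"# whitelist {bset.name}: {len(bset)} barcodes, length {bset.length}, "
                 f"min pairwise Hamming distance {bset.min_pairwise_dist}\n")
        for bc in bset.barcodes:
            fh.write(bc + "\n")


def read_whitelist(path: str | Path, name: str | None = None) -> BarcodeSet:
    codes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            codes.append(line.upper())
    return BarcodeSet(name=name or Path(path).stem, barcodes=tuple(codes))
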