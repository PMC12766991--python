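"""Combinatorial sample demultiplexing and multiplexing statistics.

One pair at a time: restructure (barcode B + UMI moved to read 1, 33-bp
technical prefix deleted from read 2) -> tag extraction -> whitelist
correction -> tag quality filter -> sample-sheet lookup.  Every input pair
receives exactly one outcome, so the outcome counts always sum to the
input count — the conservation invariant every run is checked against.

Two decoding-quality rates are reported: the fraction of pairs whose A and
B barcodes are both whitelist-assignable (the "barcode readout" of a
single-sample library) and the fraction actually assigned to a sheet
sample.  Valid barcode pairs absent from the sheet are tallied separately
(``pair_not_in_sheet``) as a cross-contamination diagnostic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .barcodes import BarcodeSet, SampleSheet
from .readproc import (
    MOSAIC_END,
    ReadPair,
    correct_barcode,
    extract_tags,
    me_structure_ok,
    quality_filter_tags,
    restructure_pair,
    trim_me_readthrough,
    trim_polya,
)

#: Outcome labels, in precedence order.
FAIL_STRUCTURE = "fail_structure"
BAD_A = "bad_a"
BAD_B = "bad_b"
FAIL_QUALITY = "fail_quality"
PAIR_NOT_IN_SHEET = "pair_not_in_sheet"
ASSIGNED = "assigned"

UNASSIGNED_REASONS = (FAIL_STRUCTURE, BAD_A, BAD_B, FAIL_QUALITY, PAIR_NOT_IN_SHEET)


@dataclass(frozen=True)
class DemuxConfig:
    min_tag_quality: int = 10
    max_barcode_dist: int = 1
    max_n_in_barcode: int = 2
    check_me: bool = False
    me_max_mismatch: int = 3
    trim_readthrough: bool = True
    trim_polya: bool = True
    polya_min_run: int = 6
    polya_max_mismatch: int = 1
    keep_r1_insert: bool = False
    mosaic_end: str = MOSAIC_END


@dataclass(frozen=True)
class DecodedRead:
    read_id: str
    sample_id: str
    a_index: int
    b_index: int
    umi: str
    seq: str   # trimmed cDNA insert read from the B-proximal fragment end
    qual: str
    r1_seq: Optional[str] = None
    r1_qual: Optional[str] = None


@dataclass
class DemuxStats:
    total_pairs: int = 0
    assigned_pairs: int = 0
    both_barcodes_valid_pairs: int = 0
    per_sample_counts: Counter = field(default_factory=Counter)
    unassigned_breakdown: Counter = field(default_factory=Counter)

    @property
    def barcode_filtration_rate(self) -> float:
        """Fraction of pairs assigned to a sheet sample."""
        return self.assigned_pairs / self.total_pairs if self.total_pairs else 0.0

    @property
    def both_barcodes_valid_rate(self) -> float:
        """Fraction of pairs with both barcodes whitelist-assignable."""
        return self.both_barcodes_valid_pairs / self.total_pairs if self.total_pairs else 0.0

    def validate(self) -> None:
        unassigned = sum(self.unassigned_breakdown.values())
        if self.assigned_pairs + unassigned != self.total_pairs:
            raise AssertionError("demux outcome counts do not sum to input pairs")
        if sum(self.per_sample_counts.values()) != self.assigned_pairs:
            raise AssertionError("per-sample counts do not sum to assigned pairs")

    def to_dict(self) -> dict:
        self.validate()
        return {
            "total_pairs": self.total_pairs,
            "assigned_pairs": self.assigned_pairs,
            "both_barcodes_valid_pairs": self.both_barcodes_valid_pairs,
            "barcode_filtration_rate": self.barcode_filtration_rate,
            "both_barcodes_valid_rate": self.both_barcodes_valid_rate,
            "per_sample_counts": dict(self.per_sample_counts),
            "unassigned_breakdown": {k: self.unassigned_breakdown.get(k, 0) for k in UNASSIGNED_REASONS},
        }


def demultiplex_stream(
    pairs: Iterable[ReadPair],
    set_a: BarcodeSet,
    set_b: BarcodeSet,
    sheet: SampleSheet,
    config: DemuxConfig = DemuxConfig(),
) -> tuple[list[DecodedRead], DemuxStats]:
    """Decode a stream of raw pairs into per-sample records plus statistics."""
    sheet.validate_against(set_a, set_b)
    lookup = sheet.lookup()
    stats = DemuxStats()
    records: list[DecodedRead] = []
    for pair in pairs:
        stats.total_pairs += 1
        if config.check_me and not me_structure_ok(
            pair, config.mosaic_end, config.me_max_mismatch
        ):
            stats.unassigned_breakdown[FAIL_STRUCTURE] += 1
            continue
        restructured = restructure_pair(pair)
        if restructured is None:
            stats.unassigned_breakdown[FAIL_STRUCTURE] += 1
            continue
        tags = extract_tags(restructured, restructured=True)
        if tags is None:
            stats.unassigned_breakdown[FAIL_STRUCTURE] += 1
            continue
        a_idx, _ = correct_barcode(
            tags.barcode_a_raw, set_a, config.max_barcode_dist, config.max_n_in_barcode
        )
        b_idx, _ = correct_barcode(
            tags.barcode_b_raw, set_b, config.max_barcode_dist, config.max_n_in_barcode
        )
        if a_idx is not None and b_idx is not None:
            stats.both_barcodes_valid_pairs += 1
        if a_idx is None:
            stats.unassigned_breakdown[BAD_A] += 1
            continue
        if b_idx is None:
            stats.unassigned_breakdown[BAD_B] += 1
            continue
        if not quality_filter_tags(restructured, config.min_tag_quality, restructured=True):
            stats.unassigned_breakdown[FAIL_QUALITY] += 1
            continue
        sample = lookup.get((a_idx, b_idx))
        if sample is None:
            stats.unassigned_breakdown[PAIR_NOT_IN_SHEET] += 1
            continue
        seq, qual = restructured.r2_seq, restructured.r2_qual
        if config.trim_readthrough:
            seq, qual = trim_me_readthrough(seq, qual, config.mosaic_end)
        if config.trim_polya:
            seq, qual = trim_polya(seq, qual, config.polya_min_run, config.polya_max_mismatch)
        r1_seq = r1_qual = None
        if config.keep_r1_insert:
            from .seqs import R1_TECH_PREFIX

            r1_seq = pair.r1_seq[R1_TECH_PREFIX:]
            r1_qual = pair.r1_qual[R1_TECH_PREFIX:]
            if config.trim_readthrough:
                r1_seq, r1_qual = trim_me_readthrough(r1_seq, r1_qual, config.mosaic_end)
            if config.trim_polya:
                r1_seq, r1_qual = trim_polya(
                    r1_seq, r1_qual, config.polya_min_run, config.polya_max_mismatch
                )
        stats.assigned_pairs += 1
        stats.per_sample_counts[sample] += 1
        records.append(
            DecodedRead(pair.read_id, sample, a_idx, b_idx, tags.umi, seq, qual, r1_seq, r1_qual)
        )
    stats.validate()
    return records, stats


def per_base_composition(seqs: Iterable[str], n_positions: int) -> pd.DataFrame:
    """Position x {A,C,G,T,N} base-fraction matrix over the first
    ``n_positions`` cycles; rows sum to 1 over reads long enough to cover
    the position.  Raises on an empty stream."""
    letters = "ACGTN"
    counts = np.zeros((n_positions, len(letters)), dtype=np.int64)
    n_reads = 0
    for seq in seqs:
        n_reads += 1
        upto = min(len(seq), n_positions)
        for i in range(upto):
            j = letters.find(seq[i])
            counts[i, j if j >= 0 else 4] += 1
    if n_reads == 0:
        raise ValueError("no reads")
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        frac = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    return pd.DataFrame(frac, columns=list(letters), index=pd.RangeIndex(n_positions, name="position"))
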