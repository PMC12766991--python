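"""Quality metrics: gene-body coverage, 3'/5' bias, species mixing, reports.

Gene-body coverage follows the percentile-bin convention: each fragment
interval is projected onto 100 bins spanning its transcript 5'->3', each
transcript's binned mass is normalised to 1, and profiles are averaged
over transcripts.  A flat profile (0.01 per bin) indicates unbiased
full-length capture; the bias index — mean of the 3'-most quintile over
the 5'-most quintile — is 1 for a flat profile and grows with
3'-degradation.

Species-mixing ("barnyard") calls: a sample whose minor-species fraction
exceeds the threshold (strictly more than 20% by default) is MIXED,
flagging doublets or cross-contamination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .demux import DemuxStats
from .quant import ExpressionMatrix
from .simulate import Transcriptome

N_COVERAGE_BINS = 100


@dataclass(frozen=True)
class CoverageProfile:
    bins: np.ndarray  # 100 mean normalised-coverage values, 5'->3'
    n_transcripts: int

    def __post_init__(self) -> None:
        bins = np.asarray(self.bins, dtype=float)
        object.__setattr__(self, "bins", bins)
        if bins.shape != (N_COVERAGE_BINS,):
            raise ValueError(f"profile must have {N_COVERAGE_BINS} bins")
        if abs(bins.sum() - 1.0) > 1e-9:
            raise ValueError("profile bins must sum to 1")


def gene_body_coverage(
    assignments: pd.DataFrame,
    transcriptome: Transcriptome,
    min_len: int = 500,
) -> CoverageProfile:
    """Average percentile-bin coverage over transcripts >= ``min_len`` nt.

    ``assignments`` needs ``transcript_id``, ``start`` and ``end`` columns
    (transcript-coordinate half-open intervals); rows without a transcript
    are ignored.  Intervals are clipped to the transcript body, so
    poly(A)-tail overhang does not contribute.
    """
    lengths = {r.transcript_id: len(r.sequence) for r in transcriptome.records}
    per_transcript: dict[str, np.ndarray] = {}
    cols = assignments[["transcript_id", "start", "end"]].dropna()
    for tid, start, end in cols.itertuples(index=False):
        tlen = lengths.get(tid)
        if tlen is None or tlen < min_len:
            continue
        s = max(0.0, float(start))
        e = min(float(tlen), float(end))
        if e <= s:
            continue
        profile = per_transcript.setdefault(tid, np.zeros(N_COVERAGE_BINS))
        # fractional overlap of [s, e) with each percentile bin
        edges = np.linspace(0, tlen, N_COVERAGE_BINS + 1)
        lo = np.clip(edges[:-1], s, e)
        hi = np.clip(edges[1:], s, e)
        profile += hi - lo
    if not per_transcript:
        raise ValueError("no eligible transcripts with coverage")
    stacked = np.stack([p / p.sum() for p in per_transcript.values()])
    mean = stacked.mean(axis=0)
    return CoverageProfile(mean / mean.sum(), n_transcripts=len(per_transcript))


def coverage_bias_index(profile: CoverageProfile) -> float:
    """3'-quintile / 5'-quintile mean-coverage ratio; 1.0 when flat,
    ``inf`` when the 5' quintile holds no mass."""
    five = profile.bins[:20].mean()
    three = profile.bins[80:].mean()
    if five == 0:
        return float("inf")
    return float(three / five)


UNDETERMINED = "UNDETERMINED"
MIXED = "MIXED"


@dataclass(frozen=True)
class BarnyardCall:
    sample_id: str
    human_count: int
    mouse_count: int
    minor_fraction: float
    call: str  # HUMAN | MOUSE | MIXED | UNDETERMINED


def barnyard_classify(
    matrix: ExpressionMatrix,
    threshold: float = 0.20,
    species_of: Optional[dict[str, str]] = None,
) -> list[BarnyardCall]:
    """Classify each sample by its two-species UMI split.

    A sample is MIXED when strictly more than ``threshold`` of its counts
    belong to the minor species; exactly at the threshold it keeps its
    major-species call.  Gene species default to the id prefix before the
    first underscore; every gene must resolve to one of exactly two species.
    """
    if species_of is None:
        species_of = {g: g.split("_", 1)[0] for g in matrix.gene_ids}
    labels = sorted({species_of[g] for g in matrix.gene_ids})
    if len(labels) != 2:
        raise ValueError(f"expected exactly two species labels, got {labels}")
    sp_a, sp_b = labels
    mask_a = np.array([species_of[g] == sp_a for g in matrix.gene_ids])
    calls = []
    for j, sample in enumerate(matrix.sample_ids):
        col = matrix.counts[:, j]
        count_a = int(col[mask_a].sum())
        count_b = int(col[~mask_a].sum())
        total = count_a + count_b
        human = count_a if sp_a == "HUMAN" else count_b
        mouse = count_b if sp_a == "HUMAN" else count_a
        if total == 0:
            calls.append(BarnyardCall(sample, human, mouse, 0.0, UNDETERMINED))
            continue
        minor = min(count_a, count_b) / total
        if minor > threshold:
            call = MIXED
        else:
            call = sp_a if count_a >= count_b else sp_b
        calls.append(BarnyardCall(sample, human, mouse, minor, call))
    return calls


REQUIRED_REPORT_SECTIONS = ("demux", "expression", "coverage", "barnyard")


def qc_report(
    stats: DemuxStats,
    matrix: ExpressionMatrix,
    profile: Optional[CoverageProfile] = None,
    calls: Optional[Iterable[BarnyardCall]] = None,
) -> dict:
    """Aggregate all metrics into one JSON-serialisable report."""
    report = {
        "demux": stats.to_dict(),
        "expression": {
            "n_genes": len(matrix.gene_ids),
            "n_samples": len(matrix.sample_ids),
            "total_umis": matrix.total,
            "per_sample_umis": matrix.per_sample_totals(),
            "genes_detected_per_sample": {
                s: int((matrix.counts[:, j] > 0).sum())
                for j, s in enumerate(matrix.sample_ids)
            },
            "dedup_policy": matrix.policy,
        },
        "coverage": (
            {
                "bins": [float(x) for x in profile.bins],
                "bias_index": coverage_bias_index(profile),
                "n_transcripts": profile.n_transcripts,
            }
            if profile is not None
            else None
        ),
        "barnyard": (
            [
                {
                    "sample_id": c.sample_id,
                    "human_count": c.human_count,
                    "mouse_count": c.mouse_count,
                    "minor_fraction": c.minor_fraction,
                    "call": c.call,
                }
                for c in calls
            ]
            if calls is not None
            else None
        ),
    }
    validate_qc_report(report)
    return report


def validate_qc_report(report: dict) -> None:
    missing = [k for k in REQUIRED_REPORT_SECTIONS if k not in report]
    if missing:
        raise ValueError(f"qc report missing sections {missing}")
    demux = report["demux"]
    for key in ("total_pairs", "assigned_pairs", "barcode_filtration_rate"):
        if key not in demux:
            raise ValueError(f"qc report demux section missing {key}")
    json.dumps(report)  # must be serialisable


def write_coverage_tsv(profile: CoverageProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"bin": np.arange(N_COVERAGE_BINS), "mean_coverage": profile.bins}
    ).to_csv(path, sep="\t", index=False)


def plot_coverage(profile: CoverageProfile, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(np.arange(N_COVERAGE_BINS), profile.bins)
    ax.set_xlabel("gene body percentile (5'->3')")
    ax.set_ylabel("mean normalised coverage")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_barnyard(calls: Iterable[BarnyardCall], path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    calls = list(calls)
    colors = {"HUMAN": "tab:blue", "MOUSE": "tab:red", MIXED: "gray", UNDETERMINED: "black"}
    fig, ax = plt.subplots(figsize=(4, 4))
    for c in calls:
        ax.scatter(c.human_count, c.mouse_count, c=colors.get(c.call, "green"), s=18)
    ax.set_xlabel("human UMIs")
    ax.set_ylabel("mouse UMIs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
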