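"""Transcript assignment by k-mer voting and UMI-deduplicated expression.

The built-in matcher replaces a genomic aligner for desk-scale,
self-contained work: an exact k-mer index over both strands of the
transcriptome, and a majority vote across the insert's k-mers.  The
winning gene needs at least ``min_votes`` and more than twice the
runner-up's votes, otherwise the read is AMBIGUOUS.  Votes are pooled at
the gene level first; the transcript is reported when a single isoform
wins within the winning gene.

Deduplication: a 6-nt UMI has only 4096 states and collides quickly
within a deeply covered gene, so the default policy (``umi_pos``) keys on
(sample, gene, UMI, fragment-start rounded to 10 nt).  The ``umi`` policy
counts plain (sample, gene, UMI) triples for strict digital-expression
semantics.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .demux import DecodedRead
from .seqs import revcomp
from .simulate import Transcriptome

UNMAPPED = "unmapped"
AMBIGUOUS = "ambiguous"
TOO_SHORT = "too_short"
MAPPED = "mapped"

ASSIGNMENT_COLUMNS = [
    "read_id", "sample_id", "umi", "status",
    "gene_id", "transcript_id", "strand", "start", "end",
]


@dataclass(frozen=True)
class KmerIndex:
    k: int
    #: k-mer -> tuple of (transcript index, forward offset)
    lookup: dict
    transcript_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    lengths: tuple[int, ...]


def build_kmer_index(transcriptome: Transcriptome, k: int = 21) -> KmerIndex:
    """Forward-strand exact k-mer index; the reverse strand is matched by
    querying the reverse complement of the read."""
    if k > int(transcriptome.lengths.min()):
        raise ValueError(f"k={k} exceeds shortest transcript")
    ids = [r.transcript_id for r in transcriptome.records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids")
    lookup: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for t_idx, rec in enumerate(transcriptome.records):
        seq = rec.sequence
        for off in range(len(seq) - k + 1):
            lookup[seq[off : off + k]].append((t_idx, off))
    return KmerIndex(
        k=k,
        lookup={km: tuple(v) for km, v in lookup.items()},
        transcript_ids=tuple(ids),
        gene_ids=tuple(r.gene_id for r in transcriptome.records),
        lengths=tuple(int(x) for x in transcriptome.lengths),
    )


def assign_transcript(
    insert: str, idx: KmerIndex, min_votes: int = 3
) -> tuple[str, Optional[str], Optional[str], Optional[str], Optional[int], Optional[int]]:
    """Vote the insert onto a gene.

    Returns ``(status, gene_id, transcript_id, strand, start, end)`` with
    transcript coordinates of the insert on the forward strand.  ``status``
    is one of mapped / unmapped / ambiguous / too_short.
    """
    k = idx.k
    if len(insert) < k:
        return TOO_SHORT, None, None, None, None, None
    gene_votes: Counter = Counter()
    # per (gene, strand): transcript-level diagonal tallies
    diag_votes: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for strand, seq in (("+", insert), ("-", revcomp(insert))):
        for p in range(len(seq) - k + 1):
            for t_idx, off in idx.lookup.get(seq[p : p + k], ()):
                gene = idx.gene_ids[t_idx]
                gene_votes[(gene, strand)] += 1
                diag_votes[(gene, strand)][(t_idx, off - p)] += 1
    if not gene_votes:
        return UNMAPPED, None, None, None, None, None
    ranked = gene_votes.most_common()
    (gene, strand), top = ranked[0]
    runner = ranked[1][1] if len(ranked) > 1 else 0
    if top < min_votes or top <= 2 * runner:
        return AMBIGUOUS, None, None, None, None, None
    per_transcript: Counter = Counter()
    for (t_idx, _), v in diag_votes[(gene, strand)].items():
        per_transcript[t_idx] += v
    best_transcripts = per_transcript.most_common()
    t_idx = best_transcripts[0][0]
    unique_isoform = len(best_transcripts) == 1 or (
        best_transcripts[0][1] > best_transcripts[1][1]
    )
    diag = Counter(
        {d: v for (ti, d), v in diag_votes[(gene, strand)].items() if ti == t_idx}
    ).most_common(1)[0][0]
    if strand == "+":
        start = diag
        end = diag + len(insert)
    else:
        # rc(insert) matched forward at offset `diag`
        start = diag
        end = diag + len(insert)
    return (
        MAPPED,
        gene,
        idx.transcript_ids[t_idx] if unique_isoform else None,
        strand,
        int(start),
        int(end),
    )


def assign_reads(
    records: Iterable[DecodedRead], idx: KmerIndex, min_votes: int = 3
) -> pd.DataFrame:
    """Assign a stream of decoded reads; one row per read."""
    rows = []
    for r in records:
        status, gene, transcript, strand, start, end = assign_transcript(
            r.seq, idx, min_votes
        )
        rows.append(
            (r.read_id, r.sample_id, r.umi, status, gene, transcript, strand, start, end)
        )
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of UMI-deduplicated fragment counts."""

    counts: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    policy: str = "umi_pos"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match labels")
        if (counts < 0).any():
            raise ValueError("negative counts")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_sample_totals(self) -> dict[str, int]:
        return {s: int(self.counts[:, j].sum()) for j, s in enumerate(self.sample_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.gene_ids), columns=list(self.sample_ids))


DEDUP_POSITION_BIN = 10


def count_umis(
    assignments: pd.DataFrame,
    policy: str = "umi_pos",
    gene_ids: Optional[Iterable[str]] = None,
    sample_ids: Optional[Iterable[str]] = None,
) -> ExpressionMatrix:
    """Collapse mapped assignments into a digital expression matrix.

    ``umi``: distinct (sample, gene, UMI); ``umi_pos`` (default): distinct
    (sample, gene, UMI, start//10).  Row/column universes default to the
    genes and samples observed, or can be fixed explicitly (e.g. to the
    transcriptome and sample sheet) so empty rows are preserved.
    """
    if policy not in ("umi", "umi_pos"):
        raise ValueError(f"unknown dedup policy {policy!r}")
    mapped = assignments[assignments["status"] == MAPPED].copy()
    keys = ["sample_id", "gene_id", "umi"]
    if policy == "umi_pos":
        mapped["pos_bin"] = (mapped["start"].astype(np.int64) // DEDUP_POSITION_BIN)
        keys.append("pos_bin")
    dedup = mapped.drop_duplicates(subset=keys)
    genes = list(gene_ids) if gene_ids is not None else sorted(dedup["gene_id"].unique())
    samples = list(sample_ids) if sample_ids is not None else sorted(dedup["sample_id"].unique())
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: j for j, s in enumerate(samples)}
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    grouped = dedup.groupby(["gene_id", "sample_id"]).size()
    for (g, s), n in grouped.items():
        if g in gi and s in si:
            counts[gi[g], si[s]] = n
    return ExpressionMatrix(counts, tuple(genes), tuple(samples), policy)


def downsample_saturation(
    assignments: pd.DataFrame,
    fractions: Iterable[float],
    seed: int = 0,
    policy: str = "umi_pos",
) -> pd.DataFrame:
    """Genes and unique UMIs detected per sample at nested read subsamples.

    Nested sampling (one uniform draw per read, threshold at each fraction)
    makes detection monotone in the fraction for a fixed seed.
    """
    fractions = sorted(set(float(f) for f in fractions))
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.random(len(assignments))
    rows = []
    for f in fractions:
        sub = assignments[u < f] if f < 1.0 else assignments
        mat = count_umis(sub, policy=policy)
        for j, s in enumerate(mat.sample_ids):
            col = mat.counts[:, j]
            rows.append((f, s, int((col > 0).sum()), int(col.sum())))
    return pd.DataFrame(rows, columns=["fraction", "sample_id", "genes_detected", "unique_umis"])


def write_matrix(matrix: ExpressionMatrix, out_dir: str | Path) -> None:
    """MatrixMarket triple: matrix.mtx + genes.tsv + samples.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(out / "matrix.mtx"),
        scipy.sparse.coo_matrix(matrix.counts),
        field="integer",
        comment=f"dedup policy: {matrix.policy}",
    )
    pd.Series(list(matrix.gene_ids)).to_csv(out / "genes.tsv", index=False, header=False)
    pd.Series(list(matrix.sample_ids)).to_csv(out / "samples.tsv", index=False, header=False)
    (out / "policy.txt").write_text(matrix.policy + "\n")


def read_matrix(in_dir: str | Path) -> ExpressionMatrix:
    out = Path(in_dir)
    counts = np.asarray(scipy.io.mmread(str(out / "matrix.mtx")).todense(), dtype=np.int64)
    genes = pd.read_csv(out / "genes.tsv", header=None)[0].astype(str).tolist() if counts.shape[0] else []
    samples = pd.read_csv(out / "samples.tsv", header=None)[0].astype(str).tolist() if counts.shape[1] else []
    policy_file = out / "policy.txt"
    policy = policy_file.read_text().strip() if policy_file.exists() else "umi_pos"
    if counts.shape != (len(genes), len(samples)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match labels ({len(genes)}, {len(samples)})"
        )
    return ExpressionMatrix(counts, tuple(genes), tuple(samples), policy)


def write_matrix_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_matrix_tsv(path: str | Path, policy: str = "umi_pos") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionMatrix(
        df.to_numpy(dtype=np.int64), tuple(df.index.astype(str)), tuple(df.columns.astype(str)), policy
    )
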