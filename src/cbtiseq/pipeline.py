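"""End-to-end pipeline: simulate -> decode/demux -> quant -> qc.

A single YAML-configurable run that chains the library stages and writes
every artifact with a checksum manifest.  Outputs are deterministic for a
fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import barcodes, demux, io, qc, quant, simulate


@dataclass
class RunConfig:
    """Pipeline parameters; unknown keys in a config file are rejected."""

    seed: int = 0
    n_samples: int = 4
    n_genes: int = 40
    reads_per_sample: int = 1000
    barcode_k_a: int = 10
    barcode_k_b: int = 10
    min_dist: int = barcodes.DESIGN_MIN_DIST
    sheet_layout: str = "diagonal"  # diagonal | full
    mean_transcript_length: int = 2000
    fragment_length_mean: float = 400.0
    fragment_length_sd: float = 75.0
    fragment_length_bounds: tuple[int, int] = (150, 800)
    substitution_error_rate: float = 0.002
    polya_length: int = 90
    degradation_bias: float = 0.0
    species_mix: Optional[tuple[int, int]] = None
    dedup_policy: str = "umi_pos"
    kmer_size: int = 21
    min_votes: int = 3
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fragment_length_bounds" in raw:
            raw["fragment_length_bounds"] = tuple(raw["fragment_length_bounds"])
        if raw.get("species_mix") is not None:
            raw["species_mix"] = tuple(raw["species_mix"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage, write artifacts + manifest, return the QC report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(cfg.seed)
    seeds = root_rng.integers(0, 2**31 - 1, size=4)

    set_a = barcodes.generate_barcode_set(
        cfg.barcode_k_a, min_dist=cfg.min_dist, seed=int(seeds[0]), name="A"
    )
    set_b = barcodes.generate_barcode_set(
        cfg.barcode_k_b, min_dist=cfg.min_dist, seed=int(seeds[1]), name="B",
        exclude=set_a.barcodes,
    )
    barcodes.write_whitelist(set_a, out / "whitelist_A.txt")
    barcodes.write_whitelist(set_b, out / "whitelist_B.txt")

    if cfg.sheet_layout == "full":
        sheet = barcodes.SampleSheet.full(cfg.barcode_k_a, cfg.barcode_k_b)
        sheet = barcodes.SampleSheet(sheet.entries[: cfg.n_samples])
    else:
        sheet = barcodes.SampleSheet.diagonal(cfg.n_samples)
    sheet.to_csv(out / "samplesheet.csv")

    transcriptome = simulate.make_transcriptome(
        cfg.n_genes,
        mean_length=cfg.mean_transcript_length,
        species_mix=cfg.species_mix,
        seed=int(seeds[2]),
    )
    transcriptome.write_fasta(out / "transcriptome.fasta")

    sim_cfg = simulate.SimConfig(
        reads_per_sample=cfg.reads_per_sample,
        fragment_length_mean=cfg.fragment_length_mean,
        fragment_length_sd=cfg.fragment_length_sd,
        fragment_length_bounds=cfg.fragment_length_bounds,
        substitution_error_rate=cfg.substitution_error_rate,
        polya_length=cfg.polya_length,
        degradation_bias=cfg.degradation_bias,
        seed=int(seeds[3]),
    )
    pairs, truth = simulate.simulate_library(transcriptome, sheet, set_a, set_b, sim_cfg)
    io.write_fastq_pairs(pairs, out / "reads_R1.fastq", out / "reads_R2.fastq")
    simulate.write_truth(truth, out / "truth.tsv")

    records, stats = demux.demultiplex_stream(pairs, set_a, set_b, sheet)
    io.write_decoded(records, out / "decoded.tsv")
    (out / "demux_stats.json").write_text(json.dumps(stats.to_dict(), indent=2))

    idx = quant.build_kmer_index(transcriptome, k=cfg.kmer_size)
    assignments = quant.assign_reads(records, idx, min_votes=cfg.min_votes)
    matrix = quant.count_umis(
        assignments,
        policy=cfg.dedup_policy,
        gene_ids=[r.gene_id for r in transcriptome.records],
        sample_ids=sheet.sample_ids,
    )
    quant.write_matrix(matrix, out / "matrix")

    profile = qc.gene_body_coverage(assignments, transcriptome)
    qc.write_coverage_tsv(profile, out / "coverage.tsv")
    calls = None
    if cfg.species_mix is not None:
        calls = qc.barnyard_classify(matrix)
    report = qc.qc_report(stats, matrix, profile, calls)
    (out / "qc_report.json").write_text(json.dumps(report, indent=2))

    if cfg.plots:
        qc.plot_coverage(profile, out / "coverage.png")
        if calls is not None:
            qc.plot_barnyard(calls, out / "barnyard.png")

    artifacts = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {str(p.relative_to(out)): _sha256(p) for p in artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
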