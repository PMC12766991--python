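"""Synthetic transcriptomes and barcoded-Tn5 paired-end read simulation.

The simulator emulates tagmentation of pre-amplified full-length cDNA:
each transcript template (transcript sequence plus a poly(A) tail) is cut
into fragments whose lengths follow a truncated normal matching the
300-500 bp product range of the real chemistry, each fragment receives the
A adapter on one end and the B adapter (with a random 6-nt UMI) on the
other, and both ends are sequenced inward.

Fragment placement models a uniform tagmentation cut density: the start is
drawn uniformly over every position at which the fragment overlaps the
template, and the fragment is clipped at the template ends.  Under this
model every base of the template is covered with equal probability, so the
simulator provides an exactly flat null for the gene-body-coverage metric;
end fragments are treated as sequenceable (see the methods note for what
this deliberately ignores).  Products shorter than ``min_fragment_length``
are redrawn, mimicking bead size selection.  A 3'-degradation bias ``delta``
reweights placement by ``exp(delta * relative_position)``, shifting mass
toward the poly(A) end as degraded samples do.

Reads:

* R1 = ``barcode_A + ME + insert`` read from the A-proximal fragment end;
* R2 = ``barcode_B + UMI + ME + insert`` read from the B-proximal end on
  the opposite strand;

with substitution errors applied i.i.d. at the configured per-base rate.
Only A-B fragments are emitted: in the real protocol only fragments with
one A and one B adapter amplify during indexing PCR.  Reads shorter than
the library molecule run through into the opposite adapter and then into a
constant downstream flank, exactly what the read-through trimmer removes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .barcodes import BarcodeSet, SampleSheet
from .readproc import PHRED_OFFSET, ReadPair
from .seqs import MOSAIC_END, UMI_LENGTH, ints_to_kmers, revcomp

#: Sequence a read runs into after the library molecule (i7-side flank).
DOWNSTREAM_FLANK = "ATCTCGTATGCCGTCTTCTGCTTGAAAAAAAAGGGGTACTCCGGTT"

QUAL_GOOD = chr(PHRED_OFFSET + 37)   # 'F'
QUAL_ERROR = chr(PHRED_OFFSET + 14)  # '/'


@dataclass(frozen=True)
class TranscriptRecord:
    gene_id: str
    transcript_id: str
    sequence: str
    biotype: str = "protein_coding"
    species: str = "none"


@dataclass(frozen=True)
class Transcriptome:
    records: tuple[TranscriptRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.transcript_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript ids")
        for r in self.records:
            if len(r.sequence) < 200:
                raise ValueError(f"{r.transcript_id}: transcripts must be >= 200 nt")
            if set(r.sequence) - set("ACGT"):
                raise ValueError(f"{r.transcript_id}: non-ACGT symbols")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(r.sequence) for r in self.records])

    def gene_of(self) -> dict[str, str]:
        return {r.transcript_id: r.gene_id for r in self.records}

    def species_of(self) -> dict[str, str]:
        return {r.gene_id: r.species for r in self.records}

    def write_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(
                Seq(r.sequence),
                id=r.transcript_id,
                description=f"gene={r.gene_id} biotype={r.biotype} species={r.species}",
            )
            for r in self.records
        ]
        SeqIO.write(recs, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Transcriptome":
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            attrs = dict(
                kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
            )
            records.append(
                TranscriptRecord(
                    gene_id=attrs.get("gene", rec.id),
                    transcript_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    biotype=attrs.get("biotype", "protein_coding"),
                    species=attrs.get("species", "none"),
                )
            )
        return cls(tuple(records))


def make_transcriptome(
    n_genes: int,
    mean_length: int = 2000,
    sd_length: int = 400,
    min_length: int = 500,
    species_mix: Optional[tuple[int, int]] = None,
    lncrna_fraction: float = 0.1,
    seed: int = 0,
) -> Transcriptome:
    """Random transcriptome, one transcript per gene, deterministic per seed.

    With ``species_mix = (n_human, n_mouse)`` gene ids carry ``HUMAN_`` /
    ``MOUSE_`` prefixes for barnyard experiments (``n_genes`` is ignored in
    favour of the mix sizes).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    if species_mix is not None:
        labels = ["HUMAN"] * species_mix[0] + ["MOUSE"] * species_mix[1]
    else:
        labels = ["none"] * n_genes
    records = []
    counters: dict[str, int] = {}
    for sp in labels:
        counters[sp] = counters.get(sp, 0) + 1
        i = counters[sp]
        prefix = f"{sp}_" if sp != "none" else ""
        length = int(np.clip(rng.normal(mean_length, sd_length), min_length, None))
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
        biotype = "lncRNA" if rng.random() < lncrna_fraction else "protein_coding"
        gid = f"{prefix}G{i:04d}"
        records.append(TranscriptRecord(gid, f"{gid}.T1", seq, biotype, sp))
    return Transcriptome(tuple(records))


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults mirror the measured chemistry.

    Fragment sizing follows the observed 300-500 bp tagmentation products
    (truncated normal, mean 400 nt, sd 75 nt, bounds 150-800 nt); reads are
    150 nt; UMIs are 6 nt; the substitution error rate defaults to 0.002
    per base, a typical patterned-flow-cell value.
    """

    reads_per_sample: int = 2000
    fragment_length_mean: float = 400.0
    fragment_length_sd: float = 75.0
    fragment_length_bounds: tuple[int, int] = (150, 800)
    min_fragment_length: int = 30
    read_length: int = 150
    substitution_error_rate: float = 0.0
    umi_length: int = UMI_LENGTH
    polya_length: int = 90
    degradation_bias: float = 0.0
    expression_dispersion: float = 1.0
    unique_umis: bool = False
    mosaic_end: str = MOSAIC_END
    seed: int = 0

    def validate(self, transcriptome: Transcriptome) -> None:
        if not (0 <= self.substitution_error_rate < 0.25):
            raise ValueError("substitution_error_rate must be in [0, 0.25)")
        if self.read_length <= 33:
            raise ValueError("read_length must exceed the 33-nt technical prefix")
        lo, hi = self.fragment_length_bounds
        if not (0 < lo <= hi):
            raise ValueError("bad fragment_length_bounds")
        shortest = int(transcriptome.lengths.min()) + self.polya_length
        if hi > shortest:
            raise ValueError(
                f"fragment bound {hi} exceeds shortest template ({shortest} nt)"
            )
        if self.degradation_bias < 0:
            raise ValueError("degradation_bias must be >= 0")
        if self.min_fragment_length < 1:
            raise ValueError("min_fragment_length must be >= 1")


TRUTH_COLUMNS = [
    "read_id",
    "sample_id",
    "gene_id",
    "transcript_id",
    "frag_start",
    "frag_end",
    "umi",
    "orientation",
    "a_index",
    "b_index",
]


def _truncnorm_lengths(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.fragment_length_bounds
    a = (lo - cfg.fragment_length_mean) / cfg.fragment_length_sd
    b = (hi - cfg.fragment_length_mean) / cfg.fragment_length_sd
    draws = stats.truncnorm.rvs(
        a, b, loc=cfg.fragment_length_mean, scale=cfg.fragment_length_sd,
        size=n, random_state=rng,
    )
    return np.round(draws).astype(np.int64)


def _draw_starts(
    u: np.ndarray, frag_len: np.ndarray, template_len: np.ndarray, delta: float
) -> np.ndarray:
    """Start positions over the extended range [-(L-1), T-1].

    Uniform when ``delta`` is 0; otherwise the inverse CDF of the density
    proportional to exp(delta * relative_position) tilts mass 3'-ward.
    """
    span = template_len + frag_len - 1  # number of admissible start positions
    if delta > 0:
        rel = np.log1p(u * np.expm1(delta)) / delta
    else:
        rel = u
    return -(frag_len - 1) + np.minimum((rel * span).astype(np.int64), span - 1)


def _apply_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, str]:
    n = len(seq)
    if rate <= 0:
        return seq, QUAL_GOOD * n
    n_err = rng.binomial(n, rate)
    if n_err == 0:
        return seq, QUAL_GOOD * n
    positions = rng.choice(n, size=n_err, replace=False)
    chars = list(seq)
    quals = [QUAL_GOOD] * n
    for p in positions:
        alternatives = [c for c in "ACGT" if c != chars[p]]
        chars[p] = alternatives[rng.integers(0, 3)]
        quals[p] = QUAL_ERROR
    return "".join(chars), "".join(quals)


def simulate_library(
    transcriptome: Transcriptome,
    sheet: SampleSheet,
    set_a: BarcodeSet,
    set_b: BarcodeSet,
    cfg: SimConfig,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate an equimolar pooled library; returns (pairs, ground truth).

    Pooling is multinomial: each fragment's sample is drawn uniformly at
    random, so per-sample depths fluctuate binomially around
    ``reads_per_sample`` exactly as molecules sampled from a pooled library
    do.  Per-sample transcript abundances are log-normal with dispersion
    ``expression_dispersion``.
    """
    cfg.validate(transcriptome)
    sheet.validate_against(set_a, set_b)
    rng = np.random.default_rng(cfg.seed)

    n_samples = len(sheet.entries)
    total = n_samples * cfg.reads_per_sample
    templates = [r.sequence + "A" * cfg.polya_length for r in transcriptome.records]
    tlens = np.array([len(t) for t in templates])
    n_tr = len(templates)

    # per-sample transcript abundances (log-normal, renormalised)
    weights = rng.lognormal(0.0, cfg.expression_dispersion, size=(n_samples, n_tr))
    weights /= weights.sum(axis=1, keepdims=True)

    sample_idx = rng.integers(0, n_samples, size=total)
    tr_idx = np.empty(total, dtype=np.int64)
    for s in range(n_samples):
        mask = sample_idx == s
        tr_idx[mask] = rng.choice(n_tr, size=int(mask.sum()), p=weights[s])

    frag_len = _truncnorm_lengths(cfg, total, rng)
    tlen_i = tlens[tr_idx]
    starts = _draw_starts(rng.random(total), frag_len, tlen_i, cfg.degradation_bias)
    fs = np.maximum(starts, 0)
    fe = np.minimum(starts + frag_len, tlen_i)
    # redraw clipped fragments below the size-selection floor
    for _ in range(200):
        bad = fe - fs < cfg.min_fragment_length
        if not bad.any():
            break
        nb = int(bad.sum())
        st = _draw_starts(rng.random(nb), frag_len[bad], tlen_i[bad], cfg.degradation_bias)
        fs[bad] = np.maximum(st, 0)
        fe[bad] = np.minimum(st + frag_len[bad], tlen_i[bad])
    else:
        raise RuntimeError("could not place fragments above min_fragment_length")

    orientation = rng.integers(0, 2, size=total)  # 0: A on the left template end
    if cfg.unique_umis:
        umi_codes = np.empty(total, dtype=np.int64)
        df_groups = pd.DataFrame({"s": sample_idx, "t": tr_idx}).groupby(["s", "t"]).indices
        space = 4**cfg.umi_length
        for _, idx in df_groups.items():
            if len(idx) > space:
                raise ValueError("more fragments than distinct UMIs in one gene")
            umi_codes[idx] = rng.choice(space, size=len(idx), replace=False)
    else:
        umi_codes = rng.integers(0, 4**cfg.umi_length, size=total)
    umis = ints_to_kmers(umi_codes, cfg.umi_length)

    entries = sheet.entries
    me = cfg.mosaic_end
    rc_me = revcomp(me)
    rl = cfg.read_length
    flank = (DOWNSTREAM_FLANK * (rl // len(DOWNSTREAM_FLANK) + 2))

    pairs: list[ReadPair] = []
    truth_rows = []
    for i in range(total):
        e = entries[sample_idx[i]]
        bc_a = set_a[e.a_index]
        bc_b = set_b[e.b_index]
        frag = templates[tr_idx[i]][fs[i] : fe[i]]
        x = frag if orientation[i] == 0 else revcomp(frag)
        umi = umis[i]
        r1 = (bc_a + me + x + rc_me + revcomp(umi) + revcomp(bc_b) + flank)[:rl]
        r2 = (bc_b + umi + me + revcomp(x) + rc_me + revcomp(bc_a) + flank)[:rl]
        r1, q1 = _apply_errors(r1, cfg.substitution_error_rate, rng)
        r2, q2 = _apply_errors(r2, cfg.substitution_error_rate, rng)
        read_id = f"read{i:08d}"
        pairs.append(ReadPair(read_id, r1, q1, r2, q2))
        truth_rows.append(
            (
                read_id,
                e.sample_id,
                transcriptome.records[tr_idx[i]].gene_id,
                transcriptome.records[tr_idx[i]].transcript_id,
                int(fs[i]),
                int(fe[i]),
                umi,
                "A_left" if orientation[i] == 0 else "A_right",
                e.a_index,
                e.b_index,
            )
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return pairs, truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


class TruthFormatError(ValueError):
    pass


def read_truth(path: str | Path) -> pd.DataFrame:
    """Parse a ground-truth TSV, reporting the offending line on error."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise TruthFormatError(f"line 1: bad header {header}")
        for ln, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(TRUTH_COLUMNS):
                raise TruthFormatError(
                    f"line {ln}: expected {len(TRUTH_COLUMNS)} fields, got {len(fields)}"
                )
            try:
                rows.append(
                    (
                        fields[0], fields[1], fields[2], fields[3],
                        int(fields[4]), int(fields[5]),
                        fields[6], fields[7], int(fields[8]), int(fields[9]),
                    )
                )
            except ValueError as exc:
                raise TruthFormatError(f"line {ln}: {exc}") from None
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)
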