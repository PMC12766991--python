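"""FASTQ and decoded-record I/O (gzip-transparent)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .readproc import ReadPair


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream mate-synchronised read pairs; mismatched files are a hard error."""
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for rec1 in it1:
            try:
                rec2 = next(it2)
            except StopIteration:
                raise ValueError("R2 file has fewer reads than R1") from None
            id1 = rec1[0].split()[0]
            id2 = rec2[0].split()[0]
            if id1 != id2:
                raise ValueError(f"mate id mismatch: {id1} vs {id2}")
            yield ReadPair(id1, rec1[1], rec1[2], rec2[1], rec2[2])
        if next(it2, None) is not None:
            raise ValueError("R1 file has fewer reads than R2")


def write_fastq_pairs(
    pairs: Iterable[ReadPair], r1_path: str | Path, r2_path: str | Path
) -> int:
    n = 0
    with _open_text(r1_path, "wt") as f1, _open_text(r2_path, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}\n{p.r1_seq}\n+\n{p.r1_qual}\n")
            f2.write(f"@{p.read_id}\n{p.r2_seq}\n+\n{p.r2_qual}\n")
            n += 1
    return n


DECODED_COLUMNS = ["read_id", "sample_id", "a_index", "b_index", "umi", "seq", "qual"]


def write_decoded(records, path: str | Path) -> None:
    pd.DataFrame(
        [(r.read_id, r.sample_id, r.a_index, r.b_index, r.umi, r.seq, r.qual) for r in records],
        columns=DECODED_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_decoded(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"umi": str, "seq": str, "qual": str})
    missing = set(DECODED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"decoded table missing columns {sorted(missing)}")
    return df
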