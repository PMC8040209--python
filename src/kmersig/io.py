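"""File I/O helpers: gzip-aware FASTQ/FASTA, the shared TSV dialects, JSON.

All tabular interchange uses a single TSV dialect: first column ``feature``
(or ``sample_id`` for per-sample tables), remaining columns data.  FASTQ and
FASTA go through Biopython.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def open_maybe_gzip(path, mode: str = "rt"):
    """Open ``path``, transparently gunzipping if it ends in .gz."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fastq(path) -> Iterator[str]:
    """Yield read sequences (uppercase strings) from a FASTQ(.gz) file.

    A malformed record raises ``ValueError`` naming the file and the
    0-based index of the offending record.
    """
    path = Path(path)
    with open_maybe_gzip(path, "rt") as fh:
        it = SeqIO.parse(fh, "fastq")
        index = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record at index {index} in {path}: {exc}"
                ) from exc
            yield str(rec.seq).upper()
            index += 1


def write_fastq(path, reads: Sequence[str], name_prefix: str = "read") -> None:
    """Write reads to FASTQ(.gz) with uniform dummy qualities."""
    records = (
        SeqRecord(
            Seq(seq),
            id=f"{name_prefix}_{i}",
            description="",
            letter_annotations={"phred_quality": [40] * len(seq)},
        )
        for i, seq in enumerate(reads)
    )
    with open_maybe_gzip(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


def write_fasta(path, entries: Sequence[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as FASTA."""
    records = (SeqRecord(Seq(seq), id=name, description="") for name, seq in entries)
    with open_maybe_gzip(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV: columns sample_id, fastq1, optional fastq2."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "fastq1" not in df.columns:
        raise ValueError("sample sheet needs columns 'sample_id' and 'fastq1'")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sample sheet: {dupes}")
    return df


def write_matrix_tsv(df: pd.DataFrame, path, index_name: str = "feature") -> None:
    out = df.copy()
    out.index.name = index_name
    with open_maybe_gzip(path, "wt") as fh:
        out.to_csv(fh, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    with open_maybe_gzip(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, stable float repr, trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
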