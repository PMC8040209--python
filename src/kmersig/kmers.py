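"""Canonical k-mer counting and the joint recurrence-filtered count matrix.

Counting is exact (no probabilistic sketches) and strand-agnostic: every
length-k window of every read is replaced by its *canonical* form, the
lexicographically smaller of the window and its reverse complement, so that
libraries are treated as unstranded.  k must be odd, which guarantees no
k-mer equals its own reverse complement and the canonical map is
well defined.

The heavy lifting is vectorized: reads are packed into a 2-bit-per-base
integer code (A=0, C=1, G=2, T=3; for k <= 31 a k-mer fits in a uint64) and
forward / reverse-complement codes are built with a rolling update across
read positions, so counting a sample is a handful of numpy passes rather
than a per-window Python loop.  Because the 2-bit alphabet order matches
the lexicographic order of A<C<G<T, ``min(code, rc_code)`` is exactly the
canonical k-mer.

Windows containing any non-ACGT character (e.g. N) are skipped, matching
standard k-mer-counter behaviour; base qualities are ignored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from kmersig.io import open_maybe_gzip, parse_fastq

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte value -> 2-bit code, 255 marks invalid characters
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[ord(chr(_b).lower())] = _i
_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving on ACGT)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(seq: str) -> str:
    """Return the canonical form of ``seq``: min(seq, revcomp(seq)).

    Idempotent, and identical for a k-mer and its reverse complement.
    Raises ``ValueError`` on non-ACGT characters; callers that scan reads
    skip such windows instead.
    """
    if any(c not in "ACGT" for c in seq):
        raise ValueError(f"non-ACGT character in k-mer {seq!r}")
    rc = revcomp(seq)
    return seq if seq <= rc else rc


@dataclass(frozen=True)
class KmerParams:
    """Parameters of the counting stage.

    k
        k-mer length in nt; odd and >= 11 so the canonical map is well
        defined (an odd-length k-mer is never its own reverse complement).
    min_recurrence
        a k-mer is kept only if it reaches ``min_recurrence_abundance`` in
        at least this many samples.
    min_recurrence_abundance
        minimum within-sample count for a sample to support recurrence.
    canonical
        always True in this package; present for provenance.
    """

    k: int = 31
    min_recurrence: int = 2
    min_recurrence_abundance: int = 5
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be odd and >= 3, got {self.k}")
        if self.k > 31:
            raise ValueError("k > 31 does not fit the 64-bit k-mer code")
        if self.min_recurrence < 1:
            raise ValueError("min_recurrence must be >= 1")
        if self.min_recurrence_abundance < 1:
            raise ValueError("min_recurrence_abundance must be >= 1")
        if not self.canonical:
            raise ValueError("only canonical (unstranded) counting is supported")

    @staticmethod
    def default_recurrence(n_samples: int) -> int:
        """Default ``min_recurrence``: max(2, 10% of the cohort)."""
        return max(2, int(round(0.1 * n_samples)))


# ---------------------------------------------------------------------------
# encoded counting core
# ---------------------------------------------------------------------------

def _reads_to_byte_matrix(reads: Sequence[str] | np.ndarray) -> np.ndarray:
    """Pack reads into an (n_reads, max_len) uint8 byte matrix, 0-padded."""
    if isinstance(reads, np.ndarray) and reads.dtype == np.uint8 and reads.ndim == 2:
        return reads
    n = len(reads)
    if n == 0:
        return np.zeros((0, 0), dtype=np.uint8)
    lengths = np.fromiter((len(r) for r in reads), dtype=np.int64, count=n)
    width = int(lengths.max())
    mat = np.zeros((n, width), dtype=np.uint8)
    for i, r in enumerate(reads):
        mat[i, : lengths[i]] = np.frombuffer(r.encode("ascii"), dtype=np.uint8)
    return mat


def count_codes(reads: Sequence[str] | np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Count canonical k-mer codes over all length-k windows of ``reads``.

    Returns ``(codes, counts)`` with codes sorted ascending (ascending code
    order is lexicographic order of the k-mer strings).  Windows containing
    a non-ACGT byte are skipped; reads shorter than k contribute nothing.
    """
    mat = _reads_to_byte_matrix(reads)
    n, width = mat.shape
    if n == 0 or width < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)

    enc = _ENC[mat]
    valid = enc != 255
    base = np.where(valid, enc, 0).astype(np.uint64)
    comp = np.where(valid, 3 - enc, 0).astype(np.uint64)

    mask = np.uint64((1 << (2 * k)) - 1)
    n_win = width - k + 1

    fwd = np.empty((n, n_win), dtype=np.uint64)
    rc = np.empty((n, n_win), dtype=np.uint64)
    win_ok = np.empty((n, n_win), dtype=bool)

    # forward codes + validity run-length, scanning left to right
    code = np.zeros(n, dtype=np.uint64)
    run = np.zeros(n, dtype=np.int64)
    two = np.uint64(2)
    for j in range(width):
        code = ((code << two) | base[:, j]) & mask
        run = np.where(valid[:, j], run + 1, 0)
        if j >= k - 1:
            fwd[:, j - k + 1] = code
            win_ok[:, j - k + 1] = run >= k

    # reverse-complement codes, scanning right to left
    code = np.zeros(n, dtype=np.uint64)
    for j in range(width - 1, -1, -1):
        code = ((code << two) | comp[:, j]) & mask
        if j <= width - k:
            rc[:, j] = code

    canon = np.minimum(fwd, rc)[win_ok]
    if canon.size == 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    codes, counts = np.unique(canon, return_counts=True)
    return codes, counts.astype(np.int64)


def decode_codes(codes: np.ndarray, k: int) -> list[str]:
    """Decode uint64 k-mer codes back to ACGT strings (vectorized)."""
    codes = np.asarray(codes, dtype=np.uint64)
    chars = np.empty((codes.size, k), dtype=np.uint8)
    for j in range(k):
        shift = np.uint64(2 * (k - 1 - j))
        chars[:, j] = _DEC[(codes >> shift) & np.uint64(3)]
    return [row.tobytes().decode("ascii") for row in chars]


def encode_kmers(kmers: Iterable[str], k: int) -> np.ndarray:
    """Encode ACGT k-mer strings (length k, already canonical or not) to codes."""
    out = []
    for s in kmers:
        if len(s) != k:
            raise ValueError(f"k-mer {s!r} does not have length {k}")
        enc = _ENC[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
        if (enc == 255).any():
            raise ValueError(f"non-ACGT character in k-mer {s!r}")
        code = np.uint64(0)
        for b in enc:
            code = (code << np.uint64(2)) | np.uint64(b)
        out.append(code)
    return np.asarray(out, dtype=np.uint64)


# ---------------------------------------------------------------------------
# public counting API
# ---------------------------------------------------------------------------

def count_reads(reads: Sequence[str], params: KmerParams) -> dict[str, int]:
    """Canonical k-mer counts of an in-memory collection of reads."""
    codes, counts = count_codes(reads, params.k)
    return dict(zip(decode_codes(codes, params.k), (int(c) for c in counts)))


def count_sample(fastq_paths: Sequence[str | Path], params: KmerParams) -> dict[str, int]:
    """Count canonical k-mers across one sample's FASTQ file(s).

    Paired-end mates are treated as independent reads (pass both files).
    Files may be gzipped.  A malformed record raises ``ValueError`` naming
    the file and record index; an empty file yields an empty map with a
    warning.
    """
    reads: list[str] = []
    for path in fastq_paths:
        n_before = len(reads)
        for rec_seq in parse_fastq(path):
            reads.append(rec_seq)
        if len(reads) == n_before:
            warnings.warn(f"FASTQ file {path} contains no reads")
    return count_reads(reads, params)


def count_sample_codes(
    fastq_paths_or_reads: Sequence, params: KmerParams
) -> tuple[np.ndarray, np.ndarray]:
    """Code-level counting used by the pipeline (no string decoding)."""
    first = fastq_paths_or_reads[0] if len(fastq_paths_or_reads) else None
    if isinstance(first, (str, Path)) and Path(str(first)).exists():
        reads: list[str] = []
        for path in fastq_paths_or_reads:
            reads.extend(parse_fastq(path))
        return count_codes(reads, params.k)
    return count_codes(fastq_paths_or_reads, params.k)


# ---------------------------------------------------------------------------
# the joint matrix
# ---------------------------------------------------------------------------

@dataclass
class KmerCountMatrix:
    """Canonical k-mer x sample integer count matrix with its parameters.

    ``features`` are canonical k-mer strings in lexicographic order;
    ``counts[i, j]`` is the count of feature i in sample j.
    """

    features: list[str]
    samples: list[str]
    counts: np.ndarray
    params: KmerParams
    codes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValueError("counts shape does not match features x samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features")
        k = self.params.k
        for f in self.features[: min(len(self.features), 1000)]:
            if len(f) != k:
                raise ValueError(f"feature {f!r} does not have length k={k}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.features, columns=self.samples)

    def to_tsv(self, path: str | Path) -> None:
        """Write the shared matrix TSV dialect (first column ``feature``)."""
        df = self.to_frame()
        df.index.name = "feature"
        with open_maybe_gzip(path, "wt") as fh:
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, params: KmerParams) -> "KmerCountMatrix":
        with open_maybe_gzip(path, "rt") as fh:
            df = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(
            features=list(df.index),
            samples=list(df.columns),
            counts=df.to_numpy(dtype=np.int64),
            params=params,
        )


def join_and_filter_codes(
    per_sample: Sequence[tuple[np.ndarray, np.ndarray]],
    sample_ids: Sequence[str],
    params: KmerParams,
) -> KmerCountMatrix:
    """Join per-sample (codes, counts) pairs and apply the recurrence filter.

    A k-mer is retained iff its count is >= ``min_recurrence_abundance`` in
    at least ``min_recurrence`` samples.  Feature order is lexicographic
    (ascending code order).
    """
    if len(per_sample) != len(sample_ids):
        raise ValueError("one (codes, counts) pair required per sample id")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample ids in {list(sample_ids)}")

    all_codes = [c for c, _ in per_sample]
    union = np.unique(np.concatenate(all_codes)) if all_codes else np.empty(0, np.uint64)
    n_feat, n_samp = union.size, len(sample_ids)
    mat = np.zeros((n_feat, n_samp), dtype=np.int64)
    for j, (codes, counts) in enumerate(per_sample):
        if codes.size:
            rows = np.searchsorted(union, codes)
            mat[rows, j] = counts

    support = (mat >= params.min_recurrence_abundance).sum(axis=1)
    keep = support >= params.min_recurrence
    kept_codes = union[keep]
    kept = mat[keep]
    logger.info(
        "recurrence filter kept %d / %d k-mers (min_recurrence=%d, abundance>=%d)",
        kept.shape[0], n_feat, params.min_recurrence, params.min_recurrence_abundance,
    )
    return KmerCountMatrix(
        features=decode_codes(kept_codes, params.k),
        samples=list(sample_ids),
        counts=kept,
        params=params,
        codes=kept_codes,
    )


def join_and_filter(
    per_sample_counts: Sequence[Mapping[str, int]],
    sample_ids: Sequence[str],
    params: KmerParams,
) -> KmerCountMatrix:
    """Join per-sample {k-mer: count} maps and apply the recurrence filter."""
    pairs = []
    for counts in per_sample_counts:
        kmers = list(counts)
        codes = encode_kmers(kmers, params.k)
        order = np.argsort(codes)
        vals = np.fromiter((counts[k] for k in kmers), dtype=np.int64, count=len(kmers))
        pairs.append((codes[order], vals[order]))
    return join_and_filter_codes(pairs, sample_ids, params)
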