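"""Reduction of a k-mer matrix to contigs by count-compatible overlap merging.

K-mers (and, iteratively, the contigs built from them) are merged when they
overlap by k-1 down to k-``max_shift`` nucleotides, subject to two gates:

* **ambiguity** — a junction is merged only when it is unambiguous on both
  sides: the extending contig sees exactly one candidate at that overlap
  length, and the candidate sees exactly one incoming contig.  Competing
  extension paths stop the extension (the conservative unitig rule).
* **count compatibility** — the mean absolute contrast (MAC) between the
  two contigs' per-sample count vectors,

      MAC(c1, c2) = mean_s |c1_s - c2_s| / (c1_s + c2_s),

  must not exceed ``mac_threshold`` (default 0.25).  This keeps each contig
  made of k-mers with consistent abundance profiles, so that a contig is a
  coherent expression unit rather than an arbitrary assembly path.

Because counting is canonical (strand-agnostic), merging is bidirected:
each contig is tracked in one orientation and overlaps are tested against
both orientations of the candidate.  A merged contig's count vector is the
element-wise mean of its member k-mers' count vectors.

Overlap lengths are processed longest-first.  The k-1 pass is classic
unitig-style path compaction on the bidirected k-mer graph: junction
degrees are evaluated on the original k-mer set, and each maximal
non-branching path is walked in a canonical direction, accumulating a
contig and cutting it wherever the MAC gate fails.  Shorter overlaps
(k-2 down to k-max_shift) then merge the resulting contigs' ends, bridging
k-mers that were lost to filtering; within a pass contigs are visited in
lexicographic order of their sequence, which makes the output
deterministic and independent of input feature order.  A bridge at
overlap < k-1 introduces junction windows that are not member k-mers;
every member k-mer, however, always occurs as a window of its contig.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from kmersig.kmers import KmerCountMatrix, canonical_kmer, revcomp

logger = logging.getLogger(__name__)


def mac(c1, c2) -> float:
    """Mean absolute contrast between two per-sample count vectors.

    mean over samples of |c1_s - c2_s| / (c1_s + c2_s); a sample where both
    counts are zero contributes 0 (both vectors agree the sequence is
    absent there).  Symmetric; in [0, 1] for non-negative input.
    """
    a = np.asarray(c1, dtype=float)
    b = np.asarray(c2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"count vectors must be equal-length 1-D, got {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("count vectors must have at least one sample")
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        contrast = np.abs(a - b) / denom
    contrast[denom == 0] = 0.0
    return float(contrast.mean())


@dataclass(frozen=True)
class MergePolicy:
    """Overlap range and count-compatibility gate for contig extension."""

    max_shift: int = 15
    mac_threshold: float = 0.25

    def __post_init__(self) -> None:
        if self.max_shift < 1:
            raise ValueError("max_shift must be >= 1")
        if not (0 < self.mac_threshold <= 1):
            raise ValueError("mac_threshold must be in (0, 1]")


@dataclass
class Contig:
    """A merged sequence, its member k-mers and per-sample mean counts."""

    id: str
    seq: str
    members: list[str]
    counts: np.ndarray

    def __len__(self) -> int:
        return len(self.seq)

    def check_members(self, k: int) -> None:
        """Assert every member k-mer occurs as a canonicalized window of seq."""
        windows = {
            canonical_kmer(self.seq[i : i + k]) for i in range(len(self.seq) - k + 1)
        }
        missing = set(self.members) - windows
        if missing:
            raise AssertionError(
                f"contig {self.id}: {len(missing)} member k-mers not found as windows"
            )


class _Working:
    """Mutable contig during assembly: sequence + running member-count sums."""

    __slots__ = ("seq", "rows", "sums", "alive")

    def __init__(self, seq: str, row: int, counts: np.ndarray):
        self.seq = seq
        self.rows = [row]
        self.sums = counts.astype(float).copy()
        self.alive = True

    @property
    def mean_counts(self) -> np.ndarray:
        return self.sums / len(self.rows)

    def absorb(self, other: "_Working", new_seq: str) -> None:
        self.seq = new_seq
        self.rows.extend(other.rows)
        self.sums += other.sums
        other.alive = False


def _register(indexes, cid: int, seq: str, o: int) -> None:
    in_index, out_index = indexes
    in_index.setdefault(seq[:o], []).append((cid, "fwd"))
    in_index.setdefault(revcomp(seq[-o:]), []).append((cid, "flip"))
    out_index.setdefault(seq[-o:], []).append((cid, "fwd"))
    out_index.setdefault(revcomp(seq[:o]), []).append((cid, "flip"))


def _unregister(indexes, cid: int, seq: str, o: int) -> None:
    in_index, out_index = indexes
    for index, key in (
        (in_index, seq[:o]),
        (in_index, revcomp(seq[-o:])),
        (out_index, seq[-o:]),
        (out_index, revcomp(seq[:o])),
    ):
        bucket = index.get(key)
        if bucket is not None:
            index[key] = [e for e in bucket if e[0] != cid]
            if not index[key]:
                del index[key]


def _try_extend_right(cid, contigs, indexes, o, threshold) -> bool:
    """Attempt one unambiguous, MAC-compatible merge on the right end."""
    in_index, out_index = indexes
    x = contigs[cid]
    word = x.seq[-o:]
    # a contig never merges with its own reverse complement; self-entries
    # are not competitors (bidirected convention)
    ins = [e for e in in_index.get(word, []) if contigs[e[0]].alive and e[0] != cid]
    if len(ins) != 1:
        return False
    (y_cid, orient) = ins[0]
    # two-sided junction uniqueness: the candidate must see this contig as
    # its only incoming neighbour at this overlap length
    outs = [e for e in out_index.get(word, []) if contigs[e[0]].alive and e[0] != y_cid]
    if len(outs) != 1 or outs[0][0] != cid:
        return False
    y = contigs[y_cid]
    if mac(x.mean_counts, y.mean_counts) > threshold:
        return False
    y_seq = y.seq if orient == "fwd" else revcomp(y.seq)
    new_seq = x.seq + y_seq[o:]
    _unregister(indexes, cid, x.seq, o)
    _unregister(indexes, y_cid, y.seq, o)
    x.absorb(y, new_seq)
    _register(indexes, cid, x.seq, o)
    return True


def _compact_paths(features, counts, k: int, threshold: float) -> list[_Working]:
    """Unitig-style compaction at overlap k-1 with the MAC gate.

    Junction ambiguity is judged on the original bidirected k-mer graph:
    (a, da) -> (b, e) is followed only when b is a's sole successor and a
    is b's sole predecessor (self and reverse-complement-self excluded).
    Each maximal non-branching path is walked once, in the direction that
    spells the lexicographically smaller sequence, accumulating a contig
    whose mean count vector is compared (MAC) with each next k-mer; a
    failing junction cuts the contig and starts a new one.
    """
    o = k - 1
    n = len(features)
    oriented = [(f, revcomp(f)) for f in features]

    prefix_index: dict[str, list[tuple[int, int]]] = {}
    suffix_index: dict[str, list[tuple[int, int]]] = {}
    for i, (fwd, rev) in enumerate(oriented):
        for d, seq in ((0, fwd), (1, rev)):
            prefix_index.setdefault(seq[:o], []).append((i, d))
            suffix_index.setdefault(seq[-o:], []).append((i, d))

    def unique_next(i: int, d: int):
        cands = [e for e in prefix_index.get(oriented[i][d][-o:], []) if e[0] != i]
        if len(cands) != 1:
            return None
        j, e = cands[0]
        back = [p for p in suffix_index.get(oriented[j][e][:o], []) if p[0] != j]
        if back != [(i, d)]:
            return None
        return (j, e)

    def unique_prev(i: int, d: int):
        cands = [p for p in suffix_index.get(oriented[i][d][:o], []) if p[0] != i]
        if len(cands) != 1:
            return None
        j, e = cands[0]
        fwd = [s for s in prefix_index.get(oriented[j][e][-o:], []) if s[0] != j]
        if fwd != [(i, d)]:
            return None
        return (j, e)

    order = sorted(range(n), key=lambda i: features[i])
    visited = [False] * n
    out: list[_Working] = []
    for start in order:
        if visited[start]:
            continue
        state = (start, 0)
        seen = {start}
        while True:  # rewind to the path's beginning (cycle-guarded)
            p = unique_prev(*state)
            if p is None or p[0] in seen:
                break
            state = p
            seen.add(p[0])
        path = [state]
        seen = {state[0]}
        while True:
            nxt = unique_next(*path[-1])
            if nxt is None or nxt[0] in seen:
                break
            path.append(nxt)
            seen.add(nxt[0])
        seq = oriented[path[0][0]][path[0][1]]
        for st in path[1:]:
            seq += oriented[st[0]][st[1]][-1]
        if revcomp(seq) < seq:  # canonical walk direction
            path = [(i, 1 - d) for i, d in reversed(path)]
        for st in path:
            visited[st[0]] = True
        # accumulate along the path, cutting where counts are incompatible
        cur: _Working | None = None
        for i, d in path:
            if cur is not None and mac(cur.mean_counts, counts[i]) <= threshold:
                nxt_seq = oriented[i][d]
                cur.seq = cur.seq + nxt_seq[-1]
                cur.rows.append(i)
                cur.sums += counts[i]
            else:
                if cur is not None:
                    out.append(cur)
                cur = _Working(oriented[i][d], i, counts[i])
        out.append(cur)
    return out


def extend_contigs(matrix: KmerCountMatrix, policy: MergePolicy = MergePolicy()) -> list[Contig]:
    """Merge the matrix's k-mers into contigs under ``policy``.

    Returns contigs partitioning the input k-mer set (every input k-mer is
    a member of exactly one contig).  Output order and orientation are
    deterministic: each contig is reported in its lexicographically smaller
    orientation, and contigs are sorted by sequence.
    """
    k = matrix.params.k
    if policy.max_shift > k - 1:
        raise ValueError(f"max_shift={policy.max_shift} must be <= k-1={k - 1}")
    if len(matrix.features) == 0:
        raise ValueError("empty matrix")
    for f in matrix.features:
        if len(f) != k:
            raise ValueError(f"feature {f!r} does not have length k={k}")

    counts = np.asarray(matrix.counts, dtype=float)
    contigs = _compact_paths(matrix.features, counts, k, policy.mac_threshold)

    for o in range(k - 2, k - 1 - policy.max_shift, -1):
        while True:
            alive_ids = [i for i, c in enumerate(contigs) if c.alive]
            indexes = ({}, {})
            for i in alive_ids:
                _register(indexes, i, contigs[i].seq, o)
            merged_any = False
            # deterministic sweep: lexicographic order of current sequences
            for cid in sorted(alive_ids, key=lambda i: contigs[i].seq):
                if not contigs[cid].alive:
                    continue
                # grow right, then flip and grow the other end
                for _ in range(2):
                    while _try_extend_right(cid, contigs, indexes, o, policy.mac_threshold):
                        merged_any = True
                    x = contigs[cid]
                    _unregister(indexes, cid, x.seq, o)
                    x.seq = revcomp(x.seq)
                    _register(indexes, cid, x.seq, o)
            if not merged_any:
                break

    out: list[Contig] = []
    features = matrix.features
    for c in contigs:
        if not c.alive:
            continue
        seq = min(c.seq, revcomp(c.seq))
        members = [features[r] for r in c.rows]
        out.append(Contig(id="", seq=seq, members=members, counts=c.sums / len(c.rows)))
    out.sort(key=lambda c: c.seq)
    for i, c in enumerate(out):
        c.id = f"ctg_{i + 1}"
        c.check_members(k)

    n_members = sum(len(c.members) for c in out)
    if n_members != len(features):
        raise AssertionError(
            f"member conservation violated: {n_members} members vs {len(features)} k-mers"
        )
    logger.info("merged %d k-mers into %d contigs", len(features), len(out))
    return out


def contig_matrix(contigs: list[Contig], samples: list[str]):
    """Stack contig count vectors into a contig x sample DataFrame."""
    import pandas as pd

    data = np.vstack([c.counts for c in contigs]) if contigs else np.zeros((0, len(samples)))
    return pd.DataFrame(data, index=[c.id for c in contigs], columns=samples)
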