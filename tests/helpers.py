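"""Independent oracles used by the tests.

These deliberately re-derive results with naive algorithms (dictionary
window counting; bidirected-graph path compaction) so they stay
independent of the package's optimized implementations.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canon(seq: str) -> str:
    r = rc(seq)
    return seq if seq <= r else r


def naive_window_counts(reads, k):
    """Dictionary-of-all-windows canonical k-mer counter (the oracle)."""
    counts = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            w = read[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue
            c = canon(w)
            counts[c] = counts.get(c, 0) + 1
    return counts


def unitig_compaction(kmers, k):
    """Brute-force unambiguous-path compaction of canonical k-mers.

    Builds the bidirected overlap graph at overlap k-1 by all-pairs
    comparison, then walks maximal non-branching paths.  A node never
    connects to its own reverse complement (the package's convention).
    Returns the set of contig sequences in canonical orientation.
    """
    nodes = sorted(kmers)
    o = k - 1

    def oriented(i, d):
        return nodes[i] if d == 0 else rc(nodes[i])

    n = len(nodes)
    # successors[(i, d)] = list of (j, e) with suffix(i,d) == prefix(j,e), j != i
    successors = {}
    predecessors = {}
    for i in range(n):
        for d in (0, 1):
            suf = oriented(i, d)[-o:]
            succ = []
            for j in range(n):
                if j == i:
                    continue
                for e in (0, 1):
                    if oriented(j, e)[:o] == suf:
                        succ.append((j, e))
            successors[(i, d)] = succ
    for key, succ in successors.items():
        for t in succ:
            predecessors.setdefault(t, []).append(key)

    def next_node(state):
        succ = successors[state]
        if len(succ) != 1:
            return None
        t = succ[0]
        if len(predecessors.get(t, [])) != 1:
            return None
        return t

    def prev_node(state):
        pred = predecessors.get(state, [])
        if len(pred) != 1:
            return None
        s = pred[0]
        if len(successors[s]) != 1:
            return None
        return s

    visited = set()
    contigs = set()
    for start in range(n):
        if start in visited:
            continue
        # walk left from (start, 0) to the path's beginning
        state = (start, 0)
        seen = {start}
        while True:
            p = prev_node(state)
            if p is None or p[0] in seen:
                break
            state = p
            seen.add(p[0])
        # walk right collecting the path
        path = [state]
        seen = {state[0]}
        while True:
            nxt = next_node(path[-1])
            if nxt is None or nxt[0] in seen:
                break
            path.append(nxt)
            seen.add(nxt[0])
        seq = oriented(*path[0])
        for st in path[1:]:
            seq += oriented(*st)[o:]
        contigs.add(canon(seq))
        visited.update(st[0] for st in path)
    return contigs


def nb_noise(rng, dispersion, size):
    return rng.gamma(1.0 / dispersion, scale=dispersion, size=size)
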