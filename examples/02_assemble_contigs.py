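"""Contig assembly gated by count compatibility (mean absolute contrast).

Three 5-mers chain into the sequence AATGTGG, but the first k-mer's counts
disagree with its neighbour's (MAC > 0.25), so only the compatible pair is
merged — contigs stay coherent expression units.
"""

import numpy as np

import kmersig as ks

params = ks.KmerParams(k=5, min_recurrence=1, min_recurrence_abundance=1)
features = sorted(["AATGT", "ATGTG", "CCACA"])  # CCACA = revcomp(TGTGG)
counts = {"AATGT": [100, 90], "ATGTG": [10, 12], "CCACA": [11, 12]}
matrix = ks.KmerCountMatrix(
    features=features,
    samples=["sample1", "sample2"],
    counts=np.array([counts[f] for f in features]),
    params=params,
)

print(f"MAC(AATGT, ATGTG) = {ks.mac(counts['AATGT'], counts['ATGTG']):.3f}  (> 0.25: merge rejected)")
print(f"MAC(ATGTG, TGTGG) = {ks.mac(counts['ATGTG'], counts['CCACA']):.3f}  (<= 0.25: merge allowed)")

contigs = ks.extend_contigs(matrix, ks.MergePolicy(max_shift=1, mac_threshold=0.25))
print(f"\n{len(matrix.features)} k-mers -> {len(contigs)} contigs:")
for c in contigs:
    print(f"  {c.id}: {c.seq}  members={len(c.members)}  counts={c.counts}")
# the merged contig's counts are the mean of its member k-mers' counts
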