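"""Canonical k-mer counting and the recurrence filter.

Counts every length-k window of a few reads in canonical (strand-agnostic)
form, then joins three toy samples into one matrix keeping only k-mers
that reach 5 copies in at least 2 samples.
"""

import kmersig as ks

params = ks.KmerParams(k=11, min_recurrence=2, min_recurrence_abundance=5)

reads = ["ACGTACGTACGTACGTAC", "GTACGTACGTACGTACGT"]
counts = ks.count_reads(reads, params)
print(f"{len(counts)} canonical 11-mers in {len(reads)} reads:")
for kmer, n in sorted(counts.items()):
    print(f"  {kmer}  x{n}")
# each k-mer is reported once for itself and its reverse complement

per_sample = [
    {"ACGTACGTACG": 9, "CGTACGTACGT": 1},
    {"ACGTACGTACG": 7},
    {"CGTACGTACGT": 2},
]
matrix = ks.join_and_filter(per_sample, ["s1", "s2", "s3"], params)
print("\njoint matrix after the recurrence filter (>=5 copies in >=2 samples):")
print(matrix.to_frame())
# only ACGTACGTACG survives: the filter removes k-mers seen well in <2 samples
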