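"""Quantifying a contig signature in an independent cohort.

A signature contig does not exist as a feature in another cohort's matrix;
its expression there is the per-sample median of its constituent k-mers'
counts.  Contigs whose k-mers are all absent are reported missing and
their coefficients zeroed at prediction time.
"""

import numpy as np

import kmersig as ks
from kmersig.transfer import quantify_in_cohort

signature = ks.Signature(
    task="risk",
    features=[
        ks.SignatureFeature(id="ctg_up", coefficient=1.2, sequence="ACGTAGGTC"),
        ks.SignatureFeature(id="ctg_lost", coefficient=-0.8, sequence="GGGGGCCCC"),
    ],
    intercept=-0.5,
    base_constant=1e9,
    metadata={"k": 5},
)

# validation matrix contains ctg_up's 5 k-mers but none of ctg_lost's,
# plus background k-mers that dominate each sample's library size
kmers = ks.contig_kmers(signature, 5)["ctg_up"]
params = ks.KmerParams(k=5, min_recurrence=1, min_recurrence_abundance=1)
contig_counts = {km: c for km, c in zip(kmers, [[3, 30], [5, 50], [9, 90], [5, 55], [4, 42]])}
background = {"AAACC": [500, 480], "AACCC": [230, 260], "CCCTT": [700, 720]}
all_counts = {**contig_counts, **background}
features = sorted(all_counts)
matrix = ks.KmerCountMatrix(
    features=features,
    samples=["low_expr", "high_expr"],
    counts=np.array([all_counts[f] for f in features]),
    params=params,
)

values, missing, recovery = quantify_in_cohort(signature, matrix)
print("per-contig k-mer recovery:", dict(recovery))
print("missing contigs:", missing)
print("\nnormalized contig expression (median of matched k-mer counts,")
print("scaled by the validation sample totals):")
print(values.round(1))
# high_expr carries ~10x the counts of low_expr, and the medians show it
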