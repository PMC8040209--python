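"""Library-size normalization and clinical outcome labelling.

Normalizes a toy count matrix to counts-per-million, then assigns
low/high-risk labels from Gleason score and pT stage (the PSA-free
d'Amico adaptation) and relapse labels from event/time cutoffs.
"""

import pandas as pd

import kmersig as ks

counts = pd.DataFrame(
    {"patient1": [120, 30, 50], "patient2": [240, 60, 100]},
    index=["geneA", "geneB", "geneC"],
)
norm = ks.normalize(counts, base_constant=1e6)
print("CPM-normalized values (each column sums to 1e6):")
print(norm.values.round(0))
# patient2 sequenced twice as deep ends up identical after normalization

clinical = pd.DataFrame([
    {"sample_id": "p1", "gleason": 6, "stage": "pT2a"},
    {"sample_id": "p2", "gleason": 9, "stage": "pT3b"},
    {"sample_id": "p3", "gleason": 7, "gleason_primary": 4,
     "gleason_secondary": 3, "stage": "pT2"},
])
risk = ks.label_risk(clinical)
print("\nrisk labels (LR=NEGATIVE, HR=POSITIVE, intermediate excluded):")
print(risk.labels.to_string())

followup = pd.DataFrame([
    {"sample_id": "p1", "event": 1, "time": 1.5},
    {"sample_id": "p2", "event": 0, "time": 6.0},
    {"sample_id": "p3", "event": 1, "time": 3.0},
])
relapse = ks.label_relapse(followup, cutoffs=(2.0, 5.0))
print("\nrelapse labels (relapse <2y positive, no relapse >5y negative):")
print(relapse.labels.to_string())
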