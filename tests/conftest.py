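"""Shared fixtures: a moderate synthetic cohort and its derived objects.

The cohort is simulated once per session (2x30 samples at reduced depth)
and reused by the transfer and acceptance tests to keep the suite fast.
"""

import numpy as np
import pytest

import kmersig as ks
from kmersig.pipeline import count_cohort, run_discovery


@pytest.fixture(scope="session")
def std_config():
    return ks.SimulationConfig(seed=42, n_samples_per_class=30, reads_per_sample=12_500)


@pytest.fixture(scope="session")
def std_cohort(std_config):
    return ks.simulate_cohort(std_config)


@pytest.fixture(scope="session")
def std_params(std_cohort):
    n = len(std_cohort.sample_ids)
    return ks.KmerParams(min_recurrence=ks.KmerParams.default_recurrence(n))


@pytest.fixture(scope="session")
def std_matrix(std_cohort, std_params):
    return count_cohort(std_cohort, std_params)


@pytest.fixture(scope="session")
def std_contigs(std_matrix):
    return ks.extend_contigs(std_matrix, ks.MergePolicy())


@pytest.fixture(scope="session")
def std_discovery(std_cohort):
    return run_discovery(
        labels=std_cohort.labels, cohort=std_cohort, n_resamples=200, seed=42
    )


def random_kmer_matrix(rng, k=7, n_kmers=60, n_samples=3, walk_length=80):
    """A random De Bruijn-style instance: canonical k-mers of random walks.

    Returns a KmerCountMatrix whose features come from one or more random
    sequences (guaranteeing overlaps exist) with random positive counts.
    """
    kmers = set()
    while len(kmers) < n_kmers:
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, walk_length))
        for i in range(len(seq) - k + 1):
            kmers.add(ks.canonical_kmer(seq[i : i + k]))
    kmers = sorted(kmers)[:n_kmers]
    counts = rng.integers(1, 50, size=(len(kmers), n_samples))
    params = ks.KmerParams(k=k, min_recurrence=1, min_recurrence_abundance=1)
    return ks.KmerCountMatrix(
        features=kmers, samples=[f"s{i}" for i in range(n_samples)],
        counts=counts, params=params,
    )
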