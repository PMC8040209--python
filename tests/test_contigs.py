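"""Mean absolute contrast and count-compatible contig extension."""

import numpy as np
import pytest

import kmersig as ks

from conftest import random_kmer_matrix
from helpers import canon, unitig_compaction

P3 = ks.KmerParams(k=3, min_recurrence=1, min_recurrence_abundance=1)
P5 = ks.KmerParams(k=5, min_recurrence=1, min_recurrence_abundance=1)


def make_matrix(features, counts, params):
    counts = np.asarray(counts)
    samples = [f"s{i}" for i in range(counts.shape[1])]
    return ks.KmerCountMatrix(
        features=list(features), samples=samples, counts=counts, params=params
    )


class TestMac:
    def test_identical_vectors_zero(self):
        assert ks.mac([3, 7, 1], [3, 7, 1]) == 0.0

    def test_disjoint_support_one(self):
        assert ks.mac([10, 10], [0, 0]) == 1.0

    def test_hand_checked_value(self):
        # per-sample contrasts |3-1|/4 and |1-3|/4, mean 0.5
        assert ks.mac([3, 1], [1, 3]) == pytest.approx(0.5)

    def test_both_zero_sample_contributes_zero(self):
        assert ks.mac([5, 0], [5, 0]) == 0.0

    def test_symmetry_and_direct_formula_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(1, 8)
            a = rng.integers(0, 100, n).astype(float)
            b = rng.integers(0, 100, n).astype(float)
            got = ks.mac(a, b)
            direct = np.mean(
                [0.0 if ai + bi == 0 else abs(ai - bi) / (ai + bi) for ai, bi in zip(a, b)]
            )
            assert got == pytest.approx(direct)
            assert got == pytest.approx(ks.mac(b, a))
            assert 0.0 <= got <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ks.mac([1, 2], [1, 2, 3])


class TestExtendContigs:
    def test_simple_unambiguous_merge(self):
        # ACG and CGA overlap by 2 with identical counts -> one contig
        m = make_matrix(["ACG", "CGA"], [[10, 10], [10, 10]], P3)
        out = ks.extend_contigs(m, ks.MergePolicy(max_shift=1, mac_threshold=0.25))
        assert len(out) == 1
        assert out[0].seq in ("ACGA", canon("ACGA"))
        assert sorted(out[0].members) == ["ACG", "CGA"]
        np.testing.assert_allclose(out[0].counts, [10, 10])

    def test_mac_incompatible_adjacency_blocks_merge(self):
        # the three-contig pattern: both junctions overlap by k-1, but the
        # first pair's counts are incompatible -> it stays unmerged
        feats = sorted(["AATGT", "ATGTG", "CCACA"])  # chain AATGTGG
        counts = {"AATGT": [100, 100], "ATGTG": [10, 10], "CCACA": [11, 11]}
        m = make_matrix(feats, [counts[f] for f in feats], P5)
        assert ks.mac(counts["AATGT"], counts["ATGTG"]) > 0.25
        assert ks.mac(counts["ATGTG"], counts["CCACA"]) <= 0.25
        out = ks.extend_contigs(m, ks.MergePolicy(max_shift=1, mac_threshold=0.25))
        seqs = sorted(c.seq for c in out)
        assert len(out) == 2
        assert canon("AATGT") in seqs
        assert canon("ATGTGG") in seqs
        merged = next(c for c in out if len(c.seq) == 6)
        np.testing.assert_allclose(merged.counts, [10.5, 10.5])  # mean of members

    def test_competing_paths_block_extension(self):
        # ACG's right end matches both CGA and CGC -> ambiguous, no merge
        m = make_matrix(["ACG", "CGA", "CGC"], [[10]] * 3, P3)
        out = ks.extend_contigs(m, ks.MergePolicy(max_shift=1, mac_threshold=1.0))
        assert sorted(c.seq for c in out) == ["ACG", "CGA", "CGC"]

    def test_conservation_and_member_windows_random(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            m = random_kmer_matrix(rng, k=7, n_kmers=80, walk_length=60)
            out = ks.extend_contigs(m, ks.MergePolicy(max_shift=3, mac_threshold=0.25))
            assert sum(len(c.members) for c in out) == len(m.features)
            for c in out:
                c.check_members(7)  # every member occurs as a window

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(11)
        m = random_kmer_matrix(rng, k=7, n_kmers=100, walk_length=70)
        n_prev = None
        for thr in (0.05, 0.15, 0.3, 0.6, 1.0):
            n = len(ks.extend_contigs(m, ks.MergePolicy(max_shift=1, mac_threshold=thr)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_matches_unitig_compaction_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            m = random_kmer_matrix(rng, k=7, n_kmers=60, n_samples=2, walk_length=50)
            out = ks.extend_contigs(m, ks.MergePolicy(max_shift=1, mac_threshold=1.0))
            got = {canon(c.seq) for c in out}
            expected = unitig_compaction(m.features, 7)
            assert got == expected

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        m = random_kmer_matrix(rng, k=7, n_kmers=50, walk_length=60)
        perm = rng.permutation(len(m.features))
        m2 = make_matrix(
            [m.features[i] for i in perm], m.counts[perm], m.params
        )
        a = ks.extend_contigs(m, ks.MergePolicy(max_shift=3, mac_threshold=0.25))
        b = ks.extend_contigs(m2, ks.MergePolicy(max_shift=3, mac_threshold=0.25))
        assert [c.seq for c in a] == [c.seq for c in b]
        for ca, cb in zip(a, b):
            np.testing.assert_allclose(ca.counts, cb.counts)

    def test_policy_validation(self):
        m = make_matrix(["ACG"], [[1]], P3)
        with pytest.raises(ValueError, match="max_shift"):
            ks.extend_contigs(m, ks.MergePolicy(max_shift=5, mac_threshold=0.25))
        with pytest.raises(ValueError):
            ks.MergePolicy(mac_threshold=0.0)
        with pytest.raises(ValueError, match="empty"):
            ks.extend_contigs(
                make_matrix([], np.zeros((0, 1), dtype=int), P3), ks.MergePolicy(max_shift=1)
            )

    def test_shorter_overlaps_bridge_filtered_kmers(self):
        # drop the middle k-mer of a chain; an overlap of k-2 reconnects it
        seq = "AATGTGG"  # 5-mers AATGT, ATGTG, TGTGG
        feats = sorted([canon("AATGT"), canon("TGTGG")])
        m = make_matrix(feats, [[10, 10], [10, 10]], P5)
        out1 = ks.extend_contigs(m, ks.MergePolicy(max_shift=1, mac_threshold=1.0))
        assert len(out1) == 2  # k-1 overlap alone cannot join them
        out2 = ks.extend_contigs(m, ks.MergePolicy(max_shift=2, mac_threshold=1.0))
        assert len(out2) == 1
        assert out2[0].seq == canon(seq)
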