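"""Canonical k-mer counting, joining and the recurrence filter."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kmersig as ks
from kmersig.kmers import count_codes, decode_codes, encode_kmers

from helpers import canon, naive_window_counts, rc

P3 = ks.KmerParams(k=3, min_recurrence=1, min_recurrence_abundance=1)

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


class TestCanonical:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACG", "ACG"), ("TTT", "AAA"), ("CAT", "ATG")],
    )
    def test_examples(self, seq, expected):
        assert ks.canonical_kmer(seq) == expected

    @given(st.text(alphabet="ACGT", min_size=3, max_size=31).filter(lambda s: len(s) % 2 == 1))
    @settings(deadline=None, max_examples=100)
    def test_idempotent_and_strand_invariant(self, seq):
        c = ks.canonical_kmer(seq)
        assert ks.canonical_kmer(c) == c
        assert ks.canonical_kmer(ks.revcomp(seq)) == c
        assert c <= ks.revcomp(c)

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            ks.canonical_kmer("ACN")


class TestCountReads:
    @pytest.mark.parametrize(
        "reads,expected",
        [
            (["AAAAA"], {"AAA": 3}),       # all windows canonicalize together
            (["ACGT"], {"ACG": 2}),        # CGT canonicalizes to ACG
            (["AC"], {}),                  # shorter than k: no window
            (["AANGT"], {}),               # every window overlaps the N
            (["AAANGTT"], {"AAA": 1, "AAC": 1}),  # windows clear of N survive
        ],
    )
    def test_examples(self, reads, expected):
        assert ks.count_reads(reads, P3) == expected

    @given(st.lists(dna, min_size=1, max_size=12))
    @settings(deadline=None, max_examples=60)
    def test_matches_naive_oracle(self, reads):
        assert ks.count_reads(reads, P3) == naive_window_counts(reads, 3)

    @given(st.lists(st.text(alphabet="ACGT", min_size=0, max_size=60), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=40)
    def test_order_and_strand_invariance(self, reads):
        base = ks.count_reads(reads, P3)
        assert ks.count_reads(list(reversed(reads)), P3) == base
        assert ks.count_reads([rc(r) for r in reads], P3) == base

    def test_total_counts_bounded_by_windows(self):
        rng = np.random.default_rng(0)
        reads = ["".join("ACGT"[i] for i in rng.integers(0, 4, 50)) for _ in range(20)]
        counts = ks.count_reads(reads, P3)
        n_windows = sum(max(len(r) - 2, 0) for r in reads)
        assert sum(counts.values()) <= n_windows

    def test_code_roundtrip(self):
        kmers = ["ACGTAGG", "TTTTTTT", "GATTACA"]
        codes = encode_kmers(kmers, 7)
        assert decode_codes(codes, 7) == kmers


class TestCountSample:
    def _write_fastq(self, path, reads, gz=False):
        text = "".join(f"@r{i}\n{r}\n+\n{'I' * len(r)}\n" for i, r in enumerate(reads))
        if gz:
            with gzip.open(path, "wt") as fh:
                fh.write(text)
        else:
            path.write_text(text)

    def test_plain_and_gzip(self, tmp_path):
        fq = tmp_path / "a.fastq"
        fqz = tmp_path / "b.fastq.gz"
        self._write_fastq(fq, ["AAAAA", "ACGT"])
        self._write_fastq(fqz, ["AAAAA", "ACGT"], gz=True)
        expected = {"AAA": 3, "ACG": 2}
        assert ks.count_sample([fq], P3) == expected
        assert ks.count_sample([fqz], P3) == expected
        # paired-end mates are independent reads
        assert ks.count_sample([fq, fqz], P3) == {"AAA": 6, "ACG": 4}

    def test_empty_file_warns(self, tmp_path):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        with pytest.warns(UserWarning, match="no reads"):
            assert ks.count_sample([fq], P3) == {}

    def test_malformed_record_names_file_and_index(self, tmp_path):
        fq = tmp_path / "bad.fastq"
        fq.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\nOOPS\nII\n")
        with pytest.raises(ValueError, match=r"index 1 in .*bad\.fastq"):
            ks.count_sample([fq], P3)


class TestJoinAndFilter:
    def test_recurrence_filter_examples(self):
        params = ks.KmerParams(k=3, min_recurrence=2, min_recurrence_abundance=5)
        maps = [{"AAA": 5, "ACG": 5}, {"ACG": 7}, {"AAA": 4}]
        m = ks.join_and_filter(maps, ["s1", "s2", "s3"], params)
        # AAA reaches 5 in only one sample -> dropped; ACG passes in two
        assert m.features == ["ACG"]
        assert m.counts.tolist() == [[5, 7, 0]]

    def test_vacuous_filter_keeps_union(self):
        m = ks.join_and_filter([{"AAA": 1}, {"ACG": 2}], ["a", "b"], P3)
        assert m.features == sorted(["AAA", "ACG"])
        assert m.counts.tolist() == [[1, 0], [0, 2]]

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate sample ids"):
            ks.join_and_filter([{}, {}], ["s1", "s1"], P3)

    def test_matrix_tsv_roundtrip(self, tmp_path):
        m = ks.join_and_filter([{"AAA": 3}, {"AAA": 2, "ACG": 9}], ["a", "b"], P3)
        path = tmp_path / "m.tsv.gz"
        m.to_tsv(path)
        back = ks.KmerCountMatrix.from_tsv(path, P3)
        assert back.features == m.features
        assert back.samples == m.samples
        assert np.array_equal(back.counts, m.counts)

    def test_shuffled_reads_identical_matrix(self):
        rng = np.random.default_rng(1)
        reads = ["".join("ACGT"[i] for i in rng.integers(0, 4, 40)) for _ in range(30)]
        shuffled = list(reads)
        rng.shuffle(shuffled)
        a = ks.join_and_filter([ks.count_reads(reads, P3)], ["s"], P3)
        b = ks.join_and_filter([ks.count_reads(shuffled, P3)], ["s"], P3)
        assert a.features == b.features
        assert np.array_equal(a.counts, b.counts)


class TestParams:
    def test_invalid_params_rejected(self):
        for kwargs in (
            dict(k=4), dict(k=1), dict(min_recurrence=0),
            dict(min_recurrence_abundance=0), dict(canonical=False),
        ):
            with pytest.raises(ValueError):
                ks.KmerParams(**kwargs)

    def test_default_recurrence_rule(self):
        assert ks.KmerParams.default_recurrence(10) == 2
        assert ks.KmerParams.default_recurrence(374) == 37
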