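"""Signature transfer: k-mer extraction, median quantification, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import kmersig as ks
from kmersig.contigs import contig_matrix
from kmersig.transfer import quantify_in_cohort, predict_validation, transfer_signature


def make_signature(features, intercept=0.0, task="risk", base_constant=1e9, **meta):
    return ks.Signature(
        task=task,
        features=[ks.SignatureFeature(id=i, coefficient=c, sequence=s) for i, c, s in features],
        intercept=intercept,
        base_constant=base_constant,
        metadata=meta,
    )


def make_validation_matrix(kmer_counts: dict, samples, k=5):
    feats = sorted(kmer_counts)
    counts = np.array([kmer_counts[f] for f in feats])
    params = ks.KmerParams(k=k, min_recurrence=1, min_recurrence_abundance=1)
    return ks.KmerCountMatrix(features=feats, samples=samples, counts=counts, params=params)


class TestContigKmers:
    def test_window_counts(self):
        sig = make_signature([
            ("exact", 1.0, "ACGTA"),            # length k -> 1 k-mer
            ("plus2", 1.0, "ACGTAGG"),          # length k+2, distinct -> 3
            ("polyA", 1.0, "A" * 10),           # degenerate repeat -> 1
        ])
        out = ks.contig_kmers(sig, 5)
        assert len(out["exact"]) == 1
        assert len(out["plus2"]) == 3
        assert out["polyA"] == ["AAAAA"]
        # all returned k-mers are canonical
        for kms in out.values():
            assert all(km == ks.canonical_kmer(km) for km in kms)

    def test_short_contig_rejected_by_name(self):
        sig = make_signature([("tiny", 1.0, "ACG")])
        with pytest.raises(ValueError, match="tiny"):
            ks.contig_kmers(sig, 5)


class TestQuantify:
    def test_median_of_matched_kmers(self):
        # contig with 3 distinct k-mers counted {3, 5, 9} in one sample
        contig = "ACGTAGG"
        kms = ks.contig_kmers(make_signature([("c1", 1.0, contig)]), 5)["c1"]
        vm = make_validation_matrix(
            {kms[0]: [3], kms[1]: [5], kms[2]: [9]}, samples=["s1"]
        )
        sig = make_signature([("c1", 1.0, contig)])
        values, missing, recovery = quantify_in_cohort(sig, vm)
        total = 3 + 5 + 9
        assert values.loc["c1", "s1"] == pytest.approx(5 * 1e9 / total)
        assert missing == []
        assert recovery["c1"] == 1.0

    def test_missing_contig_listed(self):
        sig = make_signature([("gone", 1.0, "GGGGGCC"), ("here", 1.0, "ACGTA")])
        vm = make_validation_matrix({"ACGTA": [7]}, samples=["s1"])
        values, missing, recovery = quantify_in_cohort(sig, vm)
        assert missing == ["gone"]
        assert recovery["gone"] == 0.0
        assert values.loc["gone", "s1"] == 0.0

    def test_median_robust_to_minority_corruption(self):
        contig = "ACGTAGGTC"  # 5 k-mers
        kms = ks.contig_kmers(make_signature([("c", 1.0, contig)]), 5)["c"]
        assert len(kms) == 5
        clean = {km: [10] for km in kms}
        corrupt = dict(clean)
        for km in kms[:2]:  # corrupt < 50 % of the k-mers
            corrupt[km] = [1000]
        sig = make_signature([("c", 1.0, contig)])
        va = make_validation_matrix(clean, ["s"])
        vb = make_validation_matrix(corrupt, ["s"])
        ra = quantify_in_cohort(sig, va)[0].loc["c", "s"]
        rb = quantify_in_cohort(sig, vb)[0].loc["c", "s"]
        # raw medians identical; only the library-size factor differs
        assert ra * va.counts.sum() / 1e9 == pytest.approx(rb * vb.counts.sum() / 1e9)

    def test_k_mismatch_rejected(self):
        sig = make_signature([("c", 1.0, "ACGTAGG")], k=7)
        vm = make_validation_matrix({"ACGTA": [1]}, ["s1"], k=5)
        with pytest.raises(ValueError, match="k mismatch"):
            quantify_in_cohort(sig, vm)


class TestPredictValidation:
    def test_zeroed_coefficient_equals_feature_removal(self):
        sig = make_signature(
            [("a", 2.0, "ACGTA"), ("b", -1.5, "CCGTT")], intercept=0.3
        )
        vals = pd.DataFrame({"s1": [4.0, 9.0], "s2": [1.0, 2.0]}, index=["a", "b"])
        # drop feature b: scoring with b missing must equal scoring a alone
        partial = vals.drop(index="b")
        full_scores = sig.decision_values(partial, missing="zero")
        manual = 0.3 + 2.0 * vals.loc["a"]
        np.testing.assert_allclose(full_scores, manual)

    def test_all_features_missing_reports_undefined(self):
        sig = make_signature([("a", 1.0, "ACGTA")])
        quantified = pd.DataFrame(index=pd.Index([], dtype=str), columns=["s1", "s2"])
        rep = predict_validation(sig, quantified, labels=None, missing_contigs=["a"])
        assert rep.roc_auc is None
        assert "undefined" in rep.notes

    def test_single_class_labels_give_no_auc(self):
        sig = make_signature([("a", 1.0, "ACGTA")])
        quantified = pd.DataFrame({"s1": [3.0], "s2": [5.0]}, index=["a"])
        rep = predict_validation(sig, quantified, labels=np.array([1, 1]))
        assert rep.roc_auc is None and "single class" in rep.notes


class TestSelfTransfer:
    def test_medians_track_stored_mean_counts(self, std_matrix, std_contigs):
        """Quantifying contigs on their own discovery matrix via k-mer
        medians correlates strongly with the stored mean-based counts."""
        contigs = [c for c in std_contigs if len(c.members) >= 3][:50]
        sig = ks.Signature(
            task="risk",
            features=[ks.SignatureFeature(id=c.id, coefficient=1.0, sequence=c.seq)
                      for c in contigs],
            intercept=0.0,
            base_constant=1e9,
            metadata={"k": std_matrix.params.k},
        )
        quantified, missing, recovery = quantify_in_cohort(sig, std_matrix)
        assert missing == []
        # contigs merged at overlap < k-1 carry junction k-mers that never
        # existed in the matrix, so recovery can dip slightly below 1
        assert recovery.mean() > 0.9
        stored = contig_matrix(contigs, std_matrix.samples)
        rhos = []
        for cid in stored.index:
            if stored.loc[cid].std() == 0:
                continue
            rho = spearmanr(stored.loc[cid], quantified.loc[cid]).statistic
            rhos.append(rho)
        assert np.mean(rhos) >= 0.95
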