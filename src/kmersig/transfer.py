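"""Quantifying signature contigs in an independent cohort by k-mer matching.

A signature learned on one cohort names contigs that do not exist as such
in another cohort's count matrix.  Each signature contig is therefore
decomposed into its constituent canonical k-mers; the k-mers found in the
validation matrix are retrieved, and the contig's expression in each
validation sample is the **median** of the matched k-mer counts (robust to
a minority of diverged or filtered k-mers).  Contigs with no matching
k-mer at all are reported missing and their logistic coefficients are set
to zero at prediction time — the model is applied with no retraining.

Medians are taken over raw validation counts, then put on the signature's
scale by the validation cohort's own per-sample totals times the
signature's base constant (CPB for contigs), mirroring how the discovery
matrix was normalized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from kmersig.io import write_json
from kmersig.kmers import KmerCountMatrix, canonical_kmer
from kmersig.selection import Signature

logger = logging.getLogger(__name__)


def contig_kmers(signature: Signature, k: int) -> dict[str, list[str]]:
    """All distinct canonical k-mers of each signature contig.

    Raises ``ValueError`` naming any contig shorter than k (such a contig
    cannot be decomposed) or lacking a sequence.
    """
    out: dict[str, list[str]] = {}
    for f in signature.features:
        if not f.sequence:
            raise ValueError(f"signature feature {f.id} has no sequence")
        if len(f.sequence) < k:
            raise ValueError(
                f"contig {f.id} (length {len(f.sequence)}) is shorter than k={k}"
            )
        seen: dict[str, None] = {}
        for i in range(len(f.sequence) - k + 1):
            seen.setdefault(canonical_kmer(f.sequence[i : i + k]), None)
        out[f.id] = list(seen)
    return out


def quantify_in_cohort(
    signature: Signature,
    validation_matrix: KmerCountMatrix,
    absent_policy: str = "exclude",
) -> tuple[pd.DataFrame, list[str], pd.Series]:
    """Estimate signature-contig expression in an independent cohort.

    Returns ``(values, missing, recovery)``: a contig x sample matrix of
    normalized expression values (signature scale), the list of contigs
    with zero matching k-mers, and the per-contig fraction of k-mers found.

    ``absent_policy`` controls k-mers of a contig that are absent from the
    validation matrix: ``"exclude"`` (default) takes the median over found
    k-mers only; ``"zero"`` includes them as zero counts.
    """
    if absent_policy not in ("exclude", "zero"):
        raise ValueError("absent_policy must be 'exclude' or 'zero'")
    k = validation_matrix.params.k
    sig_k = signature.metadata.get("k")
    if sig_k is not None and int(sig_k) != k:
        raise ValueError(
            f"k mismatch: signature built with k={sig_k}, validation matrix k={k}"
        )

    kmers_by_contig = contig_kmers(signature, k)
    row_of = {f: i for i, f in enumerate(validation_matrix.features)}
    counts = np.asarray(validation_matrix.counts, dtype=float)
    samples = validation_matrix.samples

    values = {}
    missing: list[str] = []
    recovery = {}
    for cid, kmers in kmers_by_contig.items():
        rows = [row_of[km] for km in kmers if km in row_of]
        recovery[cid] = len(rows) / len(kmers)
        if not rows:
            missing.append(cid)
            values[cid] = np.zeros(len(samples))
            continue
        sub = counts[rows]
        if absent_policy == "zero" and len(rows) < len(kmers):
            pad = np.zeros((len(kmers) - len(rows), len(samples)))
            sub = np.vstack([sub, pad])
        values[cid] = np.median(sub, axis=0)

    raw = pd.DataFrame(values, index=samples).T
    totals = counts.sum(axis=0)
    zero_total = totals == 0
    if zero_total.any():
        warnings.warn(f"{int(zero_total.sum())} validation sample(s) have zero total count")
    scale = np.where(zero_total, 0.0, signature.base_constant / np.where(zero_total, 1, totals))
    normalized = raw * scale
    if missing:
        logger.info("%d/%d signature contigs missing from the validation matrix",
                    len(missing), len(kmers_by_contig))
    return normalized, missing, pd.Series(recovery, name="kmer_recovery")


@dataclass
class ValidationReport:
    """Outcome of applying a signature to an independent cohort."""

    scores: pd.Series
    roc_auc: float | None
    missing_contigs: list[str]
    kmer_recovery: pd.Series
    notes: str = ""

    @property
    def overall_recovery(self) -> float:
        return float(self.kmer_recovery.mean()) if len(self.kmer_recovery) else 0.0

    def to_dict(self) -> dict:
        return {
            "roc_auc": self.roc_auc,
            "missing_contigs": list(self.missing_contigs),
            "kmer_recovery": {str(k): float(v) for k, v in self.kmer_recovery.items()},
            "scores": {str(k): float(v) for k, v in self.scores.items()},
            "notes": self.notes,
        }

    def save(self, path) -> None:
        write_json(self.to_dict(), path)


def predict_validation(
    signature: Signature,
    quantified: pd.DataFrame,
    labels=None,
    missing_contigs: list[str] | None = None,
    kmer_recovery: pd.Series | None = None,
) -> ValidationReport:
    """Score validation samples with the frozen signature model.

    ``quantified`` is the normalized contig x sample matrix from
    :func:`quantify_in_cohort`.  Values go through log1p; contigs absent
    from ``quantified`` (or listed in ``missing_contigs``) have their
    coefficients zeroed.  If ``labels`` (CohortLabels, Series or 0/1
    array over samples) are given and both classes are present, the ROC
    AUC is computed; otherwise it is None with an explanatory note.
    """
    missing_contigs = list(missing_contigs or [])
    usable = quantified.drop(index=[c for c in missing_contigs if c in quantified.index])
    x = np.log1p(usable)
    notes = ""
    present = [f.id for f in signature.features if f.id in x.index]
    if not present:
        scores = pd.Series(np.nan, index=quantified.columns, name="probability")
        return ValidationReport(
            scores=scores,
            roc_auc=None,
            missing_contigs=missing_contigs,
            kmer_recovery=kmer_recovery if kmer_recovery is not None else pd.Series(dtype=float),
            notes="all signature features missing: constant score, AUC undefined",
        )
    scores = signature.predict_proba(x, missing="zero")

    auc = None
    if labels is not None:
        if hasattr(labels, "binary"):
            y = labels.binary(list(scores.index))
            scores_l = scores.reindex(y.index)
        else:
            y = pd.Series(np.asarray(labels, dtype=int), index=scores.index)
            scores_l = scores
        if y.nunique() < 2:
            notes = "labels contain a single class: AUC undefined"
        else:
            auc = float(roc_auc_score(y.to_numpy(), scores_l.to_numpy()))
    return ValidationReport(
        scores=scores,
        roc_auc=auc,
        missing_contigs=missing_contigs,
        kmer_recovery=kmer_recovery if kmer_recovery is not None else pd.Series(dtype=float),
        notes=notes,
    )


def transfer_signature(
    signature: Signature,
    validation_matrix: KmerCountMatrix,
    labels=None,
    absent_policy: str = "exclude",
) -> ValidationReport:
    """Convenience wrapper: quantify then predict in one call."""
    quantified, missing, recovery = quantify_in_cohort(
        signature, validation_matrix, absent_policy=absent_policy
    )
    return predict_validation(
        signature, quantified, labels=labels,
        missing_contigs=missing, kmer_recovery=recovery,
    )
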