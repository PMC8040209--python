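"""End-to-end discovery and validation orchestration.

``run_discovery`` executes the whole discovery arm — count, merge
(k-mer arm only), normalize, label, rank, select, fit, evaluate — and
returns the signature plus metrics and a manifest recording every
parameter, seed and input hash, so a rerun with identical inputs yields a
byte-identical signature.  ``run_validation`` builds (or takes) a
validation matrix, transfers the signature by exact k-mer matching and
reports the validation AUC and k-mer recovery.

Two arms share the downstream stages:

* **k-mer arm** — FASTQ reads (or an in-memory synthetic cohort) are
  counted into a canonical k-mer matrix, reduced to contigs, and
  normalized to counts per billion (C_b = 1e9);
* **gene arm** — a precomputed gene x sample count matrix passes the same
  recurrence filter and is normalized to counts per million (C_b = 1e6);
  genes need no k-mer matching at validation time.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from kmersig.contigs import Contig, MergePolicy, contig_matrix, extend_contigs
from kmersig.io import read_sample_sheet
from kmersig.kmers import (
    KmerCountMatrix,
    KmerParams,
    count_sample_codes,
    join_and_filter_codes,
)
from kmersig.preprocess import (
    CONTIG_BASE_CONSTANT,
    GENE_BASE_CONSTANT,
    CohortLabels,
    log_transform,
    normalize,
)
from kmersig.ranking import rank_features
from kmersig.selection import (
    Signature,
    StabilityResult,
    evaluate_cv,
    fit_final_model,
    stability_select,
)
from kmersig.simulate import SyntheticCohort
from kmersig.transfer import ValidationReport, transfer_signature

logger = logging.getLogger(__name__)


def _hash_matrix(features, samples, counts) -> str:
    h = hashlib.sha256()
    h.update("\n".join(map(str, features)).encode())
    h.update("\n".join(map(str, samples)).encode())
    h.update(np.ascontiguousarray(counts).tobytes())
    return h.hexdigest()


def count_cohort(source, params: KmerParams) -> KmerCountMatrix:
    """Count + join + recurrence-filter a cohort into a KmerCountMatrix.

    ``source`` is a SyntheticCohort (in-memory reads) or a sample sheet
    path / DataFrame (columns sample_id, fastq1, optional fastq2).
    """
    pairs, sample_ids = [], []
    if isinstance(source, SyntheticCohort):
        for sid in source.sample_ids:
            pairs.append(count_sample_codes(source.reads[sid], params))
            sample_ids.append(sid)
    else:
        sheet = source if isinstance(source, pd.DataFrame) else read_sample_sheet(source)
        for _, row in sheet.iterrows():
            paths = [row["fastq1"]]
            if "fastq2" in sheet.columns and pd.notna(row.get("fastq2")):
                paths.append(row["fastq2"])
            pairs.append(count_sample_codes(paths, params))
            sample_ids.append(row["sample_id"])
    return join_and_filter_codes(pairs, sample_ids, params)


def recurrence_filter_frame(counts: pd.DataFrame, params: KmerParams) -> pd.DataFrame:
    """Apply the k-mer recurrence filter to a precomputed (gene) matrix."""
    support = (counts >= params.min_recurrence_abundance).sum(axis=1)
    return counts.loc[support >= params.min_recurrence]


@dataclass
class DiscoveryResult:
    signature: Signature
    metrics: dict
    manifest: dict
    stability: StabilityResult
    contigs: list[Contig] | None = None
    model_values: pd.DataFrame | None = field(default=None, repr=False)

    def save(self, outdir) -> None:
        from pathlib import Path

        from kmersig.io import write_json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.signature.save(outdir / "signature.json")
        if any(f.sequence for f in self.signature.features):
            self.signature.save_fasta(outdir / "signature.fa")
        write_json(self.metrics, outdir / "metrics.json")
        write_json(self.manifest, outdir / "manifest.json")


def run_discovery(
    labels: CohortLabels,
    cohort: SyntheticCohort | None = None,
    sample_sheet=None,
    counts: pd.DataFrame | None = None,
    params: KmerParams | None = None,
    merge_policy: MergePolicy = MergePolicy(),
    top_n: int = 500,
    rank_folds: int = 5,
    n_resamples: int = 2000,
    threshold: float = 0.5,
    cv_folds: int = 10,
    cv_repeats: int = 20,
    sampling: str = "none",
    seed: int = 0,
    evaluate: bool = True,
) -> DiscoveryResult:
    """Run the full discovery arm and return signature + metrics + manifest.

    Exactly one of ``cohort`` / ``sample_sheet`` (k-mer arm) or ``counts``
    (gene arm) must be given.  Any stage failure propagates with the stage
    name attached.
    """
    sources = [s is not None for s in (cohort, sample_sheet, counts)]
    if sum(sources) != 1:
        raise ValueError("give exactly one of cohort, sample_sheet or counts")
    gene_arm = counts is not None
    stage = "setup"
    timings: dict[str, float] = {}
    try:
        t0 = time.perf_counter()
        if gene_arm:
            stage = "filter"
            params = params or KmerParams(
                min_recurrence=KmerParams.default_recurrence(counts.shape[1])
            )
            filtered = recurrence_filter_frame(counts, params)
            base_constant = GENE_BASE_CONSTANT
            feature_values = filtered
            n_kmers, contigs = filtered.shape[0], None
            sequences: dict[str, str] = {}
            input_hash = _hash_matrix(filtered.index, filtered.columns,
                                      filtered.to_numpy())
        else:
            stage = "count"
            source = cohort if cohort is not None else sample_sheet
            n_samples = (
                len(source.sample_ids)
                if isinstance(source, SyntheticCohort)
                else len(read_sample_sheet(source) if not isinstance(source, pd.DataFrame) else source)
            )
            params = params or KmerParams(
                min_recurrence=KmerParams.default_recurrence(n_samples)
            )
            matrix = count_cohort(source, params)
            n_kmers = matrix.shape[0]
            input_hash = _hash_matrix(matrix.features, matrix.samples, matrix.counts)
            timings["count"] = time.perf_counter() - t0
            logger.info("k-mer matrix: %d k-mers x %d samples", *matrix.shape)

            stage = "merge"
            t0 = time.perf_counter()
            contigs = extend_contigs(matrix, merge_policy)
            feature_values = contig_matrix(contigs, matrix.samples)
            sequences = {c.id: c.seq for c in contigs}
            base_constant = CONTIG_BASE_CONSTANT
            timings["merge"] = time.perf_counter() - t0
            logger.info("contig matrix: %d contigs", len(contigs))

        stage = "normalize"
        t0 = time.perf_counter()
        norm = normalize(feature_values, base_constant)
        values = log_transform(norm)

        stage = "label"
        labeled = [s for s in values.columns if s in set(labels.labeled_samples())]
        if not labeled:
            raise ValueError("no labeled samples overlap the matrix columns")
        values = values[labeled]
        y = labels.binary(labeled).to_numpy()

        stage = "rank"
        ranked = rank_features(values, labels, top_n=top_n, folds=rank_folds, seed=seed)
        top_ids = [r.feature for r in ranked]
        X = values.loc[top_ids].T  # samples x features
        timings["rank"] = time.perf_counter() - t0

        stage = "select"
        t0 = time.perf_counter()
        stability = stability_select(
            X, y, n_resamples=n_resamples, threshold=threshold, seed=seed + 1_000_003
        )
        selected = stability.selected
        timings["select"] = time.perf_counter() - t0
        logger.info("stability selection kept %d features", len(selected))

        stage = "fit"
        metadata = {
            "task": labels.task,
            "seed": seed,
            "n_resamples": n_resamples,
            "threshold": threshold,
            "arm": "gene" if gene_arm else "kmer",
            "k": params.k,
            "input_hash": input_hash,
        }
        signature = fit_final_model(
            X[selected], y,
            task=labels.task,
            base_constant=base_constant,
            sequences=sequences,
            metadata=metadata,
        )

        stage = "evaluate"
        metrics: dict = {
            "n_features_after_filter": int(n_kmers),
            "n_contigs": len(contigs) if contigs is not None else None,
            "n_ranked": len(ranked),
            "n_selected": len(selected),
            "selected_frequencies": {
                f: float(stability.frequencies[f]) for f in selected
            },
        }
        if evaluate:
            cv = evaluate_cv(
                X[selected], y,
                folds=cv_folds, repeats=cv_repeats,
                sampling=sampling, seed=seed + 2_000_003,
            )
            metrics.update(cv)
    except Exception as exc:
        raise RuntimeError(f"discovery failed at stage '{stage}': {exc}") from exc

    manifest = {
        "arm": "gene" if gene_arm else "kmer",
        "k": params.k,
        "min_recurrence": params.min_recurrence,
        "min_recurrence_abundance": params.min_recurrence_abundance,
        "max_shift": merge_policy.max_shift,
        "mac_threshold": merge_policy.mac_threshold,
        "base_constant": base_constant,
        "top_n": top_n,
        "rank_folds": rank_folds,
        "n_resamples": n_resamples,
        "threshold": threshold,
        "cv_folds": cv_folds,
        "cv_repeats": cv_repeats,
        "sampling": sampling,
        "seed": seed,
        "stage_seeds": {
            "rank": seed,
            "select": seed + 1_000_003,
            "evaluate": seed + 2_000_003,
        },
        "input_hash": input_hash,
        "task": labels.task,
        "label_rule": labels.rule_set,
        "timings_s": {s: round(t, 3) for s, t in timings.items()},
    }
    return DiscoveryResult(
        signature=signature,
        metrics=metrics,
        manifest=manifest,
        stability=stability,
        contigs=contigs,
        model_values=X,
    )


def run_validation(
    signature: Signature,
    cohort: SyntheticCohort | None = None,
    sample_sheet=None,
    validation_matrix: KmerCountMatrix | None = None,
    counts: pd.DataFrame | None = None,
    labels: CohortLabels | None = None,
    params: KmerParams | None = None,
    absent_policy: str = "exclude",
) -> ValidationReport:
    """Apply a frozen signature to an independent cohort.

    K-mer arm: pass reads (``cohort``/``sample_sheet``) or a prebuilt
    ``validation_matrix``; the validation matrix is built with its own
    recurrence settings (``params``) and signature contigs are quantified
    by k-mer matching.  Gene arm: pass ``counts``; genes are looked up
    directly, missing genes' coefficients are zeroed.
    """
    sources = [s is not None for s in (cohort, sample_sheet, validation_matrix, counts)]
    if sum(sources) != 1:
        raise ValueError(
            "give exactly one of cohort, sample_sheet, validation_matrix or counts"
        )
    if counts is not None:
        norm = normalize(counts, signature.base_constant)
        values = log_transform(norm)
        present = [f.id for f in signature.features if f.id in values.index]
        missing = [f.id for f in signature.features if f.id not in values.index]
        from kmersig.transfer import predict_validation

        recovery = pd.Series(
            {f.id: 1.0 if f.id in present else 0.0 for f in signature.features},
            name="kmer_recovery",
        )
        # gene values are already on the model scale; predict_validation
        # applies log1p to its input, so hand it the normalized values
        return predict_validation(
            signature, norm.values, labels=labels,
            missing_contigs=missing, kmer_recovery=recovery,
        )
    if validation_matrix is None:
        source = cohort if cohort is not None else sample_sheet
        if params is None:
            n_samples = (
                len(source.sample_ids)
                if isinstance(source, SyntheticCohort)
                else len(read_sample_sheet(source) if not isinstance(source, pd.DataFrame) else source)
            )
            k = int(signature.metadata.get("k", 31))
            params = KmerParams(
                k=k, min_recurrence=KmerParams.default_recurrence(n_samples)
            )
        validation_matrix = count_cohort(source, params)
    return transfer_signature(
        signature, validation_matrix, labels=labels, absent_policy=absent_policy
    )
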