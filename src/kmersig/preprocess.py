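"""Count normalization and clinical outcome labelling.

Normalization scales each sample column to a fixed library size: feature
value = raw count / (sample total) * C_b, with C_b = 1e6 for gene matrices
(counts per million) and 1e9 for contig matrices (counts per billion).
Downstream models work on log(value + 1).

Two labelling tasks are supported for prostate-cancer style cohorts:

* **risk** — an adaptation of the d'Amico classification using only
  anatomo-pathological data (no PSA): low risk for Gleason 6 or 7(3+4)
  with stage pT1/pT2; high risk for Gleason 8/9 and/or stage pT3b/pT4;
  everything in between (pT3a, or pT2 with Gleason 7(4+3)) is intermediate
  and excluded.  The source rule lists pT1 both as low-risk and as
  intermediate; ``pt1_policy`` selects the reading (default ``"low"``).
* **relapse** — biochemical relapse within ``t_relapse`` years is positive;
  no relapse with follow-up beyond ``t_nonrelapse`` years is negative;
  anything else (including censoring inside the window) is unlabeled.
  Default cutoffs (2, 5) years; low-follow-up cohorts may use (5, 10).

Labels are POSITIVE / NEGATIVE / UNLABELED; unlabeled samples are excluded
from training and evaluation, never silently guessed.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
UNLABELED = "UNLABELED"

GENE_BASE_CONSTANT = 10**6
CONTIG_BASE_CONSTANT = 10**9


@dataclass
class NormalizedMatrix:
    """Feature x sample matrix of library-size-normalized values."""

    values: pd.DataFrame
    base_constant: float

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CohortLabels:
    """sample_id -> POSITIVE / NEGATIVE / UNLABELED for one task."""

    labels: pd.Series
    task: str
    rule_set: str

    def labeled_samples(self) -> list[str]:
        return list(self.labels.index[self.labels != UNLABELED])

    def binary(self, samples=None) -> pd.Series:
        """0/1 vector over labeled samples (optionally restricted/ordered)."""
        lab = self.labels[self.labels != UNLABELED]
        if samples is not None:
            lab = lab.reindex([s for s in samples if s in lab.index])
        return (lab == POSITIVE).astype(int)

    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def normalize(matrix, base_constant: float) -> NormalizedMatrix:
    """Scale every sample column to sum to ``base_constant``.

    Accepts a DataFrame (features x samples) or anything with
    ``.to_frame()`` producing one (e.g. KmerCountMatrix).  A sample whose
    raw total is zero maps to an all-zero column with a warning.
    """
    if hasattr(matrix, "to_frame"):
        matrix = matrix.to_frame()
    values = matrix.astype(float)
    if (values.to_numpy() < 0).any():
        raise ValueError("negative counts cannot be normalized")
    totals = values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) have zero total count and normalize to all zeros"
        )
    safe = totals.replace(0, np.nan)
    out = values.div(safe, axis=1).fillna(0.0) * base_constant
    return NormalizedMatrix(values=out, base_constant=float(base_constant))


def log_transform(norm: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    """Natural log of (normalized value + 1), the modelling scale."""
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    return np.log1p(values)


# ---------------------------------------------------------------------------
# outcome labelling
# ---------------------------------------------------------------------------

_STAGE_RE = re.compile(r"^p?t(\d)([a-c]?)", re.IGNORECASE)


def _parse_stage(value) -> tuple[int, str] | None:
    """Parse a pT stage string into (number, substage letter or '')."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    m = _STAGE_RE.match(str(value).strip())
    if not m:
        return None
    return int(m.group(1)), m.group(2).lower()


def _parse_gleason(row, total_col, primary_col, secondary_col):
    """Return (total, primary, secondary) ints, None where unavailable."""

    def _get(col):
        if col is None or col not in row or pd.isna(row[col]):
            return None
        try:
            return int(float(row[col]))
        except (TypeError, ValueError):
            return None

    return _get(total_col), _get(primary_col), _get(secondary_col)


def label_risk(
    clinical: pd.DataFrame,
    sample_col: str = "sample_id",
    gleason_col: str = "gleason",
    primary_col: str | None = "gleason_primary",
    secondary_col: str | None = "gleason_secondary",
    stage_col: str = "stage",
    pt1_policy: str = "low",
) -> CohortLabels:
    """Assign low/high risk labels from Gleason score and pT stage.

    POSITIVE (high risk)  iff Gleason in {8, 9} or stage in {pT3b, pT4};
    NEGATIVE (low risk)   iff Gleason in {6, 7 (3+4)} and stage in
    {pT1, pT2} (pT1 only when ``pt1_policy == "low"``); anything else —
    pT3a, pT2 with Gleason 7 (4+3), Gleason 7 without a pattern split,
    unparseable fields — is UNLABELED.
    """
    if pt1_policy not in ("low", "intermediate"):
        raise ValueError("pt1_policy must be 'low' or 'intermediate'")
    labels = {}
    for _, row in clinical.iterrows():
        sid = row[sample_col]
        total, primary, secondary = _parse_gleason(row, gleason_col, primary_col, secondary_col)
        if total is None and primary is not None and secondary is not None:
            total = primary + secondary
        stage = _parse_stage(row.get(stage_col))
        label = UNLABELED
        if total is None or stage is None:
            warnings.warn(f"sample {sid}: unparseable Gleason/stage, left UNLABELED")
        else:
            stage_num, stage_sub = stage
            high_stage = (stage_num == 3 and stage_sub == "b") or stage_num == 4
            if total in (8, 9) or high_stage:
                label = POSITIVE
            else:
                gleason_low = total == 6 or (
                    total == 7 and primary == 3 and secondary == 4
                )
                low_stage = stage_num == 2 or (stage_num == 1 and pt1_policy == "low")
                if total == 7 and (primary is None or secondary is None):
                    warnings.warn(
                        f"sample {sid}: Gleason 7 without pattern split, left UNLABELED"
                    )
                elif gleason_low and low_stage:
                    label = NEGATIVE
        labels[sid] = label
    series = pd.Series(labels, name="label")
    return CohortLabels(labels=series, task="risk", rule_set=f"damico_no_psa[pt1={pt1_policy}]")


def label_relapse(
    clinical: pd.DataFrame,
    sample_col: str = "sample_id",
    event_col: str = "event",
    time_col: str = "time",
    cutoffs: tuple[float, float] = (2.0, 5.0),
) -> CohortLabels:
    """Assign relapse labels from an event flag and a follow-up time.

    POSITIVE iff event occurred and time < cutoffs[0] years; NEGATIVE iff
    no event and time > cutoffs[1] years; otherwise UNLABELED.
    """
    t_relapse, t_nonrelapse = cutoffs
    if not (0 < t_relapse <= t_nonrelapse):
        raise ValueError(f"invalid cutoffs {cutoffs}")
    labels = {}
    for _, row in clinical.iterrows():
        sid = row[sample_col]
        event = row.get(event_col)
        time = row.get(time_col)
        label = UNLABELED
        if pd.isna(event):
            warnings.warn(f"sample {sid}: missing event flag, left UNLABELED")
        elif pd.isna(time):
            warnings.warn(f"sample {sid}: missing follow-up time, left UNLABELED")
        else:
            event = bool(int(event))
            time = float(time)
            if event and time < t_relapse:
                label = POSITIVE
            elif not event and time > t_nonrelapse:
                label = NEGATIVE
        labels[sid] = label
    series = pd.Series(labels, name="label")
    return CohortLabels(
        labels=series, task="relapse", rule_set=f"bcr[{t_relapse},{t_nonrelapse}]"
    )
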