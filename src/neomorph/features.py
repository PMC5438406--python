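"""Cohort feature-table assembly, outcome labeling and min-max scaling.

A cohort table holds one row per subject with the 14 canonical descriptors
(in the fixed order used throughout the package and its reports), the raw
Bayley composite scores, and binary low-outcome labels.  Three experimental
arms are supported: descriptors at 30 weeks PMA, at 40 weeks PMA, and the
serial change (40-week minus 30-week) for subjects imaged at both ages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .label_io import SubjectRecord

__all__ = [
    "DESCRIPTORS",
    "VOLUME_DESCRIPTORS",
    "MORPHOLOGY_DESCRIPTORS",
    "LOW_OUTCOME_THRESHOLD",
    "CohortTable",
    "ScalingParams",
    "label_low_outcome",
    "build_arm",
    "fit_minmax",
    "apply_minmax",
]

#: the 14 descriptors in canonical report order
DESCRIPTORS: tuple[str, ...] = (
    "GA", "CB", "mWM", "BGT", "vCSF", "uWM", "BS", "cGM", "eCSF",
    "ISA", "MC", "GI", "MT", "BV",
)
#: the eight relative tissue volumes plus total brain/intracranial volume
VOLUME_DESCRIPTORS: tuple[str, ...] = (
    "CB", "mWM", "BGT", "vCSF", "uWM", "BS", "cGM", "eCSF", "BV",
)
#: the four measures of cortical morphology
MORPHOLOGY_DESCRIPTORS: tuple[str, ...] = ("ISA", "MC", "GI", "MT")

#: Bayley composite score below which outcome is classed as low (-1 SD)
LOW_OUTCOME_THRESHOLD: float = 85.0

ARMS = ("30wk", "40wk", "delta")


def label_low_outcome(score: float, threshold: float = LOW_OUTCOME_THRESHOLD) -> int:
    """Binary low-outcome label: 1 iff the composite score is strictly below
    the threshold (default 85); a score exactly at the threshold is
    favourable."""
    return int(score < threshold)


@dataclass
class CohortTable:
    """Subjects x descriptors with outcome scores and binary labels.

    ``frame`` columns: ``subject_id``, the 14 :data:`DESCRIPTORS`,
    ``cognitive_score``/``motor_score`` (may hold NaN for unassessed
    subjects) and ``outcome_cognitive``/``outcome_motor`` labels.
    Rows are sorted by ``subject_id`` so assembly is order-independent.
    """

    frame: pd.DataFrame
    arm: str

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        missing = [c for c in ("subject_id", *DESCRIPTORS) if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    def features(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """Descriptor matrix (n_subjects x n_descriptors) as float64."""
        cols = list(subset) if subset is not None else list(DESCRIPTORS)
        unknown = [c for c in cols if c not in DESCRIPTORS]
        if unknown:
            raise ValueError(f"unknown descriptors: {unknown}")
        return self.frame[cols].to_numpy(dtype=np.float64)

    def labels(self, outcome: str) -> np.ndarray:
        """Binary low-outcome labels for ``outcome`` in {cognitive, motor}."""
        col = f"outcome_{outcome}"
        if col not in self.frame.columns:
            raise ValueError(f"no {col!r} column; outcome must be 'cognitive' or 'motor'")
        lab = self.frame[col].to_numpy()
        if np.isnan(lab.astype(float)).any():
            raise ValueError(f"{col} contains missing labels; drop unassessed subjects first")
        return lab.astype(np.int64)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, arm: str) -> "CohortTable":
        return cls(frame=pd.read_csv(path, dtype={"subject_id": str}), arm=arm)


def build_arm(
    records: Iterable[SubjectRecord],
    descriptors: Mapping[tuple[str, str], Mapping[str, float]],
    arm: str,
    outcome: str | None = None,
    threshold: float = LOW_OUTCOME_THRESHOLD,
) -> CohortTable:
    """Assemble one experimental arm into a :class:`CohortTable`.

    Parameters
    ----------
    records:
        Subject metadata (gestational age, Bayley scores).
    descriptors:
        ``(subject_id, timepoint)`` -> descriptor-name -> value, where
        timepoint is ``"30wk"`` or ``"40wk"``.  The 13 image descriptors
        are required; a ``"GA"`` entry, if present, is ignored in favour
        of the subject record.
    arm:
        ``"30wk"``, ``"40wk"`` or ``"delta"``.  The delta arm keeps only
        subjects with both timepoints; image descriptors are differenced
        (40wk - 30wk) while GA at birth is passed through unchanged.
    outcome:
        If given (``"cognitive"`` or ``"motor"``), subjects without that
        Bayley score are dropped; otherwise subjects missing *both*
        scores are dropped.

    Dropped-subject counts are recorded in ``frame.attrs["n_dropped"]``.
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    image_cols = [d for d in DESCRIPTORS if d != "GA"]
    rows, n_dropped = [], 0
    for rec in sorted(records, key=lambda r: r.subject_id):
        if arm == "delta":
            need = [("30wk",), ("40wk",)]
        else:
            need = [(arm,)]
        keys = [(rec.subject_id, tp[0]) for tp in need]
        if any(k not in descriptors for k in keys):
            n_dropped += 1
            continue
        score_ok = {
            "cognitive": rec.cognitive_score is not None,
            "motor": rec.motor_score is not None,
        }
        if outcome is not None:
            if not score_ok[outcome]:
                n_dropped += 1
                continue
        elif not (score_ok["cognitive"] or score_ok["motor"]):
            n_dropped += 1
            continue
        row: dict[str, object] = {"subject_id": rec.subject_id, "GA": rec.ga_birth}
        if arm == "delta":
            d30, d40 = descriptors[keys[0]], descriptors[keys[1]]
            for c in image_cols:
                row[c] = float(d40[c]) - float(d30[c])
        else:
            src = descriptors[keys[0]]
            for c in image_cols:
                row[c] = float(src[c])
        row["cognitive_score"] = np.nan if rec.cognitive_score is None else rec.cognitive_score
        row["motor_score"] = np.nan if rec.motor_score is None else rec.motor_score
        row["outcome_cognitive"] = (
            np.nan if rec.cognitive_score is None else label_low_outcome(rec.cognitive_score, threshold)
        )
        row["outcome_motor"] = (
            np.nan if rec.motor_score is None else label_low_outcome(rec.motor_score, threshold)
        )
        rows.append(row)
    if not rows:
        raise ValueError(f"arm {arm!r}: no subject has the required scans and scores")
    frame = pd.DataFrame(rows)
    frame.attrs["n_dropped"] = n_dropped
    return CohortTable(frame=frame, arm=arm)


@dataclass
class ScalingParams:
    """Per-descriptor min/max estimated on a training subset.

    The transform is x -> (x - min) / (max - min).  Constant descriptors
    (max == min) map to 0.  Test values outside the training range are
    deliberately NOT clipped, so scaled values may fall outside [0, 1]:
    clipping would discard rank information for a linear classifier.
    """

    columns: tuple[str, ...]
    minimum: np.ndarray
    maximum: np.ndarray

    @property
    def constant_mask(self) -> np.ndarray:
        return self.maximum == self.minimum


def fit_minmax(X: np.ndarray, columns: Sequence[str] | None = None) -> ScalingParams:
    """Estimate min-max scaling parameters from training rows only."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training matrix must be 2-D and non-empty")
    cols = tuple(columns) if columns is not None else tuple(f"x{i}" for i in range(X.shape[1]))
    return ScalingParams(columns=cols, minimum=X.min(axis=0), maximum=X.max(axis=0))


def apply_minmax(params: ScalingParams, X: np.ndarray) -> np.ndarray:
    """Apply fitted min-max scaling (no clipping) to rows."""
    X = np.asarray(X, dtype=np.float64)
    span = params.maximum - params.minimum
    safe = np.where(span == 0, 1.0, span)
    out = (X - params.minimum) / safe
    out[:, params.constant_mask] = 0.0
    return out
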