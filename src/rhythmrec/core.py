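"""Domain types, feature encoding, and the outcome-reward function.

The action space is the four rhythm-management strategies; patient context is
a fixed 8-feature clinical vector encoded as a length-9 design vector
(intercept + 4 z-scored continuous features + 4 binary flags).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np

from .errors import (
    EmptyCohortError,
    MissingFieldError,
    OutOfRangeError,
    ZeroVarianceError,
)

__all__ = [
    "Action",
    "PatientRecord",
    "OutcomeRecord",
    "RewardSpec",
    "FeatureScaler",
    "CONTINUOUS_FEATURES",
    "BINARY_FEATURES",
    "FEATURE_NAMES",
    "N_FEATURES",
    "N_ACTIONS",
    "validate_record",
    "fit_scaler",
    "encode_features",
    "compute_reward",
]


class Action(IntEnum):
    """The four rhythm-management strategies, in fixed index order."""

    RAC = 0  # rate control
    EXC = 1  # external cardioversion
    AAM = 2  # antiarrhythmic medication
    AFA = 3  # AF ablation

    @classmethod
    def from_code(cls, code: str) -> "Action":
        try:
            return cls[code.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown action code {code!r}; expected one of "
                f"{[a.name for a in cls]}"
            ) from None


N_ACTIONS = len(Action)

#: continuous features, in design-vector order (slots 1..4)
CONTINUOUS_FEATURES = ("age", "af_duration_months", "resting_hr", "bmi")
#: binary features, in design-vector order (slots 5..8)
BINARY_FEATURES = ("heart_failure", "la_enlargement", "hypertension", "symptomatic")
FEATURE_NAMES = ("intercept",) + CONTINUOUS_FEATURES + BINARY_FEATURES
N_FEATURES = len(FEATURE_NAMES)  # 9

# allowed (lo, hi) per continuous feature; binaries must be exactly 0/1
_RANGES = {
    "age": (30.0, 100.0),
    "af_duration_months": (0.0, float("inf")),
    "resting_hr": (30.0, 220.0),
    "bmi": (12.0, 70.0),
}


@dataclass(frozen=True)
class OutcomeRecord:
    """Binary follow-up outcome flags for one patient."""

    stroke: int
    hospitalization: int
    symptomatic_recurrence: int

    def __post_init__(self):
        for name in ("stroke", "hospitalization", "symptomatic_recurrence"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise OutOfRangeError(name, v, 0, 1)


@dataclass(frozen=True)
class RewardSpec:
    """Weights of the linear outcome-reward function (all non-positive)."""

    stroke_weight: float = -2.0
    hospitalization_weight: float = -1.0
    recurrence_weight: float = -1.0

    def __post_init__(self):
        for name in ("stroke_weight", "hospitalization_weight", "recurrence_weight"):
            v = getattr(self, name)
            if v > 0:
                raise ValueError(f"{name} must be <= 0, got {v}")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's clinical features plus optional label and outcomes.

    All eight features are required for validation; ``expert_action`` is
    needed only for supervised training rows and ``outcomes`` only for
    reinforcement-learning rows.
    """

    age: Optional[float] = None
    af_duration_months: Optional[float] = None
    heart_failure: Optional[int] = None
    la_enlargement: Optional[int] = None
    resting_hr: Optional[float] = None
    hypertension: Optional[int] = None
    bmi: Optional[float] = None
    symptomatic: Optional[int] = None
    expert_action: Optional[Action] = None
    outcomes: Optional[OutcomeRecord] = None
    patient_id: Optional[str] = None

    def with_label(self, action: Action) -> "PatientRecord":
        return replace(self, expert_action=action)

    def with_outcomes(self, outcomes: OutcomeRecord) -> "PatientRecord":
        return replace(self, outcomes=outcomes)


def validate_record(record: PatientRecord) -> PatientRecord:
    """Return ``record`` unchanged if every feature is present and in range.

    Raises :class:`MissingFieldError` or :class:`OutOfRangeError` otherwise.
    Idempotent and deterministic; never mutates or imputes.
    """
    for name in CONTINUOUS_FEATURES:
        v = getattr(record, name)
        if v is None:
            raise MissingFieldError(name)
        lo, hi = _RANGES[name]
        if not (lo <= float(v) <= hi) or not np.isfinite(v):
            raise OutOfRangeError(name, v, lo, hi)
    for name in BINARY_FEATURES:
        v = getattr(record, name)
        if v is None:
            raise MissingFieldError(name)
        if v not in (0, 1):
            raise OutOfRangeError(name, v, 0, 1)
    return record


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature mean/SD for z-scoring the continuous features.

    SDs use the sample (n-1) convention and must be strictly positive.
    """

    means: tuple
    sds: tuple

    def __post_init__(self):
        if len(self.means) != len(CONTINUOUS_FEATURES) or len(self.sds) != len(
            CONTINUOUS_FEATURES
        ):
            raise ValueError(
                f"scaler needs {len(CONTINUOUS_FEATURES)} means and sds"
            )
        for name, sd in zip(CONTINUOUS_FEATURES, self.sds):
            if not (sd > 0) or not np.isfinite(sd):
                raise ZeroVarianceError(name)

    def to_dict(self) -> dict:
        return {"means": list(self.means), "sds": list(self.sds)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(means=tuple(d["means"]), sds=tuple(d["sds"]))


def fit_scaler(cohort: Sequence[PatientRecord]) -> FeatureScaler:
    """Fit a :class:`FeatureScaler` on a cohort's continuous features.

    Raises :class:`EmptyCohortError` on an empty cohort and
    :class:`ZeroVarianceError` naming the first degenerate feature.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot fit a scaler on an empty cohort")
    for rec in cohort:
        validate_record(rec)
    means = []
    sds = []
    for name in CONTINUOUS_FEATURES:
        vals = np.array([float(getattr(r, name)) for r in cohort], dtype=float)
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        if not sd > 0:
            raise ZeroVarianceError(name)
        means.append(mu)
        sds.append(sd)
    return FeatureScaler(means=tuple(means), sds=tuple(sds))


def encode_features(record: PatientRecord, scaler: FeatureScaler) -> np.ndarray:
    """Encode a validated record as the length-9 design vector.

    Layout: intercept 1, then z-scored (age, AF duration, resting HR, BMI),
    then 0/1 (heart failure, LA enlargement, hypertension, symptomatic).
    """
    validate_record(record)
    x = np.empty(N_FEATURES, dtype=float)
    x[0] = 1.0
    for i, name in enumerate(CONTINUOUS_FEATURES):
        x[1 + i] = (float(getattr(record, name)) - scaler.means[i]) / scaler.sds[i]
    for i, name in enumerate(BINARY_FEATURES):
        x[5 + i] = float(getattr(record, name))
    return x


def compute_reward(outcomes: OutcomeRecord, spec: RewardSpec = RewardSpec()) -> float:
    """Scalar reward for one follow-up episode.

    Default spec: -2*stroke - hospitalization - symptomatic_recurrence,
    giving a range of [-4, 0].
    """
    return (
        spec.stroke_weight * outcomes.stroke
        + spec.hospitalization_weight * outcomes.hospitalization
        + spec.recurrence_weight * outcomes.symptomatic_recurrence
    )
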