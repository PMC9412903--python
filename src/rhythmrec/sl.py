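"""Supervised expert-mimicry stage.

A linear score per action, trained by per-record stochastic gradient descent
against the clinician's chosen strategy. Two loss modes share one update
rule: ``softmax_ce`` (multinomial logistic regression, the default) and
``mse_onehot`` (squared error of the raw linear scores against the one-hot
label, the literal linear-regression reading).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (
    Action,
    FeatureScaler,
    N_ACTIONS,
    N_FEATURES,
    PatientRecord,
    encode_features,
    fit_scaler,
    validate_record,
)
from .errors import DimensionMismatchError, EmptyCohortError, UnlabeledRecordError

__all__ = [
    "SLPolicyModel",
    "SLTrainConfig",
    "LOSS_MODES",
    "sl_predict",
    "sl_update",
    "sl_train",
    "sl_loss",
    "sl_best_action",
]

LOSS_MODES = ("softmax_ce", "mse_onehot")

DEFAULT_SL_LEARNING_RATE = 0.1


def _check_x(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (N_FEATURES,):
        raise DimensionMismatchError(
            f"feature vector has shape {x.shape}, expected ({N_FEATURES},)"
        )
    return x


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass(frozen=True)
class SLPolicyModel:
    """Per-action linear weights mapping a design vector to a strategy
    frequency distribution."""

    weights: np.ndarray  # (4, 9), rows in Action index order
    scaler: FeatureScaler
    loss_mode: str = "softmax_ce"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_ACTIONS, N_FEATURES):
            raise DimensionMismatchError(
                f"weights have shape {w.shape}, expected ({N_ACTIONS}, {N_FEATURES})"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")
        object.__setattr__(self, "weights", w)

    @property
    def model_id(self) -> str:
        h = hashlib.sha256(self.weights.tobytes() + self.loss_mode.encode())
        return "sl-" + h.hexdigest()[:12]

    @classmethod
    def zeros(cls, scaler: FeatureScaler, loss_mode: str = "softmax_ce") -> "SLPolicyModel":
        return cls(np.zeros((N_ACTIONS, N_FEATURES)), scaler, loss_mode)


@dataclass(frozen=True)
class SLTrainConfig:
    learning_rate: float = DEFAULT_SL_LEARNING_RATE
    epochs: int = 50
    shuffle_seed: int = 0
    loss_mode: str = "softmax_ce"
    l2: float = 0.0  # optional ridge penalty; 0 disables

    def __post_init__(self):
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")


def sl_predict(model: SLPolicyModel, x: np.ndarray) -> np.ndarray:
    """Frequency distribution over the 4 actions for one encoded patient.

    ``softmax_ce``: softmax of the linear scores. ``mse_onehot``: scores
    clipped at 0 and renormalized, falling back to uniform when all clip
    to zero. Always a valid probability vector.
    """
    x = _check_x(x)
    scores = model.weights @ x
    if model.loss_mode == "softmax_ce":
        return _softmax(scores)
    clipped = np.clip(scores, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        return np.full(N_ACTIONS, 1.0 / N_ACTIONS)
    return clipped / total


def _gradient(model: SLPolicyModel, x: np.ndarray, chosen: Action, l2: float = 0.0) -> np.ndarray:
    """Gradient of the configured per-record loss w.r.t. the weight matrix."""
    y = np.zeros(N_ACTIONS)
    y[int(chosen)] = 1.0
    if model.loss_mode == "softmax_ce":
        pred = _softmax(model.weights @ x)
    else:  # mse_onehot: loss = 0.5 * ||Wx - y||^2
        pred = model.weights @ x
    g = np.outer(pred - y, x)
    if l2:
        g = g + l2 * model.weights
    return g


def sl_update(
    model: SLPolicyModel, x: np.ndarray, chosen: Action, lr: float, l2: float = 0.0
) -> SLPolicyModel:
    """One SGD step: W <- W - lr * grad. Returns a new model."""
    x = _check_x(x)
    g = _gradient(model, x, chosen, l2)
    return replace(model, weights=model.weights - lr * g)


def sl_loss(model: SLPolicyModel, cohort: Sequence[PatientRecord]) -> float:
    """Mean per-record loss of the configured mode over a labeled cohort."""
    if len(cohort) == 0:
        raise EmptyCohortError("cannot evaluate loss on an empty cohort")
    total = 0.0
    for rec in cohort:
        if rec.expert_action is None:
            raise UnlabeledRecordError(
                f"record {rec.patient_id!r} has no expert action label"
            )
        x = encode_features(rec, model.scaler)
        a = int(rec.expert_action)
        if model.loss_mode == "softmax_ce":
            p = sl_predict(model, x)
            total += -np.log(max(p[a], 1e-300))
        else:
            y = np.zeros(N_ACTIONS)
            y[a] = 1.0
            resid = model.weights @ x - y
            total += 0.5 * float(resid @ resid)
    return total / len(cohort)


def sl_train(
    cohort: Sequence[PatientRecord], config: SLTrainConfig = SLTrainConfig()
) -> SLPolicyModel:
    """Fit the scaler, start from zero weights, and run seeded per-record SGD.

    Records are reshuffled each epoch by a generator seeded with
    ``config.shuffle_seed``, so runs are bit-reproducible.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot train on an empty cohort")
    for rec in cohort:
        validate_record(rec)
        if rec.expert_action is None:
            raise UnlabeledRecordError(
                f"record {rec.patient_id!r} has no expert action label"
            )
    scaler = fit_scaler(cohort)
    xs = np.stack([encode_features(r, scaler) for r in cohort])
    labels = np.array([int(r.expert_action) for r in cohort])

    rng = np.random.default_rng(config.shuffle_seed)
    W = np.zeros((N_ACTIONS, N_FEATURES))
    n = len(cohort)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for i in order:
            x = xs[i]
            scores = W @ x
            if config.loss_mode == "softmax_ce":
                pred = _softmax(scores)
            else:
                pred = scores
            pred[labels[i]] -= 1.0
            g = np.outer(pred, x)
            if config.l2:
                g += config.l2 * W
            W -= config.learning_rate * g
    return SLPolicyModel(W, scaler, config.loss_mode)


def sl_best_action(model: SLPolicyModel, x: np.ndarray) -> Action:
    """Single best action: argmax frequency, ties to the lowest index."""
    p = sl_predict(model, x)
    return Action(int(np.argmax(p)))
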