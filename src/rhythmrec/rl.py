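"""Reinforcement-learning stage: linear Q-learning over the 4 strategies.

Each treatment decision is a single-step episode (contextual bandit): the
target of the Q update is the observed follow-up reward itself. Weight
updates are delivered in batches (default 8 patients); per-experience
deltas are computed at the pre-batch weights and aggregated, so a batch is
invariant to the ordering of its experiences.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .core import Action, FeatureScaler, N_ACTIONS, N_FEATURES
from .errors import DimensionMismatchError, EmptyBatchError
from .sl import SLPolicyModel, _check_x

__all__ = [
    "QPolicyModel",
    "RLTrainConfig",
    "Experience",
    "q_predict",
    "q_single_delta",
    "q_batch_update",
    "rl_train",
    "greedy_action",
    "epsilon_greedy_action",
    "warm_start_from_sl",
]

DEFAULT_RL_LEARNING_RATE = 0.01
DEFAULT_BATCH_SIZE = 8


@dataclass(frozen=True)
class Experience:
    """One (context, action taken, observed reward) triple."""

    x: np.ndarray  # encoded feature vector, length 9
    action_taken: Action
    reward: float

    def __post_init__(self):
        x = _check_x(self.x)
        object.__setattr__(self, "x", x)
        if not np.isfinite(self.reward):
            raise ValueError("reward must be finite")


@dataclass(frozen=True)
class RLTrainConfig:
    learning_rate: float = DEFAULT_RL_LEARNING_RATE
    batch_size: int = DEFAULT_BATCH_SIZE
    batch_aggregation: str = "mean"  # or "sum"
    seed: int = 0

    def __post_init__(self):
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.batch_aggregation not in ("mean", "sum"):
            raise ValueError("batch_aggregation must be 'mean' or 'sum'")


@dataclass(frozen=True)
class QPolicyModel:
    """Per-action linear weights: row a gives Q(x, a) = V[a] . x.

    ``updates_applied`` counts applied batch updates; ``experiences_seen``
    counts experiences consumed into applied updates; ``pending`` holds a
    final partial batch awaiting completion.
    """

    weights: np.ndarray  # (4, 9)
    scaler: FeatureScaler
    updates_applied: int = 0
    experiences_seen: int = 0
    pending: Tuple[Experience, ...] = ()

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_ACTIONS, N_FEATURES):
            raise DimensionMismatchError(
                f"weights have shape {w.shape}, expected ({N_ACTIONS}, {N_FEATURES})"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if self.updates_applied < 0:
            raise ValueError("updates_applied must be >= 0")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "pending", tuple(self.pending))

    @property
    def model_id(self) -> str:
        h = hashlib.sha256(self.weights.tobytes())
        return "q-" + h.hexdigest()[:12]

    @classmethod
    def zeros(cls, scaler: FeatureScaler) -> "QPolicyModel":
        return cls(np.zeros((N_ACTIONS, N_FEATURES)), scaler)


def warm_start_from_sl(sl_model: SLPolicyModel, scale: float = 1.0) -> QPolicyModel:
    """Q model whose initial greedy actions match the SL argmax (scaffold).

    The SL weight rows are copied (optionally scaled); argmax of V.x then
    equals argmax of the SL scores for every context.
    """
    if not scale > 0:
        raise ValueError("scale must be > 0")
    return QPolicyModel(scale * sl_model.weights.copy(), sl_model.scaler)


def q_predict(model: QPolicyModel, x: np.ndarray) -> np.ndarray:
    """Q-value estimates (4 unbounded reals) for one encoded patient."""
    x = _check_x(x)
    return model.weights @ x


def q_single_delta(model: QPolicyModel, e: Experience, lr: float) -> np.ndarray:
    """Weight delta from one experience: lr * (r - Q(x,a)) * x in the taken
    action's row, zero elsewhere. Pure; does not mutate the model."""
    q = float(model.weights[int(e.action_taken)] @ e.x)
    delta = np.zeros((N_ACTIONS, N_FEATURES))
    delta[int(e.action_taken)] = lr * (e.reward - q) * e.x
    return delta


def q_batch_update(
    model: QPolicyModel, batch: Sequence[Experience], config: RLTrainConfig = RLTrainConfig()
) -> QPolicyModel:
    """Apply one batch update.

    Every per-experience delta is computed at the pre-batch weights, then
    aggregated (mean by default) and applied once, so the result does not
    depend on the order of experiences within the batch.
    """
    if len(batch) == 0:
        raise EmptyBatchError("batch update requires at least one experience")
    deltas = [q_single_delta(model, e, config.learning_rate) for e in batch]
    agg = np.sum(deltas, axis=0)
    if config.batch_aggregation == "mean":
        agg /= len(batch)
    return replace(
        model,
        weights=model.weights + agg,
        updates_applied=model.updates_applied + 1,
        experiences_seen=model.experiences_seen + len(batch),
    )


def rl_train(
    model: QPolicyModel,
    experiences: Iterable[Experience],
    config: RLTrainConfig = RLTrainConfig(),
    flush_partial: bool = False,
) -> QPolicyModel:
    """Consume an experience stream in arrival order in batches of
    ``config.batch_size``.

    A trailing partial batch is carried on the model's ``pending`` buffer
    (and prepended on the next call) unless ``flush_partial`` is true, in
    which case it is applied immediately with the configured aggregation.
    """
    buffer = list(model.pending)
    model = replace(model, pending=())
    for e in experiences:
        buffer.append(e)
        if len(buffer) == config.batch_size:
            model = q_batch_update(model, buffer, config)
            buffer = []
    if buffer:
        if flush_partial:
            model = q_batch_update(model, buffer, config)
        else:
            model = replace(model, pending=tuple(buffer))
    return model


def greedy_action(model: QPolicyModel, x: np.ndarray) -> Action:
    """Argmax of the Q-values; ties broken by the lowest action index."""
    q = q_predict(model, x)
    return Action(int(np.argmax(q)))


def epsilon_greedy_action(
    model: QPolicyModel, x: np.ndarray, epsilon: float, rng: np.random.Generator
) -> Action:
    """Greedy action with probability 1-epsilon, else uniform random."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    if rng.random() < epsilon:
        return Action(int(rng.integers(N_ACTIONS)))
    return greedy_action(model, x)
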