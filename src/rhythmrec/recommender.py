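"""Two-stage decision surface: blends the mimicry distribution with the
value-derived distribution on a linear experience-count schedule."""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Optional

import numpy as np

from .core import Action, N_ACTIONS, PatientRecord, encode_features, validate_record
from .errors import ScalerMismatchError
from .rl import QPolicyModel, q_predict
from .sl import SLPolicyModel, _softmax, sl_predict

__all__ = [
    "BlendSchedule",
    "Recommendation",
    "blend_weight",
    "recommend",
    "format_recommendation",
]


@dataclass(frozen=True)
class BlendSchedule:
    """Linear SL-to-RL transition: blend weight beta(n) = min(1, n/N)."""

    switch_count: int = 500  # N: RL experiences at which blending reaches 1
    temperature: float = 1.0  # tau for softmax(Q / tau)

    def __post_init__(self):
        if self.switch_count < 1:
            raise ValueError("switch_count must be >= 1")
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class Recommendation:
    frequencies: np.ndarray  # 4 nonnegative reals summing to 1
    best_action: Action
    beta_used: float
    sl_model_id: str
    q_model_id: str

    def to_dict(self) -> dict:
        return {
            "frequencies": {a.name: float(self.frequencies[a]) for a in Action},
            "best_action": self.best_action.name,
            "beta": self.beta_used,
            "sl_model_id": self.sl_model_id,
            "q_model_id": self.q_model_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Recommendation":
        freqs = np.array([d["frequencies"][a.name] for a in Action], dtype=float)
        return cls(
            frequencies=freqs,
            best_action=Action.from_code(d["best_action"]),
            beta_used=float(d["beta"]),
            sl_model_id=d["sl_model_id"],
            q_model_id=d["q_model_id"],
        )


def blend_weight(n_rl_experiences: int, schedule: BlendSchedule) -> float:
    """min(1, n/N): 0 before any RL experience, 1 at the switch count."""
    if n_rl_experiences < 0:
        raise ValueError("n_rl_experiences must be >= 0")
    return min(1.0, n_rl_experiences / schedule.switch_count)


def recommend(
    sl: SLPolicyModel,
    q: QPolicyModel,
    record: PatientRecord,
    schedule: BlendSchedule = BlendSchedule(),
    n_rl_experiences: Optional[int] = None,
) -> Recommendation:
    """Per-action recommendation for one patient.

    frequencies = (1-beta) * sl_predict + beta * softmax(Q / tau), with beta
    from the schedule at the Q model's experience count (overridable via
    ``n_rl_experiences``). Both models must share a scaler.
    """
    if sl.scaler != q.scaler:
        raise ScalerMismatchError(
            "SL and Q models were fitted with different feature scalers"
        )
    validate_record(record)
    x = encode_features(record, sl.scaler)
    n = q.experiences_seen if n_rl_experiences is None else n_rl_experiences
    beta = blend_weight(n, schedule)
    p_sl = sl_predict(sl, x)
    p_rl = _softmax(q_predict(q, x) / schedule.temperature)
    freqs = (1.0 - beta) * p_sl + beta * p_rl
    return Recommendation(
        frequencies=freqs,
        best_action=Action(int(np.argmax(freqs))),
        beta_used=beta,
        sl_model_id=sl.model_id,
        q_model_id=q.model_id,
    )


def _pct(value: float) -> str:
    """Percentage with 1 decimal, half-even rounding."""
    return str(Decimal(repr(value * 100.0)).quantize(Decimal("0.1"), ROUND_HALF_EVEN))


def format_recommendation(rec: Recommendation, as_json: bool = False) -> str:
    """Stable plain-text (or full-precision JSON) rendering."""
    if as_json:
        return json.dumps(rec.to_dict(), indent=2, sort_keys=True)
    lines = [f"Recommended strategy: {rec.best_action.name}"]
    for a in Action:
        marker = " <-- recommended" if a == rec.best_action else ""
        lines.append(f"  {a.name}  {_pct(float(rec.frequencies[a]))}%{marker}")
    lines.append(f"  (blend weight beta = {rec.beta_used:.3f})")
    return "\n".join(lines)
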