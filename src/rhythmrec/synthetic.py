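"""Synthetic patient cohorts with a known expert policy and outcome model.

Two world flavours:

* :class:`SyntheticWorld` — continuous covariate distributions, a
  ground-truth linear expert score matrix, and per-outcome logistic models.
  Emulates the 100-patient chart-review initialization cohort.
* :class:`DiscreteWorld` — a small set of fixed patient templates with
  tabulated Bernoulli outcome rates, so expected rewards (and hence optimal
  policies and regrets) are computable in closed form. Used as the
  brute-force oracle in tests.

All distribution parameters, expert weights, and outcome coefficients here
are invented, clinically-plausible artifact defaults — tests depend only on
recovery of whatever ground truth is configured, never on the clinical
choices themselves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    Action,
    BINARY_FEATURES,
    CONTINUOUS_FEATURES,
    FeatureScaler,
    N_ACTIONS,
    N_FEATURES,
    OutcomeRecord,
    PatientRecord,
    RewardSpec,
    encode_features,
    validate_record,
)
from .errors import WorldConfigError
from .sl import _softmax

__all__ = [
    "SyntheticWorld",
    "DiscreteWorld",
    "TruncNormalSpec",
    "LogNormalSpec",
    "sample_cohort",
    "sample_outcomes",
    "outcome_probabilities",
    "expected_reward",
    "expected_reward_linear",
    "make_initialization_cohort",
    "default_world",
    "suboptimal_expert_world",
    "q_oracle_world",
    "q_oracle_scaler",
    "get_world",
    "WORLD_NAMES",
]

OUTCOME_NAMES = ("stroke", "hospitalization", "symptomatic_recurrence")


@dataclass(frozen=True)
class TruncNormalSpec:
    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self):
        if not (self.sd > 0 and self.lo < self.hi):
            raise WorldConfigError(f"bad truncated-normal spec: {self}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # rejection sampling; acceptance region is wide for all defaults
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean, self.sd, size=max(n - filled, 16))
            ok = draw[(draw >= self.lo) & (draw <= self.hi)]
            take = min(len(ok), n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out


@dataclass(frozen=True)
class LogNormalSpec:
    mu: float  # mean of log
    sigma: float  # sd of log
    hi: float = float("inf")

    def __post_init__(self):
        if not self.sigma > 0:
            raise WorldConfigError(f"bad log-normal spec: {self}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        draw = rng.lognormal(self.mu, self.sigma, size=n)
        return np.minimum(draw, self.hi)


@dataclass(frozen=True)
class SyntheticWorld:
    """Continuous-covariate world: feature samplers + ground-truth expert
    score matrix + per-outcome logistic coefficients.

    The expert and outcome models act on features encoded with the world's
    own fixed ``reference_scaler`` (nominal population moments), so the
    ground truth is independent of any cohort actually drawn.
    """

    age: TruncNormalSpec
    af_duration: LogNormalSpec
    resting_hr: TruncNormalSpec
    bmi: TruncNormalSpec
    p_heart_failure: float
    p_la_enlargement: float
    p_hypertension: float
    p_symptomatic: float
    expert_weights: np.ndarray  # (4, 9), ground-truth W*
    outcome_logits: np.ndarray  # (3, 4, 9): [outcome][action] -> logit coefs
    reference_scaler: FeatureScaler
    expert_mode: str = "argmax"  # or "softmax"
    name: str = "custom"

    def __post_init__(self):
        ew = np.asarray(self.expert_weights, dtype=float)
        ol = np.asarray(self.outcome_logits, dtype=float)
        if ew.shape != (N_ACTIONS, N_FEATURES):
            raise WorldConfigError(f"expert_weights shape {ew.shape}")
        if ol.shape != (3, N_ACTIONS, N_FEATURES):
            raise WorldConfigError(f"outcome_logits shape {ol.shape}")
        for p in (
            self.p_heart_failure,
            self.p_la_enlargement,
            self.p_hypertension,
            self.p_symptomatic,
        ):
            if not 0.0 <= p <= 1.0:
                raise WorldConfigError(f"binary prevalence {p} outside [0, 1]")
        if self.expert_mode not in ("argmax", "softmax"):
            raise WorldConfigError("expert_mode must be 'argmax' or 'softmax'")
        object.__setattr__(self, "expert_weights", ew)
        object.__setattr__(self, "outcome_logits", ol)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def plain(spec) -> dict:
            return {k: float(v) for k, v in vars(spec).items()}

        return {
            "kind": "continuous",
            "name": self.name,
            "age": plain(self.age),
            "af_duration": plain(self.af_duration),
            "resting_hr": plain(self.resting_hr),
            "bmi": plain(self.bmi),
            "p_heart_failure": self.p_heart_failure,
            "p_la_enlargement": self.p_la_enlargement,
            "p_hypertension": self.p_hypertension,
            "p_symptomatic": self.p_symptomatic,
            "expert_weights": self.expert_weights.tolist(),
            "outcome_logits": self.outcome_logits.tolist(),
            "reference_scaler": self.reference_scaler.to_dict(),
            "expert_mode": self.expert_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticWorld":
        if d.get("kind") != "continuous":
            raise WorldConfigError(f"not a continuous world config: kind={d.get('kind')!r}")
        return cls(
            age=TruncNormalSpec(**d["age"]),
            af_duration=LogNormalSpec(**d["af_duration"]),
            resting_hr=TruncNormalSpec(**d["resting_hr"]),
            bmi=TruncNormalSpec(**d["bmi"]),
            p_heart_failure=d["p_heart_failure"],
            p_la_enlargement=d["p_la_enlargement"],
            p_hypertension=d["p_hypertension"],
            p_symptomatic=d["p_symptomatic"],
            expert_weights=np.array(d["expert_weights"], dtype=float),
            outcome_logits=np.array(d["outcome_logits"], dtype=float),
            reference_scaler=FeatureScaler.from_dict(d["reference_scaler"]),
            expert_mode=d.get("expert_mode", "argmax"),
            name=d.get("name", "custom"),
        )


@dataclass(frozen=True)
class DiscreteWorld:
    """K fixed patient templates with tabulated per-(context, action)
    Bernoulli outcome rates; expected rewards are exact."""

    contexts: Tuple[PatientRecord, ...]  # templates without labels/outcomes
    probs: Tuple[float, ...]
    outcome_rates: np.ndarray  # (K, 4, 3): [context][action] -> 3 rates
    expert_actions: Tuple[Action, ...]  # deterministic expert per context
    name: str = "custom-discrete"

    def __post_init__(self):
        contexts = tuple(self.contexts)
        probs = tuple(float(p) for p in self.probs)
        rates = np.asarray(self.outcome_rates, dtype=float)
        k = len(contexts)
        if k == 0:
            raise WorldConfigError("discrete world needs at least one context")
        for rec in contexts:
            validate_record(rec)
        if len(probs) != k or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise WorldConfigError("context probabilities must be a distribution")
        if rates.shape != (k, N_ACTIONS, 3):
            raise WorldConfigError(
                f"outcome_rates shape {rates.shape}, expected ({k}, {N_ACTIONS}, 3)"
            )
        if rates.min() < 0 or rates.max() > 1:
            raise WorldConfigError("outcome rates must lie in [0, 1]")
        if len(self.expert_actions) != k:
            raise WorldConfigError("need one expert action per context")
        object.__setattr__(self, "contexts", contexts)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "outcome_rates", rates)
        object.__setattr__(self, "expert_actions", tuple(Action(a) for a in self.expert_actions))

    @property
    def n_contexts(self) -> int:
        return len(self.contexts)

    def context_index(self, record: PatientRecord) -> int:
        """Index of the template matching this record's 8 features."""
        for i, tpl in enumerate(self.contexts):
            if all(
                getattr(tpl, f) == getattr(record, f)
                for f in CONTINUOUS_FEATURES + BINARY_FEATURES
            ):
                return i
        raise WorldConfigError("record does not match any context template")

    def to_dict(self) -> dict:
        feat = CONTINUOUS_FEATURES + BINARY_FEATURES
        return {
            "kind": "discrete",
            "name": self.name,
            "contexts": [{f: getattr(c, f) for f in feat} for c in self.contexts],
            "probs": list(self.probs),
            "outcome_rates": self.outcome_rates.tolist(),
            "expert_actions": [a.name for a in self.expert_actions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteWorld":
        if d.get("kind") != "discrete":
            raise WorldConfigError(f"not a discrete world config: kind={d.get('kind')!r}")
        return cls(
            contexts=tuple(PatientRecord(**c) for c in d["contexts"]),
            probs=tuple(d["probs"]),
            outcome_rates=np.array(d["outcome_rates"], dtype=float),
            expert_actions=tuple(Action.from_code(a) for a in d["expert_actions"]),
            name=d.get("name", "custom-discrete"),
        )


# ---------------------------------------------------------------------------
# sampling


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def expert_action_for(
    world: SyntheticWorld, record: PatientRecord, rng: Optional[np.random.Generator] = None
) -> Action:
    """Ground-truth expert label: argmax (or seeded softmax draw) of W* . x."""
    x = encode_features(record, world.reference_scaler)
    scores = world.expert_weights @ x
    if world.expert_mode == "argmax":
        return Action(int(np.argmax(scores)))
    if rng is None:
        raise WorldConfigError("softmax expert mode requires an rng")
    p = _softmax(scores)
    return Action(int(rng.choice(N_ACTIONS, p=p)))


def sample_cohort(world, n: int, seed: int) -> List[PatientRecord]:
    """Draw ``n`` validated, expert-labeled records. Same seed, same cohort."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(world, DiscreteWorld):
        idx = rng.choice(world.n_contexts, size=n, p=world.probs)
        return [
            replace(
                world.contexts[i],
                expert_action=world.expert_actions[i],
                patient_id=f"d{pos:05d}",
            )
            for pos, i in enumerate(idx)
        ]
    if not isinstance(world, SyntheticWorld):
        raise WorldConfigError(f"unknown world type {type(world).__name__}")
    ages = world.age.sample(n, rng)
    durs = world.af_duration.sample(n, rng)
    hrs = world.resting_hr.sample(n, rng)
    bmis = world.bmi.sample(n, rng)
    hf = rng.random(n) < world.p_heart_failure
    lae = rng.random(n) < world.p_la_enlargement
    htn = rng.random(n) < world.p_hypertension
    sym = rng.random(n) < world.p_symptomatic
    cohort = []
    for i in range(n):
        rec = PatientRecord(
            age=float(ages[i]),
            af_duration_months=float(durs[i]),
            heart_failure=int(hf[i]),
            la_enlargement=int(lae[i]),
            resting_hr=float(hrs[i]),
            hypertension=int(htn[i]),
            bmi=float(bmis[i]),
            symptomatic=int(sym[i]),
            patient_id=f"s{i:05d}",
        )
        validate_record(rec)
        rec = rec.with_label(expert_action_for(world, rec, rng))
        cohort.append(rec)
    return cohort


def outcome_probabilities(world, record: PatientRecord, action: Action) -> np.ndarray:
    """(p_stroke, p_hosp, p_recurrence) for taking ``action`` on ``record``."""
    if isinstance(world, DiscreteWorld):
        return world.outcome_rates[world.context_index(record), int(action)].copy()
    if not isinstance(world, SyntheticWorld):
        raise WorldConfigError(f"unknown world type {type(world).__name__}")
    x = encode_features(record, world.reference_scaler)
    logits = world.outcome_logits[:, int(action), :] @ x
    return _sigmoid(logits)


def sample_outcomes(world, record: PatientRecord, action: Action, seed) -> OutcomeRecord:
    """Three seeded Bernoulli draws from the world's outcome model.

    ``seed`` may be an int or a ``numpy.random.Generator`` (for streaming)."""
    validate_record(record)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = outcome_probabilities(world, record, action)
    draws = rng.random(3) < p
    return OutcomeRecord(int(draws[0]), int(draws[1]), int(draws[2]))


# ---------------------------------------------------------------------------
# exact expectations (discrete worlds)


def expected_reward(
    world: DiscreteWorld, context: int, action: Action, spec: RewardSpec = RewardSpec()
) -> float:
    """Exact E[reward | context, action] by enumerating all 8 outcome
    combinations of the three independent Bernoulli flags."""
    if not isinstance(world, DiscreteWorld):
        raise WorldConfigError(
            "expected_reward is exact only for discrete worlds; use Monte-Carlo "
            "policy_value for continuous worlds"
        )
    rates = world.outcome_rates[context, int(action)]
    weights = (spec.stroke_weight, spec.hospitalization_weight, spec.recurrence_weight)
    total = 0.0
    for flags in itertools.product((0, 1), repeat=3):
        prob = 1.0
        reward = 0.0
        for f, p, w in zip(flags, rates, weights):
            prob *= p if f else (1.0 - p)
            reward += w * f
        total += prob * reward
    return total


def expected_reward_linear(
    world: DiscreteWorld, context: int, action: Action, spec: RewardSpec = RewardSpec()
) -> float:
    """Same expectation via linearity: spec-weighted sum of the three rates."""
    rates = world.outcome_rates[context, int(action)]
    return float(
        spec.stroke_weight * rates[0]
        + spec.hospitalization_weight * rates[1]
        + spec.recurrence_weight * rates[2]
    )


# ---------------------------------------------------------------------------
# named worlds


def _default_expert_weights() -> np.ndarray:
    # rows: RAC, EXC, AAM, AFA; cols: intercept, z_age, z_dur, z_hr, z_bmi,
    # hf, lae, htn, sympt. Textbook-consistent tendencies: symptomatic and
    # shorter-duration AF pushes toward rhythm control; older asymptomatic
    # patients toward rate control; LA enlargement away from ablation.
    return np.array(
        [
            [0.2, 1.0, 0.8, 0.2, 0.3, 0.5, 0.6, 0.2, -1.5],  # RAC
            [-0.5, -0.2, -1.0, 0.5, 0.0, 0.3, -0.3, 0.0, 1.0],  # EXC
            [0.3, 0.1, -0.2, 0.0, -0.1, -0.5, 0.0, 0.1, 0.8],  # AAM
            [-0.3, -1.2, -0.5, 0.2, -0.2, 0.4, -0.8, -0.1, 1.2],  # AFA
        ]
    )


def _default_outcome_logits() -> np.ndarray:
    ol = np.zeros((3, N_ACTIONS, N_FEATURES))
    # stroke: rare, rises with age / heart failure / hypertension
    for a in range(N_ACTIONS):
        ol[0, a, 0] = -3.4
        ol[0, a, 1] = 0.5  # z_age
        ol[0, a, 5] = 0.4  # heart failure
        ol[0, a, 7] = 0.3  # hypertension
    # hospitalization: higher for procedural strategies
    ol[1, :, 0] = [-1.8, -1.4, -1.5, -1.2]
    ol[1, :, 5] = 0.6
    # symptomatic recurrence: lowest after ablation, highest under rate control
    ol[2, :, 0] = [-0.1, 0.2, -0.4, -1.3]
    ol[2, :, 8] = 0.5  # symptomatic at baseline
    ol[2, :, 2] = 0.3  # longer AF duration
    return ol


def default_world() -> SyntheticWorld:
    """The default continuous world emulating an AF chart-review cohort."""
    return SyntheticWorld(
        age=TruncNormalSpec(68.0, 10.0, 35.0, 95.0),
        af_duration=LogNormalSpec(np.log(24.0), 0.8),
        resting_hr=TruncNormalSpec(88.0, 15.0, 40.0, 180.0),
        bmi=TruncNormalSpec(29.0, 5.0, 16.0, 55.0),
        p_heart_failure=0.3,
        p_la_enlargement=0.4,
        p_hypertension=0.6,
        p_symptomatic=0.55,
        expert_weights=_default_expert_weights(),
        outcome_logits=_default_outcome_logits(),
        # nominal population moments of the samplers (pre-truncation)
        reference_scaler=FeatureScaler(
            means=(68.0, 33.0, 88.0, 29.0), sds=(10.0, 31.0, 15.0, 5.0)
        ),
        expert_mode="argmax",
        name="default",
    )


def suboptimal_expert_world() -> DiscreteWorld:
    """Four-context discrete world whose expert is deliberately suboptimal in
    context 2 (prefers antiarrhythmics where ablation has the better expected
    reward). Exercises RL policy improvement over mimicry."""
    contexts = (
        PatientRecord(age=80, af_duration_months=48, heart_failure=1, la_enlargement=1,
                      resting_hr=75, hypertension=1, bmi=30, symptomatic=0),
        PatientRecord(age=45, af_duration_months=3, heart_failure=0, la_enlargement=0,
                      resting_hr=110, hypertension=0, bmi=24, symptomatic=1),
        PatientRecord(age=60, af_duration_months=12, heart_failure=0, la_enlargement=0,
                      resting_hr=95, hypertension=1, bmi=28, symptomatic=1),
        PatientRecord(age=55, af_duration_months=24, heart_failure=1, la_enlargement=0,
                      resting_hr=88, hypertension=0, bmi=33, symptomatic=1),
    )
    # (p_stroke, p_hosp, p_recurrence) per (context, action)
    rates = np.array(
        [
            [[0.03, 0.10, 0.10], [0.05, 0.40, 0.50], [0.04, 0.30, 0.40], [0.04, 0.50, 0.30]],
            [[0.01, 0.10, 0.60], [0.01, 0.10, 0.20], [0.01, 0.20, 0.30], [0.02, 0.30, 0.20]],
            [[0.05, 0.20, 0.70], [0.04, 0.30, 0.60], [0.05, 0.30, 0.50], [0.02, 0.20, 0.10]],
            [[0.02, 0.15, 0.55], [0.03, 0.20, 0.50], [0.02, 0.20, 0.35], [0.02, 0.25, 0.10]],
        ]
    )
    # expert matches the optimum everywhere except context 2 (AAM vs AFA)
    experts = (Action.RAC, Action.EXC, Action.AAM, Action.AFA)
    return DiscreteWorld(
        contexts=contexts,
        probs=(0.25, 0.25, 0.25, 0.25),
        outcome_rates=rates,
        expert_actions=experts,
        name="suboptimal-expert",
    )


def q_oracle_world() -> DiscreteWorld:
    """Four-context discrete world tuned as a Q-convergence oracle.

    Contexts are near-orthogonal in the encoded feature space (each deviates
    from the reference means in one continuous feature) and outcome rates are
    modest, keeping both the reward variance and the constant-step SGD noise
    floor low. Expected rewards and the optimal policy follow in closed form
    from the rate table. Pair with :func:`q_oracle_scaler` for encoding.
    """
    contexts = (
        PatientRecord(age=82, af_duration_months=33, heart_failure=0, la_enlargement=0,
                      resting_hr=88, hypertension=1, bmi=29, symptomatic=0),
        PatientRecord(age=70, af_duration_months=70.2, heart_failure=0, la_enlargement=0,
                      resting_hr=88, hypertension=0, bmi=29, symptomatic=1),
        PatientRecord(age=70, af_duration_months=33, heart_failure=1, la_enlargement=0,
                      resting_hr=106, hypertension=0, bmi=29, symptomatic=1),
        PatientRecord(age=70, af_duration_months=33, heart_failure=0, la_enlargement=1,
                      resting_hr=88, hypertension=0, bmi=35, symptomatic=1),
    )
    rates = np.array(
        [
            [[0.002, 0.015, 0.02], [0.004, 0.045, 0.09], [0.004, 0.04, 0.07], [0.004, 0.05, 0.045]],
            [[0.002, 0.015, 0.09], [0.002, 0.015, 0.02], [0.004, 0.04, 0.07], [0.004, 0.045, 0.05]],
            [[0.004, 0.02, 0.11], [0.004, 0.04, 0.09], [0.004, 0.03, 0.08], [0.002, 0.02, 0.015]],
            [[0.004, 0.03, 0.10], [0.004, 0.04, 0.08], [0.002, 0.015, 0.03], [0.004, 0.045, 0.07]],
        ]
    )
    return DiscreteWorld(
        contexts=contexts,
        probs=(0.25, 0.25, 0.25, 0.25),
        outcome_rates=rates,
        expert_actions=(Action.RAC, Action.EXC, Action.AFA, Action.AAM),
        name="discrete-oracle",
    )


def q_oracle_scaler() -> FeatureScaler:
    """Fixed reference scaler matching :func:`q_oracle_world`'s design."""
    return FeatureScaler(means=(70.0, 33.0, 88.0, 29.0), sds=(10.0, 31.0, 15.0, 5.0))


WORLD_NAMES = ("default", "suboptimal-expert", "discrete-oracle")


def get_world(name: str):
    """Look up a shipped named world fixture."""
    if name == "default":
        return default_world()
    if name == "suboptimal-expert":
        return suboptimal_expert_world()
    if name == "discrete-oracle":
        return q_oracle_world()
    raise WorldConfigError(f"unknown world {name!r}; known: {WORLD_NAMES}")


def make_initialization_cohort(seed: int = 0) -> List[PatientRecord]:
    """Exactly 100 labeled records from the default world — the starting
    cohort for the supervised stage."""
    return sample_cohort(default_world(), 100, seed)
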