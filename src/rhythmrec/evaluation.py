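"""Learning metrics: expert agreement, Q-estimation error, policy value,
and regret against the enumerated optimal policy.

A *policy* throughout is any callable mapping a validated
:class:`~rhythmrec.core.PatientRecord` to an :class:`~rhythmrec.core.Action`.
Discrete worlds admit exact (closed-form) values; continuous worlds are
evaluated by seeded Monte-Carlo with reported standard errors.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np

from .core import (
    Action,
    N_ACTIONS,
    PatientRecord,
    RewardSpec,
    compute_reward,
    encode_features,
    fit_scaler,
)
from .errors import EmptyCohortError, UnlabeledRecordError, WorldConfigError
from .rl import Experience, QPolicyModel, RLTrainConfig, greedy_action, rl_train
from .sl import SLPolicyModel, sl_best_action
from .synthetic import (
    DiscreteWorld,
    expected_reward,
    sample_cohort,
    sample_outcomes,
)

__all__ = [
    "EvalReport",
    "PolicyFn",
    "sl_policy_fn",
    "q_policy_fn",
    "expert_policy_fn",
    "policy_agreement",
    "policy_value",
    "policy_value_and_se",
    "optimal_value",
    "regret",
    "q_max_abs_error",
    "collect_experiences",
    "learning_curve",
]

PolicyFn = Callable[[PatientRecord], Action]


@dataclass(frozen=True)
class EvalReport:
    """One evaluation snapshot; ``None`` marks metrics not applicable."""

    policy_value: float
    regret: float
    n_eval: int
    seed: int
    sl_agreement: Optional[float] = None
    q_max_abs_error: Optional[float] = None
    policy_value_se: Optional[float] = None
    checkpoint: Optional[int] = None

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# policy adapters


def sl_policy_fn(model: SLPolicyModel) -> PolicyFn:
    """Mimicry policy: argmax of the SL frequency distribution."""
    return lambda rec: sl_best_action(model, encode_features(rec, model.scaler))


def q_policy_fn(model: QPolicyModel) -> PolicyFn:
    """Greedy value policy: argmax of the Q estimates."""
    return lambda rec: greedy_action(model, encode_features(rec, model.scaler))


def expert_policy_fn(world: DiscreteWorld) -> PolicyFn:
    """The discrete world's own (possibly suboptimal) expert."""
    return lambda rec: world.expert_actions[world.context_index(rec)]


# ---------------------------------------------------------------------------
# agreement


def policy_agreement(model: SLPolicyModel, cohort: Sequence[PatientRecord]) -> float:
    """Fraction of records where the model's best action equals the expert
    label."""
    if len(cohort) == 0:
        raise EmptyCohortError("cannot compute agreement on an empty cohort")
    hits = 0
    for rec in cohort:
        if rec.expert_action is None:
            raise UnlabeledRecordError(
                f"record {rec.patient_id!r} has no expert action label"
            )
        x = encode_features(rec, model.scaler)
        hits += int(sl_best_action(model, x) == rec.expert_action)
    return hits / len(cohort)


# ---------------------------------------------------------------------------
# value and regret


def _exact_policy_value(
    policy: PolicyFn, world: DiscreteWorld, spec: RewardSpec
) -> float:
    return sum(
        p * expected_reward(world, k, policy(ctx), spec)
        for k, (p, ctx) in enumerate(zip(world.probs, world.contexts))
    )


def policy_value_and_se(
    policy: PolicyFn,
    world,
    n: int,
    seed: int,
    spec: RewardSpec = RewardSpec(),
) -> tuple:
    """Monte-Carlo mean reward per decision and its standard error."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    records = sample_cohort(world, n, int(rng.integers(2**31)))
    rewards = np.empty(n)
    for i, rec in enumerate(records):
        a = policy(rec)
        out = sample_outcomes(world, rec, a, rng)
        rewards[i] = compute_reward(out, spec)
    se = float(rewards.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return float(rewards.mean()), se


def policy_value(
    policy: PolicyFn,
    world,
    n: int = 10_000,
    seed: int = 0,
    spec: RewardSpec = RewardSpec(),
    exact: bool = False,
) -> float:
    """Expected reward per decision under ``policy``.

    ``exact=True`` (discrete worlds only) uses the closed-form expectation;
    otherwise a seeded Monte-Carlo estimate over ``n`` rollouts.
    """
    if exact:
        if not isinstance(world, DiscreteWorld):
            raise WorldConfigError("exact policy value requires a discrete world")
        return _exact_policy_value(policy, world, spec)
    return policy_value_and_se(policy, world, n, seed, spec)[0]


def optimal_value(world: DiscreteWorld, spec: RewardSpec = RewardSpec()) -> float:
    """Exact value of the enumerated optimal policy."""
    if not isinstance(world, DiscreteWorld):
        raise WorldConfigError("optimal_value requires a discrete world")
    return sum(
        p * max(expected_reward(world, k, a, spec) for a in Action)
        for k, p in enumerate(world.probs)
    )


def optimal_policy_fn(world: DiscreteWorld, spec: RewardSpec = RewardSpec()) -> PolicyFn:
    """Brute-force optimal policy (ties to the lowest action index)."""
    best = {}
    for k, ctx in enumerate(world.contexts):
        values = [expected_reward(world, k, a, spec) for a in Action]
        best[k] = Action(int(np.argmax(values)))
    return lambda rec: best[world.context_index(rec)]


def regret(
    policy: PolicyFn,
    world,
    n: int = 10_000,
    seed: int = 0,
    spec: RewardSpec = RewardSpec(),
    exact: Optional[bool] = None,
) -> float:
    """Optimal value minus policy value; >= 0 exactly in discrete worlds.

    ``exact`` defaults to True for discrete worlds. Continuous worlds have
    no closed-form optimum; there regret is estimated against the best of
    the four constant-action policies by Monte-Carlo.
    """
    if exact is None:
        exact = isinstance(world, DiscreteWorld)
    if exact:
        return optimal_value(world, spec) - policy_value(
            policy, world, spec=spec, exact=True
        )
    best_const = max(
        policy_value_and_se(lambda _rec, _a=a: _a, world, n, seed + 1 + int(a), spec)[0]
        for a in Action
    )
    return best_const - policy_value(policy, world, n=n, seed=seed, spec=spec)


def q_max_abs_error(
    model: QPolicyModel, world: DiscreteWorld, spec: RewardSpec = RewardSpec()
) -> float:
    """max |Q(x, a) - E[reward | context, action]| over all pairs."""
    if not isinstance(world, DiscreteWorld):
        raise WorldConfigError("q_max_abs_error requires a discrete world")
    worst = 0.0
    for k, ctx in enumerate(world.contexts):
        x = encode_features(ctx, model.scaler)
        q = model.weights @ x
        for a in Action:
            worst = max(worst, abs(float(q[a]) - expected_reward(world, k, a, spec)))
    return worst


# ---------------------------------------------------------------------------
# experience collection and learning curves


def collect_experiences(
    world,
    n: int,
    seed: int,
    scaler,
    behavior: str = "uniform",
    model: Optional[QPolicyModel] = None,
    epsilon: float = 0.1,
    spec: RewardSpec = RewardSpec(),
) -> List[Experience]:
    """Simulate ``n`` treatment decisions and their follow-up rewards.

    ``behavior``: ``"uniform"`` explores all actions uniformly; ``"expert"``
    follows the world's expert labels; ``"epsilon-greedy"`` follows ``model``
    greedily with epsilon-random exploration.
    """
    from .rl import epsilon_greedy_action  # local import avoids cycle at module load

    rng = np.random.default_rng(seed)
    records = sample_cohort(world, n, int(rng.integers(2**31)))
    out = []
    for rec in records:
        x = encode_features(rec, scaler)
        if behavior == "uniform":
            a = Action(int(rng.integers(N_ACTIONS)))
        elif behavior == "expert":
            if rec.expert_action is None:
                raise UnlabeledRecordError("expert behavior needs labeled records")
            a = rec.expert_action
        elif behavior == "epsilon-greedy":
            if model is None:
                raise ValueError("epsilon-greedy behavior requires a Q model")
            a = epsilon_greedy_action(model, x, epsilon, rng)
        else:
            raise ValueError(f"unknown behavior {behavior!r}")
        outcomes = sample_outcomes(world, rec, a, rng)
        out.append(Experience(x=x, action_taken=a, reward=compute_reward(outcomes, spec)))
    return out


def learning_curve(
    world,
    checkpoints: Sequence[int],
    seed: int = 0,
    config: RLTrainConfig = RLTrainConfig(),
    spec: RewardSpec = RewardSpec(),
    behavior: str = "uniform",
    eval_n: int = 2_000,
    scaler=None,
) -> List[EvalReport]:
    """Train a Q model on a single behavior stream and evaluate it at each
    experience-count checkpoint. Checkpoints must be nondecreasing; fully
    reproducible from ``seed``."""
    checkpoints = list(checkpoints)
    if any(b < a for a, b in zip(checkpoints, checkpoints[1:])):
        raise ValueError("checkpoints must be nondecreasing")
    if checkpoints and checkpoints[0] < 0:
        raise ValueError("checkpoints must be >= 0")
    if scaler is None:
        scaler = fit_scaler(sample_cohort(world, 512, seed))
    total = checkpoints[-1] if checkpoints else 0
    stream = collect_experiences(world, total, seed + 1, scaler, behavior=behavior, spec=spec)
    model = QPolicyModel.zeros(scaler)
    reports = []
    consumed = 0
    exact = isinstance(world, DiscreteWorld)
    for cp in checkpoints:
        model = rl_train(model, stream[consumed:cp], config)
        consumed = cp
        pol = q_policy_fn(model)
        if exact:
            value = policy_value(pol, world, spec=spec, exact=True)
            gap = optimal_value(world, spec) - value
            qerr = q_max_abs_error(model, world, spec)
            se = None
        else:
            value, se = policy_value_and_se(pol, world, eval_n, seed + 2 + cp, spec)
            gap = regret(pol, world, n=eval_n, seed=seed + 3 + cp, spec=spec, exact=False)
            qerr = None
        reports.append(
            EvalReport(
                policy_value=value,
                regret=gap,
                n_eval=(0 if exact else eval_n),
                seed=seed,
                q_max_abs_error=qerr,
                policy_value_se=se,
                checkpoint=cp,
            )
        )
    return reports
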