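"""File formats: patient cohort CSV, experience log CSV, model JSON, and
world YAML.

One CSV dialect only: comma separator, UTF-8, required header, "." decimal.
Model JSON stores floats via Python's shortest round-trip representation,
so save -> load reproduces weights bit-exactly.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import yaml

from .core import (
    Action,
    FEATURE_NAMES,
    FeatureScaler,
    OutcomeRecord,
    PatientRecord,
    RewardSpec,
    compute_reward,
    encode_features,
    validate_record,
)
from .errors import CsvFormatError, ModelFormatError, WorldConfigError
from .rl import Experience, QPolicyModel
from .sl import SLPolicyModel
from .synthetic import (
    DiscreteWorld,
    SyntheticWorld,
    WORLD_NAMES,
    get_world,
)

__all__ = [
    "COHORT_CSV_HEADER",
    "EXPERIENCE_CSV_HEADER",
    "FORMAT_VERSION",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_experience_csv",
    "experiences_from_cohort",
    "save_model",
    "load_model",
    "load_world",
    "save_world",
]

COHORT_CSV_HEADER = [
    "patient_id",
    "age",
    "af_duration_months",
    "heart_failure",
    "la_enlargement",
    "resting_hr",
    "hypertension",
    "bmi",
    "symptomatic",
    "expert_action",
    "stroke",
    "hospitalization",
    "symptomatic_recurrence",
]

EXPERIENCE_CSV_HEADER = [
    "patient_id",
    "action_taken",
    "stroke",
    "hospitalization",
    "symptomatic_recurrence",
    "reward",
]

FORMAT_VERSION = 1

_OUTCOME_COLS = ("stroke", "hospitalization", "symptomatic_recurrence")


def _parse_float(value: str, row: int, col: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise CsvFormatError(
            f"row {row}: column {col!r}: cannot parse {value!r} as a number"
        ) from None


def _parse_binary(value: str, row: int, col: str) -> int:
    if value not in ("0", "1"):
        raise CsvFormatError(
            f"row {row}: column {col!r}: expected 0 or 1, got {value!r}"
        )
    return int(value)


def read_cohort_csv(path: Union[str, Path]) -> List[PatientRecord]:
    """Read and validate a patient cohort CSV.

    Error messages carry the 1-based data row index. Empty ``expert_action``
    and outcome cells yield ``None`` label/outcomes; partial outcome triples
    are rejected.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CsvFormatError(f"{path}: empty file, expected header") from None
        if header != COHORT_CSV_HEADER:
            raise CsvFormatError(
                f"{path}: bad header {header!r}; expected {COHORT_CSV_HEADER!r}"
            )
        records = []
        for i, row in enumerate(reader, start=1):
            if len(row) != len(COHORT_CSV_HEADER):
                raise CsvFormatError(
                    f"row {i}: has {len(row)} fields, expected {len(COHORT_CSV_HEADER)}"
                )
            d = dict(zip(COHORT_CSV_HEADER, row))
            try:
                action = (
                    Action.from_code(d["expert_action"]) if d["expert_action"] else None
                )
            except ValueError as exc:
                raise CsvFormatError(f"row {i}: {exc}") from None
            flags = [d[c] for c in _OUTCOME_COLS]
            if all(f == "" for f in flags):
                outcomes = None
            elif any(f == "" for f in flags):
                raise CsvFormatError(
                    f"row {i}: outcome columns must be all set or all empty"
                )
            else:
                outcomes = OutcomeRecord(
                    *(_parse_binary(f, i, c) for f, c in zip(flags, _OUTCOME_COLS))
                )
            rec = PatientRecord(
                patient_id=d["patient_id"] or None,
                age=_parse_float(d["age"], i, "age"),
                af_duration_months=_parse_float(
                    d["af_duration_months"], i, "af_duration_months"
                ),
                heart_failure=_parse_binary(d["heart_failure"], i, "heart_failure"),
                la_enlargement=_parse_binary(d["la_enlargement"], i, "la_enlargement"),
                resting_hr=_parse_float(d["resting_hr"], i, "resting_hr"),
                hypertension=_parse_binary(d["hypertension"], i, "hypertension"),
                bmi=_parse_float(d["bmi"], i, "bmi"),
                symptomatic=_parse_binary(d["symptomatic"], i, "symptomatic"),
                expert_action=action,
                outcomes=outcomes,
            )
            try:
                validate_record(rec)
            except ValueError as exc:
                raise CsvFormatError(f"row {i}: {exc}") from exc
            records.append(rec)
    return records


def _fmt(v) -> str:
    # repr round-trips floats losslessly; integers stay integral
    if isinstance(v, float) and v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(v) if isinstance(v, float) else str(v)


def write_cohort_csv(records: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_CSV_HEADER)
        for rec in records:
            out = rec.outcomes
            writer.writerow(
                [
                    rec.patient_id or "",
                    _fmt(float(rec.age)),
                    _fmt(float(rec.af_duration_months)),
                    rec.heart_failure,
                    rec.la_enlargement,
                    _fmt(float(rec.resting_hr)),
                    rec.hypertension,
                    _fmt(float(rec.bmi)),
                    rec.symptomatic,
                    rec.expert_action.name if rec.expert_action is not None else "",
                    out.stroke if out else "",
                    out.hospitalization if out else "",
                    out.symptomatic_recurrence if out else "",
                ]
            )


def experiences_from_cohort(
    records: Sequence[PatientRecord],
    scaler: FeatureScaler,
    spec: RewardSpec = RewardSpec(),
) -> List[Experience]:
    """Build RL experiences from cohort rows carrying an action and outcomes.

    The ``expert_action`` column is read as the action actually taken."""
    out = []
    for rec in records:
        if rec.expert_action is None:
            raise CsvFormatError(
                f"record {rec.patient_id!r}: no action recorded (expert_action empty)"
            )
        if rec.outcomes is None:
            raise CsvFormatError(
                f"record {rec.patient_id!r}: no follow-up outcomes recorded"
            )
        out.append(
            Experience(
                x=encode_features(rec, scaler),
                action_taken=rec.expert_action,
                reward=compute_reward(rec.outcomes, spec),
            )
        )
    return out


def write_experience_csv(
    records: Sequence[PatientRecord],
    path: Union[str, Path],
    spec: RewardSpec = RewardSpec(),
) -> None:
    """Write the experience log (action, outcome flags, derived reward)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EXPERIENCE_CSV_HEADER)
        for rec in records:
            if rec.expert_action is None or rec.outcomes is None:
                raise CsvFormatError(
                    f"record {rec.patient_id!r}: needs action and outcomes"
                )
            o = rec.outcomes
            writer.writerow(
                [
                    rec.patient_id or "",
                    rec.expert_action.name,
                    o.stroke,
                    o.hospitalization,
                    o.symptomatic_recurrence,
                    _fmt(float(compute_reward(o, spec))),
                ]
            )


# ---------------------------------------------------------------------------
# model JSON


def _model_payload(model) -> dict:
    base = {
        "format_version": FORMAT_VERSION,
        "weights": model.weights.tolist(),
        "scaler": model.scaler.to_dict(),
        "action_order": [a.name for a in Action],
        "feature_order": list(FEATURE_NAMES),
    }
    if isinstance(model, SLPolicyModel):
        base["kind"] = "sl"
        base["loss_mode"] = model.loss_mode
    elif isinstance(model, QPolicyModel):
        base["kind"] = "q"
        base["updates_applied"] = model.updates_applied
        base["experiences_seen"] = model.experiences_seen
        base["pending_buffer"] = [
            {"x": e.x.tolist(), "action_taken": e.action_taken.name, "reward": e.reward}
            for e in model.pending
        ]
    else:
        raise ModelFormatError(f"cannot serialize model of type {type(model).__name__}")
    return base


def save_model(model, path: Union[str, Path]) -> None:
    """Serialize an SL or Q model to JSON (lossless float round-trip)."""
    Path(path).write_text(
        json.dumps(_model_payload(model), indent=2, sort_keys=True), encoding="utf-8"
    )


def load_model(path: Union[str, Path]):
    """Load a model JSON; returns :class:`SLPolicyModel` or
    :class:`QPolicyModel` per its ``kind`` field."""
    try:
        d = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: corrupt model file: {exc}") from exc
    if not isinstance(d, dict):
        raise ModelFormatError(f"{path}: corrupt model file: not a JSON object")
    version = d.get("format_version")
    if version != FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported format_version {version!r} (expected {FORMAT_VERSION})"
        )
    try:
        weights = np.array(d["weights"], dtype=float)
        scaler = FeatureScaler.from_dict(d["scaler"])
        kind = d["kind"]
        if kind == "sl":
            return SLPolicyModel(weights, scaler, d["loss_mode"])
        if kind == "q":
            pending = tuple(
                Experience(
                    x=np.array(e["x"], dtype=float),
                    action_taken=Action.from_code(e["action_taken"]),
                    reward=float(e["reward"]),
                )
                for e in d.get("pending_buffer", [])
            )
            return QPolicyModel(
                weights,
                scaler,
                updates_applied=int(d["updates_applied"]),
                experiences_seen=int(d.get("experiences_seen", 0)),
                pending=pending,
            )
        raise ModelFormatError(f"{path}: unknown model kind {kind!r}")
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ModelFormatError):
            raise
        raise ModelFormatError(f"{path}: corrupt model file: {exc}") from exc


# ---------------------------------------------------------------------------
# worlds


def load_world(name_or_path: str):
    """Resolve a world by shipped fixture name or YAML/JSON config path."""
    if name_or_path in WORLD_NAMES:
        return get_world(name_or_path)
    path = Path(name_or_path)
    if not path.exists():
        raise WorldConfigError(
            f"{name_or_path!r} is neither a known world name {WORLD_NAMES} "
            f"nor an existing config file"
        )
    d = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(d, dict) or "kind" not in d:
        raise WorldConfigError(f"{path}: world config must be a mapping with a 'kind'")
    if d["kind"] == "continuous":
        return SyntheticWorld.from_dict(d)
    if d["kind"] == "discrete":
        return DiscreteWorld.from_dict(d)
    raise WorldConfigError(f"{path}: unknown world kind {d['kind']!r}")


def save_world(world, path: Union[str, Path]) -> None:
    Path(path).write_text(
        yaml.safe_dump(world.to_dict(), sort_keys=False), encoding="utf-8"
    )
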