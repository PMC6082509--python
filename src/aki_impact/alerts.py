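"""APS clinical-prediction-rule scoring and RED/AMBER/GREEN alert states.

The Acute Kidney Injury Prediction Score (APS) is an additive integer score
over admission-time predictors (age, comorbidity history, physiology); a
score at or above the cutoff (default 5) flags the patient "at risk of AKI"
(AMBER).  Established AKI — community-acquired at admission, or
hospital-acquired later in the stay — is flagged RED and outranks the score.
States only ever escalate (GREEN -> AMBER -> RED) during an admission.

The weight table is declarative configuration, not code.  The default table
shipped with the package (``data/aps_weights_synthetic.yaml``) is a synthetic
representative weighting over the documented predictor set; site deployments
should substitute their validated weights.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional

import yaml

from .exceptions import ConfigurationError, DataError
from .records import AdmissionRecord, AkiClassification

_OPS = {
    "ge": lambda v, t: v >= t,
    "gt": lambda v, t: v > t,
    "le": lambda v, t: v <= t,
    "lt": lambda v, t: v < t,
    "eq": lambda v, t: v == t,
    "is_true": lambda v, t: bool(v),
}

State = Literal["GREEN", "AMBER", "RED"]
Reason = Literal["none", "aps_at_risk", "ca_aki", "ha_aki"]


@dataclass(frozen=True)
class ApsWeightEntry:
    """One scored predictor: ``points`` awarded when ``field op threshold``."""

    name: str
    field: str
    op: str
    points: int
    threshold: Optional[float] = None

    def __post_init__(self):
        if self.op not in _OPS:
            raise ConfigurationError(f"unknown comparator {self.op!r}")
        if self.points < 0:
            raise ConfigurationError("points must be >= 0")
        if self.op != "is_true" and self.threshold is None:
            raise ConfigurationError(f"{self.name}: comparator {self.op!r} needs a threshold")


@dataclass(frozen=True)
class ApsWeights:
    entries: tuple[ApsWeightEntry, ...]
    cutoff: int = 5

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ApsWeights":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: Mapping) -> "ApsWeights":
        entries = tuple(
            ApsWeightEntry(
                name=e["name"],
                field=e["field"],
                op=e["op"],
                points=int(e["points"]),
                threshold=e.get("threshold"),
            )
            for e in raw.get("entries", [])
        )
        return cls(entries=entries, cutoff=int(raw.get("cutoff", 5)))


def default_weights() -> ApsWeights:
    """The packaged synthetic weight table (cutoff 5)."""
    ref = resources.files("aki_impact").joinpath("data/aps_weights_synthetic.yaml")
    with resources.as_file(ref) as path:
        return ApsWeights.from_yaml(path)


def _field_value(record, name: str):
    if isinstance(record, AdmissionRecord):
        if name in record.comorbidities:
            return record.comorbidities[name]
        if not hasattr(record, name):
            raise ConfigurationError(f"weight table references unknown field {name!r}")
        return getattr(record, name)
    if isinstance(record, Mapping):
        if name not in record:
            raise ConfigurationError(f"weight table references unknown field {name!r}")
        return record[name]
    raise ConfigurationError(f"cannot score object of type {type(record).__name__}")


def compute_aps(record, weights: ApsWeights) -> int:
    """Additive score: sum of points over satisfied predictor conditions.

    ``record`` may be an :class:`AdmissionRecord` or any mapping with the
    predictor fields.  Deterministic and invariant to entry order.
    """
    score = 0
    for e in weights.entries:
        v = _field_value(record, e.field)
        if _OPS[e.op](v, e.threshold):
            score += e.points
    return score


@dataclass(frozen=True)
class AlertState:
    state: State
    reason: Reason

    def __post_init__(self):
        ok = {
            "RED": {"ca_aki", "ha_aki"},
            "AMBER": {"aps_at_risk"},
            "GREEN": {"none"},
        }
        if self.reason not in ok[self.state]:
            raise DataError(f"inconsistent alert {self.state}/{self.reason}")


def assign_state(aps: int, aki: AkiClassification, cutoff: int = 5) -> AlertState:
    """Final alert state for an admission.

    RED for any AKI (reason records community vs hospital-acquired); else
    AMBER when the score meets the cutoff; else GREEN.  At admission the
    state reflects CA status only — HA onset escalates to RED later, never
    the reverse — so the final state shown here is also the maximum reached.
    """
    if aps < 0:
        raise DataError("APS score cannot be negative")
    if aki.category == "CA":
        return AlertState("RED", "ca_aki")
    if aki.category == "HA":
        return AlertState("RED", "ha_aki")
    if aps >= cutoff:
        return AlertState("AMBER", "aps_at_risk")
    return AlertState("GREEN", "none")


def state_at_admission(aps: int, aki: AkiClassification, cutoff: int = 5) -> AlertState:
    """Alert state shown at admission: CA-AKI flags RED; HA-AKI has not
    happened yet, so such admissions show their score-based state."""
    if aki.category == "CA":
        return AlertState("RED", "ca_aki")
    if aps >= cutoff:
        return AlertState("AMBER", "aps_at_risk")
    return AlertState("GREEN", "none")


@dataclass(frozen=True)
class ComplianceReport:
    """Care-bundle completion, as percentages; None when no alerts exist."""

    red_pct: Optional[float]
    flagged_pct: Optional[float]  # AMBER or RED
    n_red: int
    n_flagged: int


def bundle_compliance(
    states: Mapping[str, AlertState], submitted: Iterable[str]
) -> ComplianceReport:
    """Proportion of alerted admissions with a complete bundle submitted.

    ``states`` maps admission_id -> final AlertState; ``submitted`` holds the
    admission ids with a completed electronic bundle and must be a subset of
    the alerted (non-GREEN) admissions.
    """
    submitted = set(submitted)
    alerted = {k for k, s in states.items() if s.state != "GREEN"}
    stray = submitted - alerted
    if stray:
        raise DataError(f"bundle submitted for non-alerted admissions: {sorted(stray)[:5]}")
    red = {k for k, s in states.items() if s.state == "RED"}
    red_pct = 100.0 * len(submitted & red) / len(red) if red else None
    flagged_pct = 100.0 * len(submitted) / len(alerted) if alerted else None
    return ComplianceReport(
        red_pct=red_pct,
        flagged_pct=flagged_pct,
        n_red=len(red),
        n_flagged=len(alerted),
    )
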