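"""Domain records flowing through the screening engine.

Timestamps are timezone-aware datetimes; comparisons happen in UTC.
The Alert record stands in for the pop-up shown to the prescriber; the
PriorResultReport is the structured replacement for an attached document
with the previous result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from typing import Literal, Optional

AlertKind = Literal["BLOCK", "WARN_WITH_MOTIVATION"]
AlertReason = Literal["TOO_SOON", "INCOMPATIBLE_PAIR", "DUPLICATE_IN_ORDER"]
ResolutionAction = Literal["CANCELLED", "OVERRIDDEN"]
MotivationCode = Literal[
    "SPECIALIST_REQUEST", "CLINICAL_EVIDENCE", "LAB_DATA_CONFIRMATION", "OTHER"
]

MOTIVATION_CODES = (
    "SPECIALIST_REQUEST",
    "CLINICAL_EVIDENCE",
    "LAB_DATA_CONFIRMATION",
    "OTHER",
)


def ensure_utc(ts: datetime) -> datetime:
    if ts.tzinfo is None:
        raise ValueError(f"timestamp {ts!r} must carry an explicit offset")
    return ts.astimezone(timezone.utc)


def age_completed_years(birth_date: date, at: datetime) -> int:
    """Completed years of age at a timestamp (floor convention)."""
    d = ensure_utc(at).date()
    return d.year - birth_date.year - (
        (d.month, d.day) < (birth_date.month, birth_date.day)
    )


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: Literal["F", "M"]
    birth_date: date


@dataclass(frozen=True)
class TestResult:
    """One executed (or pending) laboratory result in a patient's history."""

    patient_id: str
    analyte: str
    collected_at: datetime
    value: Optional[float] = None
    units: str = ""
    executed: bool = True

    def __post_init__(self):
        if self.executed and self.collected_at is None:
            raise ValueError("executed results must have collected_at set")
        if self.value is not None and not math.isfinite(self.value):
            raise ValueError(f"result value must be finite, got {self.value!r}")


@dataclass(frozen=True)
class TestRequest:
    """One requested examination inside an order.

    ``analyte`` holds the code as the requesting system spells it; the
    engine resolves it against the rule set's canonical ids and code
    maps.
    """

    analyte: str
    priority: Literal["ROUTINE", "URGENT"] = "ROUTINE"
    sample_type: str = "ANY"


@dataclass
class Order:
    order_id: str
    patient_id: str
    ward_group: str
    requesting_system: str
    ordered_at: datetime
    requests: list[TestRequest]

    def __post_init__(self):
        if not self.requests:
            raise ValueError(f"order {self.order_id}: requests must be non-empty")


@dataclass(frozen=True)
class PriorResultReport:
    """Structured report of the previous result attached to an alert."""

    analyte: str
    value: Optional[float]
    units: str
    collected_at: datetime
    range_lower: Optional[float]
    range_upper: Optional[float]
    in_range: Optional[bool]


@dataclass
class Alert:
    alert_id: str
    rule_id: Optional[str]
    order_id: str
    analyte: str
    kind: AlertKind
    reason: AlertReason
    comment: str
    prior_result_ref: Optional[TestResult] = None
    elapsed_hours: Optional[float] = None
    prior_in_normal_range: Optional[bool] = None
    prior_report: Optional[PriorResultReport] = None

    def __post_init__(self):
        if self.reason == "TOO_SOON":
            if self.prior_result_ref is None or self.elapsed_hours is None:
                raise ValueError(
                    "TOO_SOON alerts must carry prior_result_ref and elapsed_hours"
                )
            if self.elapsed_hours < 0:
                raise ValueError("elapsed_hours must be >= 0")


@dataclass(frozen=True)
class OverrideMotivation:
    code: MotivationCode
    free_text: Optional[str] = None

    def __post_init__(self):
        if self.code == "OTHER" and not (self.free_text or "").strip():
            raise ValueError("motivation code OTHER requires non-empty free_text")


@dataclass
class Resolution:
    alert_id: str
    action: ResolutionAction
    motivation: Optional[OverrideMotivation] = None


@dataclass
class AuditEvent:
    """Record of one screening call, whether or not alerts fired."""

    timestamp: datetime
    requesting_system: str
    order_id: str
    n_requests: int
    alerts: list[Alert] = field(default_factory=list)
    resolutions: list[Resolution] = field(default_factory=list)
    unmapped_codes: list[str] = field(default_factory=list)
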