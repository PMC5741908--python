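"""Delimited-file and JSON-lines IO for the screening pipeline.

Tables travel as UTF-8 CSV with ISO-8601 timestamps (explicit offset);
the audit trail is append-only JSON lines, one screening event per
line, so runs can be replayed and diffed.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import date, datetime
from typing import Iterable

import pandas as pd

from .records import (
    Alert,
    AuditEvent,
    Order,
    OverrideMotivation,
    Patient,
    PriorResultReport,
    Resolution,
    TestRequest,
    TestResult,
)


def read_table(path) -> pd.DataFrame:
    """CSV reader safe for analyte codes: only empty cells count as
    missing (the default parser would turn the sodium code "NA" into NaN)."""
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


def _parse_ts(value) -> datetime:
    if isinstance(value, datetime):
        ts = value
    else:
        ts = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    if ts.tzinfo is None:
        raise ValueError(f"timestamp {value!r} lacks an explicit offset")
    return ts


def patients_from_frame(df: pd.DataFrame) -> dict[str, Patient]:
    out = {}
    for row in df.itertuples(index=False):
        out[row.patient_id] = Patient(
            patient_id=row.patient_id,
            sex=row.sex,
            birth_date=date.fromisoformat(str(row.birth_date)),
        )
    return out


def results_from_frame(df: pd.DataFrame) -> list[TestResult]:
    out = []
    for row in df.itertuples(index=False):
        value = getattr(row, "value", None)
        if value is not None and pd.isna(value):
            value = None
        out.append(
            TestResult(
                patient_id=row.patient_id,
                analyte=row.analyte,
                collected_at=_parse_ts(row.collected_at),
                value=None if value is None else float(value),
                units=str(getattr(row, "units", "") or ""),
                executed=bool(getattr(row, "executed", True)),
            )
        )
    return out


def orders_from_frame(df: pd.DataFrame) -> list[Order]:
    """Group a request-level table (one row per request) into Orders."""
    by_id: dict[str, Order] = {}
    for r in df.itertuples(index=False):
        oid = str(r.order_id)
        request = TestRequest(
            analyte=str(r.analyte),
            priority=str(getattr(r, "priority", "ROUTINE")),
            sample_type=str(getattr(r, "sample_type", "ANY")),
        )
        order = by_id.get(oid)
        if order is None:
            by_id[oid] = Order(
                order_id=oid,
                patient_id=str(r.patient_id),
                ward_group=str(r.ward_group),
                requesting_system=str(r.requesting_system),
                ordered_at=_parse_ts(r.ordered_at),
                requests=[request],
            )
        else:
            order.requests.append(request)
    orders = sorted(by_id.values(), key=lambda o: (o.ordered_at, o.order_id))
    return orders


def _encode(obj):
    if isinstance(obj, datetime):
        return obj.isoformat()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _encode(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


def write_audit_log(events: Iterable[AuditEvent], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in events:
            fh.write(json.dumps(_encode(e), sort_keys=True) + "\n")


def _decode_alert(d: dict) -> Alert:
    prior = d.get("prior_result_ref")
    report = d.get("prior_report")
    return Alert(
        alert_id=d["alert_id"],
        rule_id=d.get("rule_id"),
        order_id=d["order_id"],
        analyte=d["analyte"],
        kind=d["kind"],
        reason=d["reason"],
        comment=d["comment"],
        prior_result_ref=None if prior is None else TestResult(
            patient_id=prior["patient_id"],
            analyte=prior["analyte"],
            collected_at=_parse_ts(prior["collected_at"]),
            value=prior.get("value"),
            units=prior.get("units", ""),
            executed=prior.get("executed", True),
        ),
        elapsed_hours=d.get("elapsed_hours"),
        prior_in_normal_range=d.get("prior_in_normal_range"),
        prior_report=None if report is None else PriorResultReport(
            analyte=report["analyte"],
            value=report.get("value"),
            units=report.get("units", ""),
            collected_at=_parse_ts(report["collected_at"]),
            range_lower=report.get("range_lower"),
            range_upper=report.get("range_upper"),
            in_range=report.get("in_range"),
        ),
    )


def read_audit_log(path) -> list[AuditEvent]:
    events = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            events.append(
                AuditEvent(
                    timestamp=_parse_ts(d["timestamp"]),
                    requesting_system=d["requesting_system"],
                    order_id=d["order_id"],
                    n_requests=d["n_requests"],
                    alerts=[_decode_alert(a) for a in d.get("alerts", [])],
                    resolutions=[
                        Resolution(
                            alert_id=r["alert_id"],
                            action=r["action"],
                            motivation=None if r.get("motivation") is None
                            else OverrideMotivation(
                                code=r["motivation"]["code"],
                                free_text=r["motivation"].get("free_text"),
                            ),
                        )
                        for r in d.get("resolutions", [])
                    ],
                    unmapped_codes=list(d.get("unmapped_codes", [])),
                )
            )
    return events


def read_resolutions(path) -> list[dict]:
    """Resolutions CSV: order_id, alert_id, action, motivation_code, free_text."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rows = []
    for r in df.itertuples(index=False):
        code = getattr(r, "motivation_code", "") or ""
        rows.append(
            {
                "order_id": r.order_id,
                "alert_id": r.alert_id,
                "action": r.action,
                "motivation": None if not code else OverrideMotivation(
                    code=code, free_text=getattr(r, "free_text", "") or None
                ),
            }
        )
    return rows


def write_frame(df: pd.DataFrame, path) -> None:
    """Deterministic CSV output (fixed float formatting, no index)."""
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = df[col].map(lambda t: t.isoformat())
        elif df[col].map(lambda v: isinstance(v, datetime)).any():
            df[col] = df[col].map(
                lambda t: t.isoformat() if isinstance(t, datetime) else t
            )
    df.to_csv(path, index=False, float_format="%.6g")
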