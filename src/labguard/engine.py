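"""Order screening: retest-interval checks, incompatibilities, audit.

The screening contract, in order of evaluation for each request:

1. resolve the requested code to a canonical analyte (unresolvable
   codes exempt the request and are audit-logged);
2. select the applicable rule after scope filters (ward group, order
   priority, sample type); when several rules match, the most severe
   outcome wins (BLOCK over WARN), ties broken by lexicographic
   rule_id, so the result never depends on rule-file ordering;
3. time criterion: the latest *executed* prior result strictly before
   the order anchors the elapsed time; an alert fires iff
   elapsed < min_interval (an elapsed time exactly equal to the
   interval is appropriate);
4. quantitative criterion (rules flagged TIME_AND_QUANT): annotates the
   alert with whether the prior value sat inside the patient's
   sex/age-matched normality range and, when it did, attaches a
   structured prior-result report.  It never suppresses the alert.

Order-level checks add one BLOCK alert per incompatible analyte pair
and per analyte requested more than once in the same order.
"""

from __future__ import annotations

from collections import Counter
from datetime import datetime
from typing import Iterable, Optional, Sequence

from .records import (
    Alert,
    AuditEvent,
    Order,
    OverrideMotivation,
    Patient,
    PriorResultReport,
    Resolution,
    TestResult,
    age_completed_years,
    ensure_utc,
)
from .rules import AppropriatenessRule, RuleSet, lookup_normality, map_code


class ResolutionError(ValueError):
    """Base class for invalid alert resolutions."""


class UnknownAlertError(ResolutionError):
    pass


class AlreadyResolvedError(ResolutionError):
    pass


class HardStopOverrideError(ResolutionError):
    """A BLOCK alert may only be resolved by cancelling the test."""


class MissingMotivationError(ResolutionError):
    """Overriding a soft stop requires a coded motivation."""


def latest_prior_result(
    history: Iterable[TestResult],
    patient_id: str,
    analyte: str,
    before: datetime,
) -> Optional[TestResult]:
    """The executed result with maximal collected_at strictly before `before`."""
    cutoff = ensure_utc(before)
    best: Optional[TestResult] = None
    for res in history:
        if not res.executed or res.patient_id != patient_id or res.analyte != analyte:
            continue
        when = ensure_utc(res.collected_at)
        if when < cutoff and (best is None or when > ensure_utc(best.collected_at)):
            best = res
    return best


def evaluate_time_criterion(
    rule: AppropriatenessRule, prior: TestResult, order_time: datetime
) -> tuple[bool, float]:
    """Check the prior result against the rule's minimum retest interval.

    Returns (triggered, elapsed_hours); triggered iff
    elapsed < min_interval (strict — elapsed exactly equal to the
    interval does not trigger).
    """
    if rule.min_interval_hours is None:
        raise ValueError(f"rule {rule.rule_id} has no retest interval")
    elapsed = (
        ensure_utc(order_time) - ensure_utc(prior.collected_at)
    ).total_seconds() / 3600.0
    if elapsed < 0:
        raise ValueError(
            f"prior result at {prior.collected_at} is after order time {order_time}"
        )
    return elapsed < rule.min_interval_hours, elapsed


def evaluate_quant_criterion(
    ruleset: RuleSet,
    rule: AppropriatenessRule,
    prior: TestResult,
    patient: Patient,
    order_time: datetime,
) -> Optional[bool]:
    """Was the prior value inside the patient's normality range?

    Returns True/False, or None (inapplicable) when the prior has no
    numeric value or no range matches the patient's sex and age.
    """
    if rule.prior_criteria != "TIME_AND_QUANT":
        raise ValueError(
            f"rule {rule.rule_id} does not declare a quantitative criterion"
        )
    if prior.value is None:
        return None
    age = age_completed_years(patient.birth_date, order_time)
    nr = lookup_normality(ruleset, rule.analyte, patient.sex, age)
    if nr is None:
        return None
    return nr.contains(prior.value)


def _scope_matches(rule: AppropriatenessRule, order: Order, priority: str,
                   sample_type: str) -> bool:
    if rule.ward_groups and order.ward_group not in rule.ward_groups:
        return False
    if rule.priority_scope != "ANY" and rule.priority_scope != priority:
        return False
    if rule.sample_type != "ANY" and sample_type != "ANY" \
            and rule.sample_type != sample_type:
        return False
    return True


def _select_rule(candidates: list[AppropriatenessRule]) -> AppropriatenessRule:
    # most severe outcome first (BLOCK > WARN), then lexicographic rule_id
    return sorted(
        candidates,
        key=lambda r: (0 if r.outcome == "BLOCK" else 1, r.rule_id),
    )[0]


def _resolve_analyte(ruleset: RuleSet, system: str, code: str) -> Optional[str]:
    if code in ruleset.analyte_ids():
        return code
    return map_code(ruleset, system, code)


def check_incompatibilities(order: Order, ruleset: RuleSet) -> list[Alert]:
    """Within-order checks: incompatible pairs and duplicated analytes.

    Emits one BLOCK alert per unordered incompatible pair present and
    one per analyte appearing more than once.  Alert ids are assigned
    by check_order; here they are placeholders.
    """
    alerts: list[Alert] = []
    resolved: list[tuple[int, Optional[str]]] = [
        (pos, _resolve_analyte(ruleset, order.requesting_system, req.analyte))
        for pos, req in enumerate(order.requests)
    ]
    present = {a for _, a in resolved if a is not None}

    pair_rules: dict[frozenset, AppropriatenessRule] = {}
    for rule in sorted(ruleset.rules, key=lambda r: r.rule_id):
        if rule.ward_groups and order.ward_group not in rule.ward_groups:
            continue
        if rule.analyte not in present:
            continue
        for other in sorted(rule.incompatible_with):
            if other in present:
                pair_rules.setdefault(frozenset((rule.analyte, other)), rule)

    first_pos = {}
    for pos, a in resolved:
        if a is not None and a not in first_pos:
            first_pos[a] = pos

    for pair, rule in sorted(
        pair_rules.items(), key=lambda kv: min(first_pos[a] for a in kv[0])
    ):
        a, b = sorted(pair)
        alerts.append(
            Alert(
                alert_id="",
                rule_id=rule.rule_id,
                order_id=order.order_id,
                analyte=f"{a}+{b}",
                kind="BLOCK",
                reason="INCOMPATIBLE_PAIR",
                comment=rule.reporting_comment,
            )
        )

    counts = Counter(a for _, a in resolved if a is not None)
    for analyte in sorted((a for a, n in counts.items() if n > 1),
                          key=lambda a: first_pos[a]):
        rules = [r for r in sorted(ruleset.rules, key=lambda r: r.rule_id)
                 if r.analyte == analyte and r.has_retest_check]
        alerts.append(
            Alert(
                alert_id="",
                rule_id=rules[0].rule_id if rules else None,
                order_id=order.order_id,
                analyte=analyte,
                kind="BLOCK",
                reason="DUPLICATE_IN_ORDER",
                comment=f"{analyte} requested more than once in the same order",
            )
        )
    return alerts


def check_order(
    order: Order,
    patient: Patient,
    history: Sequence[TestResult],
    ruleset: RuleSet,
) -> tuple[list[Alert], AuditEvent]:
    """Screen one order; returns (alerts, audit event).

    Emits at most one alert per request plus the within-order alerts;
    output is invariant to permutations of both the rule list and the
    request list (canonical alert ordering: analyte, then rule_id, then
    reason).
    An AuditEvent is produced for every call, alerts or not.
    """
    if order.patient_id != patient.patient_id:
        raise ValueError(
            f"order {order.order_id} is for patient {order.patient_id}, "
            f"not {patient.patient_id}"
        )
    order_time = ensure_utc(order.ordered_at)
    alerts: list[Alert] = []
    unmapped: list[str] = []

    for pos, req in enumerate(order.requests):
        analyte = _resolve_analyte(ruleset, order.requesting_system, req.analyte)
        if analyte is None:
            unmapped.append(req.analyte)
            continue
        candidates = [
            r for r in ruleset.rules_for(analyte)
            if r.has_retest_check
            and _scope_matches(r, order, req.priority, req.sample_type)
        ]
        if not candidates:
            continue
        rule = _select_rule(candidates)
        prior = latest_prior_result(history, patient.patient_id, analyte, order_time)
        if prior is None:
            continue
        triggered, elapsed = evaluate_time_criterion(rule, prior, order_time)
        if not triggered:
            continue
        in_range: Optional[bool] = None
        report: Optional[PriorResultReport] = None
        if rule.prior_criteria == "TIME_AND_QUANT":
            in_range = evaluate_quant_criterion(
                ruleset, rule, prior, patient, order_time
            )
            if in_range:
                age = age_completed_years(patient.birth_date, order_time)
                nr = lookup_normality(ruleset, analyte, patient.sex, age)
                report = PriorResultReport(
                    analyte=analyte,
                    value=prior.value,
                    units=prior.units,
                    collected_at=prior.collected_at,
                    range_lower=nr.lower if nr else None,
                    range_upper=nr.upper if nr else None,
                    in_range=True,
                )
        alerts.append(
            Alert(
                alert_id=f"__pos{pos:04d}",
                rule_id=rule.rule_id,
                order_id=order.order_id,
                analyte=analyte,
                kind=rule.outcome,
                reason="TOO_SOON",
                comment=rule.reporting_comment,
                prior_result_ref=prior,
                elapsed_hours=elapsed,
                prior_in_normal_range=in_range,
                prior_report=report,
            )
        )

    alerts.extend(check_incompatibilities(order, ruleset))
    # canonical ordering independent of request and rule list permutations
    alerts.sort(key=lambda a: (a.analyte, a.rule_id or "", a.reason))
    for i, alert in enumerate(alerts, start=1):
        alert.alert_id = f"{order.order_id}:A{i}"

    audit = AuditEvent(
        timestamp=order_time,
        requesting_system=order.requesting_system,
        order_id=order.order_id,
        n_requests=len(order.requests),
        alerts=alerts,
        unmapped_codes=sorted(set(unmapped)),
    )
    return alerts, audit


def screen_stream(
    orders: Sequence[Order],
    patients: dict[str, Patient],
    history: Sequence[TestResult],
    ruleset: RuleSet,
) -> list[AuditEvent]:
    """Screen a chronological order stream; one audit event per order.

    Histories are grouped per patient once up front; latest_prior_result
    only ever looks strictly before each order's timestamp, so passing a
    patient's full (possibly future-reaching) history is safe.
    """
    by_patient: dict[str, list[TestResult]] = {}
    for res in history:
        by_patient.setdefault(res.patient_id, []).append(res)
    events = []
    for order in sorted(orders, key=lambda o: (ensure_utc(o.ordered_at), o.order_id)):
        patient = patients[order.patient_id]
        _, audit = check_order(
            order, patient, by_patient.get(order.patient_id, ()), ruleset
        )
        events.append(audit)
    return events


def resolve_alert(
    audit: AuditEvent,
    alert_id: str,
    action: str,
    motivation: Optional[OverrideMotivation] = None,
) -> AuditEvent:
    """Record the prescriber's response to an alert.

    Hard stops (BLOCK) may only be CANCELLED; overriding a soft stop
    requires a motivation.  Each failure mode raises a distinct error.
    """
    alert = next((a for a in audit.alerts if a.alert_id == alert_id), None)
    if alert is None:
        raise UnknownAlertError(f"no alert {alert_id!r} in event {audit.order_id}")
    if any(r.alert_id == alert_id for r in audit.resolutions):
        raise AlreadyResolvedError(f"alert {alert_id!r} already resolved")
    if action == "OVERRIDDEN":
        if alert.kind == "BLOCK":
            raise HardStopOverrideError(
                f"alert {alert_id!r} is a hard stop; the only allowed action "
                "is to cancel the test"
            )
        if motivation is None:
            raise MissingMotivationError(
                f"overriding soft-stop alert {alert_id!r} requires a motivation"
            )
    elif action != "CANCELLED":
        raise ResolutionError(f"unknown action {action!r}")
    audit.resolutions.append(
        Resolution(alert_id=alert_id, action=action, motivation=motivation)
    )
    return audit


def audit_summary(events: Sequence[AuditEvent]) -> dict:
    """Aggregate counts over an audit stream.

    Rates that have an empty denominator (no orders, no resolved soft
    stops) are reported as None rather than a number.
    """
    orders = len(events)
    requests = sum(e.n_requests for e in events)
    by_kind: Counter = Counter()
    by_reason: Counter = Counter()
    by_analyte: Counter = Counter()
    motivations: Counter = Counter()
    soft_resolved = 0
    soft_overridden = 0
    triggered_orders = 0
    unmapped = 0
    for e in events:
        if e.alerts:
            triggered_orders += 1
        unmapped += len(e.unmapped_codes)
        alerts_by_id = {a.alert_id: a for a in e.alerts}
        for a in e.alerts:
            by_kind[a.kind] += 1
            by_reason[a.reason] += 1
            by_analyte[a.analyte] += 1
        for r in e.resolutions:
            alert = alerts_by_id.get(r.alert_id)
            if alert is not None and alert.kind == "WARN_WITH_MOTIVATION":
                soft_resolved += 1
                if r.action == "OVERRIDDEN":
                    soft_overridden += 1
            if r.motivation is not None:
                motivations[r.motivation.code] += 1
    return {
        "orders_screened": orders,
        "requests_screened": requests,
        "alerts_total": sum(by_kind.values()),
        "alerts_by_kind": dict(by_kind),
        "alerts_by_reason": dict(by_reason),
        "alerts_by_analyte": dict(by_analyte),
        "trigger_fraction": (triggered_orders / orders) if orders else None,
        "override_rate": (soft_overridden / soft_resolved) if soft_resolved else None,
        "motivation_codes": dict(motivations),
        "unmapped_codes": unmapped,
    }
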