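"""Built-in verification suite for the screening engine.

Clinical rule engines conventionally ship an operational-qualification
suite: a fixed set of scripted order scenarios with known expected
outcomes, runnable on demand to demonstrate that the deployed rule
logic behaves as documented.  This module encodes twenty such scenarios
over the default rule set (interval boundaries at exactly 24 h / 72 h /
3 months / 6 months, the hard stop on the ANA pair, soft stops with
each motivation code, and the scope filters) plus a ward-scoped
calcium rule added only for the scope scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Callable

from .datasets import default_ruleset
from .engine import HardStopOverrideError, MissingMotivationError, check_order, resolve_alert
from .records import Order, OverrideMotivation, Patient, TestRequest, TestResult
from .rules import AnalyteCode, AppropriatenessRule, RuleSet

_UTC = timezone.utc
T0 = datetime(2015, 10, 1, 12, 0, tzinfo=_UTC)
PATIENT = Patient(patient_id="PX", sex="F", birth_date=date(1955, 3, 2))


def scenario_ruleset() -> RuleSet:
    rs = default_ruleset()
    rs.analytes.append(AnalyteCode(canonical_id="CA", display_name="Calcium"))
    rs.rules.append(
        AppropriatenessRule(
            rule_id="R_CA_MED_24H",
            analyte="CA",
            min_interval="24h",
            priority_scope="ROUTINE",
            ward_groups={"MEDICINE"},
            outcome="WARN_WITH_MOTIVATION",
            reporting_comment="Calcium executed in the last 24h",
        )
    )
    return rs


def _order(analytes, ward="MEDICINE", priority="ROUTINE", when=T0):
    return Order(
        order_id="OX",
        patient_id="PX",
        ward_group=ward,
        requesting_system="SAP",
        ordered_at=when,
        requests=[TestRequest(analyte=a, priority=priority) for a in analytes],
    )


def _prior(analyte, hours_before, value=None):
    return TestResult(
        patient_id="PX",
        analyte=analyte,
        collected_at=T0 - timedelta(hours=hours_before),
        value=value,
        executed=True,
    )


@dataclass
class Scenario:
    name: str
    run: Callable[[RuleSet], bool]


def _expect_too_soon(analyte, hours_before, kind="WARN_WITH_MOTIVATION"):
    def run(rs):
        alerts, _ = check_order(_order([analyte]), PATIENT,
                                [_prior(analyte, hours_before)], rs)
        return (
            len(alerts) == 1
            and alerts[0].reason == "TOO_SOON"
            and alerts[0].kind == kind
        )
    return run


def _expect_clear(analyte, hours_before, **order_kw):
    def run(rs):
        alerts, _ = check_order(_order([analyte], **order_kw), PATIENT,
                                [_prior(analyte, hours_before)], rs)
        return alerts == []
    return run


def _soft_override(code, free_text=None):
    def run(rs):
        alerts, audit = check_order(_order(["NA"]), PATIENT,
                                    [_prior("NA", 10.0, value=140.0)], rs)
        if len(alerts) != 1 or alerts[0].kind != "WARN_WITH_MOTIVATION":
            return False
        resolve_alert(audit, alerts[0].alert_id, "OVERRIDDEN",
                      OverrideMotivation(code=code, free_text=free_text))
        r = audit.resolutions[-1]
        return r.action == "OVERRIDDEN" and r.motivation.code == code
    return run


SECOND_H = 1.0 / 3600.0
MONTH_H = 720.0


def build_scenarios() -> list[Scenario]:
    return [
        Scenario("aptt repeat 12h inside 24h interval warns",
                 _expect_too_soon("APTT", 12.0)),
        Scenario("aptt repeat at exactly 24h is appropriate",
                 _expect_clear("APTT", 24.0)),
        Scenario("aptt repeat one second under 24h warns",
                 _expect_too_soon("APTT", 24.0 - SECOND_H)),
        Scenario("vancomycin repeat at exactly 72h is appropriate",
                 _expect_clear("VANCO", 72.0)),
        Scenario("vancomycin repeat one second under 72h warns",
                 _expect_too_soon("VANCO", 72.0 - SECOND_H)),
        Scenario("ferritin repeat at exactly 3 months is appropriate",
                 _expect_clear("FERRI", 3 * MONTH_H)),
        Scenario("ferritin repeat one second under 3 months warns",
                 _expect_too_soon("FERRI", 3 * MONTH_H - SECOND_H)),
        Scenario("tsh repeat at exactly 6 months is appropriate",
                 _expect_clear("TSH", 6 * MONTH_H)),
        Scenario("tsh repeat after 7 months is appropriate",
                 _expect_clear("TSH", 7 * MONTH_H)),
        Scenario("tsh repeat after 1 month warns",
                 _expect_too_soon("TSH", MONTH_H)),
        Scenario(
            "ana with ana-reflex in one order hard-stops",
            lambda rs: (lambda alerts: len(alerts) == 1
                        and alerts[0].kind == "BLOCK"
                        and alerts[0].reason == "INCOMPATIBLE_PAIR")(
                check_order(_order(["ANA", "ANA_REFLEX"]), PATIENT, [], rs)[0]
            ),
        ),
        Scenario(
            "ana alone raises no alert",
            lambda rs: check_order(_order(["ANA"]), PATIENT, [], rs)[0] == [],
        ),
        Scenario(
            "sodium listed twice in one order hard-stops as duplicate",
            lambda rs: (lambda alerts: len(alerts) == 1
                        and alerts[0].kind == "BLOCK"
                        and alerts[0].reason == "DUPLICATE_IN_ORDER")(
                check_order(_order(["NA", "NA"]), PATIENT, [], rs)[0]
            ),
        ),
        Scenario(
            "sodium repeat at 10h soft-stops carrying the rule comment",
            lambda rs: (lambda alerts: len(alerts) == 1
                        and alerts[0].kind == "WARN_WITH_MOTIVATION"
                        and "24 h" in alerts[0].comment
                        and alerts[0].prior_in_normal_range is True)(
                check_order(_order(["NA"]), PATIENT,
                            [_prior("NA", 10.0, value=140.0)], rs)[0]
            ),
        ),
        Scenario("soft stop overridden with specialist request",
                 _soft_override("SPECIALIST_REQUEST")),
        Scenario("soft stop overridden with clinical evidence",
                 _soft_override("CLINICAL_EVIDENCE")),
        Scenario("soft stop overridden with lab data confirmation",
                 _soft_override("LAB_DATA_CONFIRMATION")),
        Scenario(
            "soft stop override with OTHER requires free text",
            lambda rs: _soft_override("OTHER", "repeat after transfusion")(rs)
            and _rejects_missing_motivation(rs),
        ),
        Scenario(
            "hard stop cannot be overridden, only cancelled",
            _hard_stop_behaviour,
        ),
        Scenario(
            "ward and priority scope filters exempt out-of-scope requests",
            _scope_filters,
        ),
    ]


def _rejects_missing_motivation(rs) -> bool:
    alerts, audit = check_order(_order(["NA"]), PATIENT,
                                [_prior("NA", 10.0, value=140.0)], rs)
    try:
        resolve_alert(audit, alerts[0].alert_id, "OVERRIDDEN", None)
    except MissingMotivationError:
        return True
    return False


def _hard_stop_behaviour(rs) -> bool:
    alerts, audit = check_order(_order(["ANA", "ANA_REFLEX"]), PATIENT, [], rs)
    try:
        resolve_alert(audit, alerts[0].alert_id, "OVERRIDDEN",
                      OverrideMotivation(code="CLINICAL_EVIDENCE"))
        return False
    except HardStopOverrideError:
        pass
    resolve_alert(audit, alerts[0].alert_id, "CANCELLED")
    return audit.resolutions[-1].action == "CANCELLED"


def _scope_filters(rs) -> bool:
    history = [_prior("CA", 10.0), _prior("NA", 10.0, value=140.0)]
    in_scope, _ = check_order(_order(["CA"], ward="MEDICINE"), PATIENT, history, rs)
    out_ward, _ = check_order(_order(["CA"], ward="CARDIOLOGY"), PATIENT, history, rs)
    urgent, _ = check_order(_order(["NA"], priority="URGENT"), PATIENT, history, rs)
    return len(in_scope) == 1 and out_ward == [] and urgent == []


def run_scenarios(ruleset: RuleSet | None = None) -> list[tuple[str, bool]]:
    """Run every scripted scenario; returns (name, passed) pairs."""
    rs = ruleset if ruleset is not None else scenario_ruleset()
    out = []
    for sc in build_scenarios():
        try:
            ok = bool(sc.run(rs))
        except Exception:
            ok = False
        out.append((sc.name, ok))
    return out
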