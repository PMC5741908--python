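"""Synthetic patients, result histories and order streams.

The generator emulates the study layout the evaluation modules expect:
two ward groups (intervention / control) observed over a pre and a post
period of three months each, elderly inpatients, and per-analyte order
streams in which a configurable fraction of repeat requests falls
inside the minimum retest interval.

The order process per (patient, analyte, period) is a sequence of
base/follow-up pairs: base orders are spaced well clear of the retest
interval, and each follow-up lands inside the interval with probability
``redundancy_rate`` (a planted violation) or outside it otherwise.
This makes the planted violation status of every repeat request exact,
so the alert fraction recovered by the screening engine is a clean
binomial draw at the configured rate.

A single global seed expands into independent substreams (patients /
timing / values / overrides), so drawing more from one stream never
perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .records import AuditEvent


class AnalyteProfile(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rate_per_patient_day: float = Field(gt=0)
    value_mean: float
    value_sd: float = Field(gt=0)
    units: str = ""


class WardSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    group: str  # INTERVENTION or CONTROL


DEFAULT_WARDS = [
    WardSpec(name="Medicine", group="INTERVENTION"),
    WardSpec(name="Cardiology", group="INTERVENTION"),
    WardSpec(name="Post-Acute and Long-term care", group="CONTROL"),
    WardSpec(name="Coronary Intensive Care", group="CONTROL"),
    WardSpec(name="Medicine (University)", group="CONTROL"),
]

# expected routine ordering intensity for an elderly inpatient cohort,
# concentrated on the analytes covered by the default rule set
DEFAULT_PROFILES = {
    "CBC": AnalyteProfile(rate_per_patient_day=0.060, value_mean=9.0,
                          value_sd=2.5, units="10^9/L"),
    "NA": AnalyteProfile(rate_per_patient_day=0.050, value_mean=140.0,
                         value_sd=4.0, units="mmol/L"),
    "PT": AnalyteProfile(rate_per_patient_day=0.030, value_mean=13.0,
                         value_sd=1.5, units="s"),
    "APTT": AnalyteProfile(rate_per_patient_day=0.030, value_mean=30.0,
                           value_sd=4.0, units="s"),
    "CRP": AnalyteProfile(rate_per_patient_day=0.030, value_mean=25.0,
                          value_sd=20.0, units="mg/L"),
    "TSH": AnalyteProfile(rate_per_patient_day=0.008, value_mean=2.0,
                          value_sd=1.0, units="mIU/L"),
    "FERRI": AnalyteProfile(rate_per_patient_day=0.005, value_mean=150.0,
                            value_sd=80.0, units="ug/L"),
    "VANCO": AnalyteProfile(rate_per_patient_day=0.003, value_mean=15.0,
                            value_sd=5.0, units="mg/L"),
}

_UTC = timezone.utc


class SimConfig(BaseModel):
    """Study-shaped simulation parameters.

    Defaults mirror the evaluated deployment: ~1233 inpatients, 51.25%
    female, mean age ~74, two 3-month observation windows a year apart,
    a 20% planted violation rate among repeat requests and a 50%
    soft-stop override rate.
    """

    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(default=1233, gt=0)
    female_fraction: float = Field(default=0.5125, ge=0, le=1)
    age_mean: float = 74.0
    age_sd: float = Field(default=9.0, gt=0)
    age_min: int = 18
    age_max: int = 100
    wards: list[WardSpec] = Field(default_factory=lambda: list(DEFAULT_WARDS))
    analyte_profiles: dict[str, AnalyteProfile] = Field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    redundancy_rate: float = Field(default=0.20, ge=0, le=1)
    override_rate: float = Field(default=0.5, ge=0, le=1)
    pre_start: datetime = datetime(2014, 9, 1, tzinfo=_UTC)
    pre_end: datetime = datetime(2014, 12, 1, tzinfo=_UTC)
    post_start: datetime = datetime(2015, 9, 1, tzinfo=_UTC)
    post_end: datetime = datetime(2015, 12, 1, tzinfo=_UTC)
    mortality_rate: float = Field(default=0.1046, ge=0, le=1)
    readmission_rate: float = Field(default=0.1046, ge=0, le=1)
    requesting_system: str = "SAP"
    seed: int = 0

    @model_validator(mode="after")
    def _check_periods(self) -> "SimConfig":
        for label, (a, b) in {
            "pre": (self.pre_start, self.pre_end),
            "post": (self.post_start, self.post_end),
        }.items():
            if not a < b:
                raise ValueError(f"{label} period is degenerate or reversed")
        if not self.pre_end <= self.post_start:
            raise ValueError("pre and post periods must be ordered and disjoint")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("patients", "timing", "values", "overrides")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _truncated_normal(rng, mean, sd, low, size):
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = out < low
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(out, low)


def _interval_hours(ruleset, analyte) -> Optional[float]:
    hours = [r.min_interval_hours for r in ruleset.rules_for(analyte)
             if r.min_interval_hours is not None]
    return min(hours) if hours else None


def generate_patients(config: SimConfig, rng: np.random.Generator,
                      ref_date: datetime) -> pd.DataFrame:
    n = config.n_patients
    female = rng.random(n) < config.female_fraction
    ages = _truncated_normal(rng, config.age_mean, config.age_sd,
                             config.age_min, n)
    ages = np.minimum(ages, config.age_max)
    wards = [config.wards[i % len(config.wards)].name for i in range(n)]
    groups = [config.wards[i % len(config.wards)].group for i in range(n)]
    birth_dates = [
        (ref_date - timedelta(days=float(a) * 365.25)).date().isoformat()
        for a in ages
    ]
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "sex": np.where(female, "F", "M"),
            "birth_date": birth_dates,
            "age": np.floor(ages).astype(int),
            "ward": wards,
            "group": groups,
        }
    )


def generate_cohort(
    config: SimConfig, ruleset=None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patients, results, orders) DataFrames.

    Fully reproducible given ``config.seed``.  Every order row carries
    its period (PRE/POST), whether it is a repeat (follow-up) request,
    and whether the repeat was planted inside the retest interval.
    Every order has a matching executed result at the same timestamp,
    emulating the pre-intervention world in which everything ordered
    was performed.
    """
    if ruleset is None:
        from .datasets import default_ruleset

        ruleset = default_ruleset()
    streams = _substreams(config.seed)
    patients = generate_patients(config, streams["patients"], config.pre_start)
    t_rng, v_rng = streams["timing"], streams["values"]

    periods = {
        "PRE": (config.pre_start, config.pre_end),
        "POST": (config.post_start, config.post_end),
    }
    order_rows = []
    result_rows = []
    for _, prow in patients.iterrows():
        pid, ward = prow["patient_id"], prow["ward"]
        for analyte in sorted(config.analyte_profiles):
            profile = config.analyte_profiles[analyte]
            interval = _interval_hours(ruleset, analyte)
            for period, (start, end) in periods.items():
                days = (end - start).total_seconds() / 86400.0
                horizon = days * 24.0

                def emit(when_hours, is_repeat, planted):
                    ts = start + timedelta(hours=when_hours)
                    order_rows.append(
                        (pid, ward, prow["group"], period, analyte,
                         ts, is_repeat, planted)
                    )
                    value = float(
                        _truncated_normal(
                            v_rng, profile.value_mean, profile.value_sd,
                            0.0, 1,
                        )[0]
                    )
                    result_rows.append((pid, analyte, ts, value, profile.units))

                max_offset = 2.0 * interval if interval else 96.0
                if interval is not None and max_offset >= horizon:
                    # retest interval comparable to the observation window:
                    # a compliant repeat cannot fit, so order at most once
                    if t_rng.poisson(profile.rate_per_patient_day * days) > 0:
                        emit(float(t_rng.uniform(0, horizon)), False, False)
                    continue
                n_pairs = t_rng.poisson(profile.rate_per_patient_day * days / 2.0)
                if n_pairs == 0:
                    continue
                t = float(t_rng.uniform(0, horizon / max(n_pairs, 1)))
                gap_hours = interval if interval else 48.0
                for _ in range(n_pairs):
                    if t + max_offset > horizon:
                        break  # reserve room for either follow-up offset
                    base_t = t
                    if interval is not None:
                        violating = bool(t_rng.random() < config.redundancy_rate)
                        if violating:
                            offset = float(t_rng.uniform(0.05, 0.95)) * interval
                        else:
                            offset = float(t_rng.uniform(1.05, 2.0)) * interval
                    else:
                        violating = False
                        offset = float(t_rng.uniform(24.0, 96.0))
                    follow_t = base_t + offset
                    emit(base_t, False, False)
                    emit(follow_t, True, violating)
                    t = follow_t + 1.05 * gap_hours \
                        + float(t_rng.exponential(0.5 * gap_hours))

    orders = pd.DataFrame(
        order_rows,
        columns=["patient_id", "ward_group", "group", "period", "analyte",
                 "ordered_at", "is_repeat", "planted_violation"],
    )
    orders = orders.sort_values(
        ["ordered_at", "patient_id", "analyte"], kind="mergesort"
    ).reset_index(drop=True)
    orders.insert(0, "order_id", [f"O{i:07d}" for i in range(len(orders))])
    orders["requesting_system"] = config.requesting_system
    orders["priority"] = "ROUTINE"
    orders["sample_type"] = "ANY"

    results = pd.DataFrame(
        result_rows,
        columns=["patient_id", "analyte", "collected_at", "value", "units"],
    )
    results = results.sort_values(
        ["collected_at", "patient_id", "analyte"], kind="mergesort"
    ).reset_index(drop=True)
    results["executed"] = True
    return patients, results, orders


def generate_admissions(
    patients: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """One admission per patient with planted mortality and readmission.

    The planted counts are deterministic (round(rate x N)) so that the
    cohort descriptives recover them exactly.
    """
    n = len(patients)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    order = rng.permutation(n)
    died = np.zeros(n, dtype=bool)
    readmitted = np.zeros(n, dtype=bool)
    died[order[: round(config.mortality_rate * n)]] = True
    readmit_order = rng.permutation(n)
    readmitted[readmit_order[: round(config.readmission_rate * n)]] = True
    offsets = rng.uniform(
        0, (config.pre_end - config.pre_start).total_seconds() / 86400.0, n
    )
    admitted = [
        (config.pre_start + timedelta(days=float(o))).isoformat()
        for o in offsets
    ]
    return pd.DataFrame(
        {
            "patient_id": patients["patient_id"],
            "ward": patients["ward"],
            "admitted_at": admitted,
            "age_at_admission": patients["age"],
            "died": died,
            "readmitted_30d": readmitted,
        }
    )


def apply_cdss_effect(
    orders: pd.DataFrame,
    events: Sequence[AuditEvent],
    override_rate: float,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Filter an order stream by the screening outcome.

    Hard-stopped (BLOCK) requests are cancelled; each soft-stopped
    request is retained with probability ``override_rate`` (the
    prescriber overrides) and cancelled otherwise.  Returns the
    retained request-level table and counters.
    """
    if not 0 <= override_rate <= 1:
        raise ValueError(f"override_rate must be in [0,1], got {override_rate}")
    blocked: set[tuple[str, str]] = set()
    soft: set[tuple[str, str]] = set()
    for e in events:
        for a in e.alerts:
            analytes = a.analyte.split("+") if a.reason == "INCOMPATIBLE_PAIR" \
                else [a.analyte]
            target = blocked if a.kind == "BLOCK" else soft
            for an in analytes:
                target.add((a.order_id, an))
    rng = np.random.default_rng(seed)
    keep = np.ones(len(orders), dtype=bool)
    n_soft = n_soft_retained = n_blocked = 0
    for i, (oid, analyte) in enumerate(
        zip(orders["order_id"], orders["analyte"])
    ):
        key = (oid, analyte)
        if key in blocked:
            keep[i] = False
            n_blocked += 1
        elif key in soft:
            n_soft += 1
            if rng.random() < override_rate:
                n_soft_retained += 1
            else:
                keep[i] = False
    retained = orders.loc[keep].reset_index(drop=True)
    stats = {
        "n_requests": int(len(orders)),
        "n_blocked": n_blocked,
        "n_soft_alerted": n_soft,
        "n_soft_retained": n_soft_retained,
        "n_retained": int(keep.sum()),
    }
    return retained, stats
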