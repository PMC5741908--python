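"""Pre/post impact analytics: volumes, costs, cohort, survey statistics.

The comparison design is two ward groups (intervention, with the
screening system; control, without) observed over a pre period and a
post period.  Percent variations are reported to two decimals with
half-away-from-zero rounding, which is the convention the ward-level
reference figures follow.

Survey statistics cover a 1-5 Likert end-user satisfaction instrument:
Cronbach's alpha for internal consistency (listwise deletion of
incomplete respondents) and Cohen's d with pooled standard deviation
for pre/post satisfaction change, treated as independent samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

Group = Literal["INTERVENTION", "CONTROL"]
Period = Literal["PRE", "POST"]


class UndefinedStatisticError(ValueError):
    """A statistic whose denominator vanished (zero variance etc.)."""


@dataclass(frozen=True)
class WardPeriodSummary:
    ward: str
    group: Group
    period: Period
    n_tests: int
    total_cost: float

    def __post_init__(self):
        if self.n_tests < 0 or int(self.n_tests) != self.n_tests:
            raise ValueError(f"n_tests must be a non-negative integer: {self.n_tests}")
        if self.total_cost < 0:
            raise ValueError(f"total_cost must be non-negative: {self.total_cost}")


@dataclass(frozen=True)
class FeeTable:
    """Per-analyte unit fee in euros, the regional charge per test."""

    fees: Mapping[str, float]

    def __post_init__(self):
        bad = [a for a, f in self.fees.items() if not f > 0]
        if bad:
            raise ValueError(f"fees must be positive; offending analytes: {bad}")


@dataclass
class DeltaRow:
    label: str
    group: Optional[str]
    pre_tests: float
    post_tests: float
    pct_tests: float
    pre_cost: Optional[float] = None
    post_cost: Optional[float] = None
    pct_cost: Optional[float] = None

    @property
    def delta_tests(self) -> float:
        return self.post_tests - self.pre_tests

    @property
    def delta_cost(self) -> Optional[float]:
        if self.pre_cost is None or self.post_cost is None:
            return None
        return self.post_cost - self.pre_cost


@dataclass
class DeltaReport:
    rows: list[DeltaRow] = field(default_factory=list)
    totals: dict[str, DeltaRow] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        records = [vars(r) | {"delta_tests": r.delta_tests, "delta_cost": r.delta_cost,
                              "is_total": False} for r in self.rows]
        records += [vars(r) | {"delta_tests": r.delta_tests, "delta_cost": r.delta_cost,
                               "is_total": True} for r in self.totals.values()]
        return pd.DataFrame(records)


def percent_change(pre: float, post: float) -> float:
    """100 x (post - pre) / pre, to 2 decimals, half away from zero."""
    if not pre > 0:
        raise ValueError(f"pre must be > 0, got {pre}")
    if post < 0:
        raise ValueError(f"post must be >= 0, got {post}")
    raw = 100.0 * (post - pre) / pre
    return float(Decimal(repr(raw)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def ward_comparison(summaries: Sequence[WardPeriodSummary]) -> DeltaReport:
    """Per-ward and per-group pre/post deltas for tests and costs.

    Every ward must appear exactly once per period; group totals sum the
    ward cells before the percent variation is computed.
    """
    seen: dict[tuple[str, str], WardPeriodSummary] = {}
    for s in summaries:
        key = (s.ward, s.period)
        if key in seen:
            raise ValueError(f"duplicate summary for ward {s.ward!r} period {s.period}")
        seen[key] = s
    wards: list[str] = []
    for s in summaries:
        if s.ward not in wards:
            wards.append(s.ward)
    missing = [w for w in wards
               if (w, "PRE") not in seen or (w, "POST") not in seen]
    if missing:
        raise ValueError(f"wards missing a period: {missing}")

    report = DeltaReport()
    group_acc: dict[str, dict[str, float]] = {}
    for w in wards:
        pre, post = seen[(w, "PRE")], seen[(w, "POST")]
        if pre.group != post.group:
            raise ValueError(f"ward {w!r} changes group between periods")
        report.rows.append(
            DeltaRow(
                label=w,
                group=pre.group,
                pre_tests=pre.n_tests,
                post_tests=post.n_tests,
                pct_tests=percent_change(pre.n_tests, post.n_tests),
                pre_cost=pre.total_cost,
                post_cost=post.total_cost,
                pct_cost=percent_change(pre.total_cost, post.total_cost),
            )
        )
        acc = group_acc.setdefault(
            pre.group, {"pre_t": 0, "post_t": 0, "pre_c": 0.0, "post_c": 0.0}
        )
        acc["pre_t"] += pre.n_tests
        acc["post_t"] += post.n_tests
        acc["pre_c"] += pre.total_cost
        acc["post_c"] += post.total_cost
    for group, acc in group_acc.items():
        report.totals[group] = DeltaRow(
            label=f"Total {group.lower()}",
            group=group,
            pre_tests=acc["pre_t"],
            post_tests=acc["post_t"],
            pct_tests=percent_change(acc["pre_t"], acc["post_t"]),
            pre_cost=acc["pre_c"],
            post_cost=acc["post_c"],
            pct_cost=percent_change(acc["pre_c"], acc["post_c"]),
        )
    return report


def analyte_deltas(
    pre_counts: Mapping[str, float], post_counts: Mapping[str, float]
) -> DeltaReport:
    """Per-analyte percent change in request counts between two periods."""
    report = DeltaReport()
    for analyte in sorted(set(pre_counts) | set(post_counts)):
        pre = pre_counts.get(analyte, 0)
        post = post_counts.get(analyte, 0)
        report.rows.append(
            DeltaRow(
                label=analyte,
                group=None,
                pre_tests=pre,
                post_tests=post,
                pct_tests=percent_change(pre, post),
            )
        )
    total_pre = sum(pre_counts.values())
    total_post = sum(post_counts.values())
    report.totals["ALL"] = DeltaRow(
        label="Total",
        group=None,
        pre_tests=total_pre,
        post_tests=total_post,
        pct_tests=percent_change(total_pre, total_post),
    )
    return report


def cost_of_orders(orders: pd.DataFrame, fees: FeeTable) -> float:
    """Total euros for an order stream: sum of the analyte fee per request.

    ``orders`` is the request-level table (one row per request) with an
    ``analyte`` column.  Every analyte present must be priced.
    """
    if len(orders) == 0:
        return 0.0
    counts = orders["analyte"].value_counts()
    unpriced = sorted(set(counts.index) - set(fees.fees))
    if unpriced:
        raise ValueError(f"unpriced analytes: {unpriced}")
    return float(sum(fees.fees[a] * int(n) for a, n in counts.items()))


def cohort_characteristics(
    patients: pd.DataFrame, admissions: pd.DataFrame
) -> dict:
    """Descriptives of an inpatient cohort.

    ``patients``: patient_id, sex, birth_date (or age).  ``admissions``:
    patient_id, ward, admitted_at, age_at_admission (optional), died
    (bool), readmitted_30d (bool).  Percentages to 2 decimals.
    """
    unknown = set(admissions["patient_id"]) - set(patients["patient_id"])
    if unknown:
        raise ValueError(f"admissions reference unknown patients: {sorted(unknown)[:5]}")
    extra = [c for c in patients.columns
             if c == "patient_id" or c not in admissions.columns]
    merged = admissions.merge(patients[extra], on="patient_id", how="left")
    n = len(merged)
    if n == 0:
        return {"n_inpatients": 0, "pct_female": None, "mean_age_by_ward": {},
                "mortality_rate_pct": None, "readmission_30d_rate_pct": None}
    age_col = "age_at_admission" if "age_at_admission" in merged else "age"
    mean_age = {
        ward: round(float(g[age_col].mean()), 2)
        for ward, g in merged.groupby("ward")
    }
    return {
        "n_inpatients": int(n),
        "pct_female": round(100.0 * float((merged["sex"] == "F").mean()), 2),
        "mean_age_by_ward": mean_age,
        "mortality_rate_pct": round(100.0 * float(merged["died"].mean()), 2),
        "readmission_30d_rate_pct": round(
            100.0 * float(merged["readmitted_30d"].mean()), 2
        ),
    }


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance z test for two proportions; two-sided normal p.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled rate.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError(f"sample size must be positive, got {n}")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside [0, {n}]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        # both proportions identically 0 or 1: no evidence of difference
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return z, min(p, 1.0)


def _score_matrix(matrix, items: Optional[Sequence[str]] = None) -> pd.DataFrame:
    if isinstance(matrix, LikertMatrix):
        df = matrix.scores
    else:
        df = pd.DataFrame(matrix)
    if items is not None:
        df = df[list(items)]
    return df


def cronbach_alpha(matrix, items: Optional[Sequence[str]] = None) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / total variance).

    Sample variances (n-1 denominator); incomplete respondents dropped
    listwise.  Raises UndefinedStatisticError when the variance of the
    respondent sums is zero.
    """
    df = _score_matrix(matrix, items).dropna(axis=0, how="any")
    k = df.shape[1]
    if k < 2:
        raise ValueError(f"need >= 2 items, got {k}")
    if df.shape[0] < 2:
        raise ValueError(f"need >= 2 complete respondents, got {df.shape[0]}")
    item_vars = df.var(axis=0, ddof=1)
    total_var = df.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedStatisticError("variance of respondent sums is zero")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Standardized mean difference (b - a) / pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    na, nb = a.size, b.size
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise UndefinedStatisticError("pooled standard deviation is zero")
    return float((b.mean() - a.mean()) / pooled)


class LikertMatrix:
    """Respondent x item scores for the 22-item satisfaction instrument.

    Scores are integers 1..5; missing answers allowed (NaN).  Optional
    respondent metadata (role, sex, tenure band, computer experience,
    education) rides along for subgroup analyses.
    """

    N_ITEMS = 22

    def __init__(
        self,
        scores: pd.DataFrame,
        respondents: Optional[pd.DataFrame] = None,
        require_item_count: bool = True,
    ):
        scores = pd.DataFrame(scores).astype(float)
        if require_item_count and scores.shape[1] != self.N_ITEMS:
            raise ValueError(
                f"expected {self.N_ITEMS} items, got {scores.shape[1]}"
            )
        values = scores.to_numpy()
        finite = values[np.isfinite(values)]
        if finite.size and (
            (finite < 1).any() or (finite > 5).any()
            or not np.allclose(finite, np.round(finite))
        ):
            raise ValueError("scores must be integers in 1..5 (or missing)")
        self.scores = scores
        self.respondents = respondents

    def alpha(self, items: Optional[Sequence[str]] = None) -> float:
        return cronbach_alpha(self, items)


def survey_change_report(
    t0: LikertMatrix, t6: LikertMatrix
) -> pd.DataFrame:
    """Per-item Cohen's d for the satisfaction change between two waves.

    Waves are treated as independent samples; items with zero pooled SD
    are reported with d = NaN.
    """
    common = [c for c in t0.scores.columns if c in set(t6.scores.columns)]
    rows = []
    for item in common:
        a = t0.scores[item].dropna()
        b = t6.scores[item].dropna()
        try:
            d = cohens_d(a, b)
        except (ValueError, UndefinedStatisticError):
            d = float("nan")
        rows.append(
            {"item": item, "mean_t0": float(a.mean()), "mean_t6": float(b.mean()),
             "n_t0": int(a.size), "n_t6": int(b.size), "cohens_d": d}
        )
    return pd.DataFrame(rows)
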