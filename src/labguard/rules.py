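"""Declarative appropriateness rules: types, validation, loading.

A rule set is a single human-editable YAML (or JSON) mapping with keys
``analytes``, ``code_maps``, ``normality_ranges`` and ``rules``.  Each
appropriateness rule names an analyte, a minimum retest interval, the
criteria used to judge the previous result (time only, or time plus a
quantitative check against a sex/age-stratified normality range), any
within-order incompatibilities, the order-priority and ward scope, the
outcome (hard stop vs. soft stop with motivation) and the comment shown
to the prescriber.

Validation is collected, not short-circuited: loading a broken config
reports *every* violation found.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    PrivateAttr,
    ValidationError,
    model_validator,
)

from .durations import DurationError, format_duration, parse_duration_hours

Sex = Literal["F", "M", "ANY"]
PriorCriteria = Literal["TIME_ONLY", "TIME_AND_QUANT"]
PriorityScope = Literal["ROUTINE", "URGENT", "ANY"]
Outcome = Literal["BLOCK", "WARN_WITH_MOTIVATION"]


class RuleSetError(ValueError):
    """Aggregate validation failure; ``errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid rule set:\n" + "\n".join(f"  - {e}" for e in self.errors)
        )


class ConfigurationError(RuntimeError):
    """Ambiguity that load-time validation should have prevented."""


class AnalyteCode(BaseModel):
    """A laboratory examination, with its per-requesting-system local codes."""

    model_config = ConfigDict(extra="forbid")

    canonical_id: str = Field(min_length=1)
    display_name: str = ""
    local_codes: dict[str, str] = Field(default_factory=dict)


class NormalityRange(BaseModel):
    """Sex/age-stratified reference interval for a numeric analyte.

    ``age_min_years`` is inclusive, ``age_max_years`` exclusive
    (``None`` = unbounded); age is completed years at the order time.
    """

    model_config = ConfigDict(extra="forbid")

    analyte: str
    sex: Sex = "ANY"
    age_min_years: int = Field(default=0, ge=0)
    age_max_years: Optional[int] = None
    lower: float
    upper: float
    units: str = ""

    @model_validator(mode="after")
    def _check_bounds(self) -> "NormalityRange":
        if not self.lower < self.upper:
            raise ValueError(
                f"normality range for {self.analyte}: lower ({self.lower}) "
                f"must be < upper ({self.upper})"
            )
        if self.age_max_years is not None and not self.age_min_years < self.age_max_years:
            raise ValueError(
                f"normality range for {self.analyte}: age_min "
                f"({self.age_min_years}) must be < age_max ({self.age_max_years})"
            )
        return self

    def matches(self, sex: str, age_years: int) -> bool:
        if self.sex != "ANY" and self.sex != sex:
            return False
        if age_years < self.age_min_years:
            return False
        if self.age_max_years is not None and age_years >= self.age_max_years:
            return False
        return True

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def age_overlaps(self, other: "NormalityRange") -> bool:
        lo = max(self.age_min_years, other.age_min_years)
        hi_self = float("inf") if self.age_max_years is None else self.age_max_years
        hi_other = float("inf") if other.age_max_years is None else other.age_max_years
        return lo < min(hi_self, hi_other)


class AppropriatenessRule(BaseModel):
    """One declarative screening rule.

    ``min_interval`` accepts "24h" / "3d" / "6mo" spellings and is
    normalised to hours; it may be omitted for rules that only declare
    within-order incompatibilities.
    """

    model_config = ConfigDict(extra="forbid")

    rule_id: str = Field(min_length=1)
    analyte: str
    min_interval: Optional[str | int | float] = None
    prior_criteria: PriorCriteria = "TIME_ONLY"
    incompatible_with: set[str] = Field(default_factory=set)
    priority_scope: PriorityScope = "ANY"
    ward_groups: set[str] = Field(default_factory=set)
    outcome: Outcome = "WARN_WITH_MOTIVATION"
    sample_type: str = "ANY"
    reporting_comment: str = Field(min_length=1)

    min_interval_hours: Optional[float] = None

    @model_validator(mode="after")
    def _normalise(self) -> "AppropriatenessRule":
        if self.min_interval is not None:
            self.min_interval_hours = parse_duration_hours(self.min_interval)
            self.min_interval = format_duration(self.min_interval_hours)
        elif self.min_interval_hours is not None:
            if self.min_interval_hours <= 0:
                raise ValueError(
                    f"rule {self.rule_id}: min_interval must be positive"
                )
            self.min_interval = format_duration(self.min_interval_hours)
        if self.min_interval_hours is None and not self.incompatible_with:
            raise ValueError(
                f"rule {self.rule_id}: needs a min_interval or an "
                "incompatible_with set (otherwise it can never fire)"
            )
        if self.analyte in self.incompatible_with:
            raise ValueError(
                f"rule {self.rule_id}: incompatible_with contains the rule's "
                f"own analyte {self.analyte!r}"
            )
        return self

    @property
    def has_retest_check(self) -> bool:
        return self.min_interval_hours is not None


class RuleSet(BaseModel):
    """A validated bundle of analytes, code maps, normality ranges, rules.

    Lookup tables are cached on first use: treat a RuleSet as immutable
    once it has screened an order (reload instead of mutating).
    """

    model_config = ConfigDict(extra="forbid")

    analytes: list[AnalyteCode] = Field(default_factory=list)
    code_maps: dict[str, dict[str, str]] = Field(default_factory=dict)
    normality_ranges: list[NormalityRange] = Field(default_factory=list)
    rules: list[AppropriatenessRule] = Field(default_factory=list)

    _ids_cache: Optional[set] = PrivateAttr(default=None)
    _code_cache: Optional[dict] = PrivateAttr(default=None)
    _rules_cache: Optional[dict] = PrivateAttr(default=None)

    def analyte_ids(self) -> set[str]:
        if self._ids_cache is None:
            self._ids_cache = {a.canonical_id for a in self.analytes}
        return self._ids_cache

    def rules_for(self, analyte: str) -> list[AppropriatenessRule]:
        if self._rules_cache is None:
            cache: dict[str, list[AppropriatenessRule]] = {}
            for r in self.rules:
                cache.setdefault(r.analyte, []).append(r)
            self._rules_cache = cache
        return self._rules_cache.get(analyte, [])

    def code_index(self) -> dict[tuple[str, str], str]:
        """(system, local code) -> canonical analyte id, from both the
        per-analyte local_codes and the top-level code_maps section."""
        if self._code_cache is not None:
            return self._code_cache
        index: dict[tuple[str, str], str] = {}
        for a in self.analytes:
            for system, local in a.local_codes.items():
                index[(system, local)] = a.canonical_id
        for system, mapping in self.code_maps.items():
            for local, canonical in mapping.items():
                index[(system, local)] = canonical
        self._code_cache = index
        return index


def _cross_validate(ruleset: RuleSet) -> list[str]:
    errors: list[str] = []
    ids = [a.canonical_id for a in ruleset.analytes]
    declared = set(ids)
    seen = set()
    for i in ids:
        if i in seen:
            errors.append(f"duplicate analyte canonical_id {i!r}")
        seen.add(i)

    # no two analytes may share a (system, local code) pair
    pair_owner: dict[tuple[str, str], str] = {}
    for a in ruleset.analytes:
        for system, local in a.local_codes.items():
            key = (system, local)
            if key in pair_owner and pair_owner[key] != a.canonical_id:
                errors.append(
                    f"local code ({system}, {local}) mapped to both "
                    f"{pair_owner[key]!r} and {a.canonical_id!r}"
                )
            pair_owner[key] = a.canonical_id
    for system, mapping in ruleset.code_maps.items():
        for local, canonical in mapping.items():
            if canonical not in declared:
                errors.append(
                    f"code_maps[{system}][{local}] references undeclared "
                    f"analyte {canonical!r}"
                )
            key = (system, local)
            if key in pair_owner and pair_owner[key] != canonical:
                errors.append(
                    f"local code ({system}, {local}) mapped to both "
                    f"{pair_owner[key]!r} and {canonical!r}"
                )
            pair_owner[key] = canonical

    rule_ids = set()
    for r in ruleset.rules:
        if r.rule_id in rule_ids:
            errors.append(f"duplicate rule_id {r.rule_id!r}")
        rule_ids.add(r.rule_id)
        if r.analyte not in declared:
            errors.append(
                f"rule {r.rule_id}: analyte {r.analyte!r} not declared"
            )
        for other in sorted(r.incompatible_with):
            if other not in declared:
                errors.append(
                    f"rule {r.rule_id}: incompatible_with references "
                    f"undeclared analyte {other!r}"
                )

    by_analyte_sex: dict[tuple[str, str], list[NormalityRange]] = {}
    for nr in ruleset.normality_ranges:
        if nr.analyte not in declared:
            errors.append(
                f"normality range references undeclared analyte {nr.analyte!r}"
            )
        by_analyte_sex.setdefault((nr.analyte, nr.sex), []).append(nr)
    # equal-specificity ranges must not overlap in age
    for (analyte, sex), ranges in by_analyte_sex.items():
        for i, a in enumerate(ranges):
            for b in ranges[i + 1:]:
                if a.age_overlaps(b):
                    errors.append(
                        f"normality ranges for {analyte} (sex {sex}) overlap "
                        f"in age: [{a.age_min_years}, {a.age_max_years}) vs "
                        f"[{b.age_min_years}, {b.age_max_years})"
                    )
    return errors


def build_ruleset(payload: dict) -> RuleSet:
    """Validate a parsed config mapping into a RuleSet.

    Raises RuleSetError listing every field-level and cross-reference
    violation found.
    """
    errors: list[str] = []
    try:
        ruleset = RuleSet.model_validate(payload)
    except ValidationError as exc:
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            errors.append(f"{loc}: {err['msg']}")
        raise RuleSetError(errors) from exc
    errors = _cross_validate(ruleset)
    if errors:
        raise RuleSetError(errors)
    return ruleset


def load_ruleset(path) -> RuleSet:
    """Load and validate a rule config file (YAML or JSON)."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            payload = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise RuleSetError([f"parse failure in {path}: {exc}"]) from exc
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise RuleSetError([f"{path}: top level must be a mapping"])
    return build_ruleset(payload)


def dump_ruleset(ruleset: RuleSet, path) -> None:
    """Serialize a RuleSet back to YAML (round-trips through load_ruleset)."""
    payload = ruleset.model_dump(exclude_none=True, exclude={"rules": {"__all__": {"min_interval_hours"}}})
    for rule in payload.get("rules", []):
        for key in ("incompatible_with", "ward_groups"):
            if key in rule:
                rule[key] = sorted(rule[key])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


NO_MATCH = None  # sentinel alias: misses are ordinary outcomes, not errors


def map_code(ruleset: RuleSet, system_id: str, local_code: str) -> Optional[str]:
    """Resolve a requesting-system local code to a canonical analyte id.

    Returns None (no-match) for unmapped codes: the request is then
    exempt from screening, and the caller audit-logs the miss.  Pure
    function of its inputs.
    """
    return ruleset.code_index().get((system_id, local_code))


def lookup_normality(
    ruleset: RuleSet, analyte: str, sex: str, age_years: int
) -> Optional[NormalityRange]:
    """Find the normality range for an analyte given patient sex and age.

    Exact-sex ranges beat ANY-sex ranges; two matches at equal
    specificity indicate a config defect (prevented at load time) and
    raise ConfigurationError.
    """
    if age_years < 0:
        raise ValueError(f"age_years must be >= 0, got {age_years}")
    candidates = [
        nr for nr in ruleset.normality_ranges
        if nr.analyte == analyte and nr.matches(sex, age_years)
    ]
    if not candidates:
        return None
    exact = [nr for nr in candidates if nr.sex != "ANY"]
    pool = exact if exact else candidates
    if len(pool) > 1:
        raise ConfigurationError(
            f"ambiguous normality ranges for {analyte} (sex {sex}, "
            f"age {age_years}): {len(pool)} candidates at equal specificity"
        )
    return pool[0]
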