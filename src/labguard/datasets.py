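"""Bundled reference inputs.

``ward_period_summaries()`` returns the published ward-level pre/post
cells of the two-hospital utilization study (number of tests and total
cost in euros per ward and period) that the impact comparison consumes.
``default_ruleset()`` loads the shipped minimum-retest-interval rules.
``synthetic_fee_table()`` is a synthetic per-analyte fee schedule used
by the simulation examples; regional fee schedules are not published,
so these unit charges are plausible placeholders, not reference data.
"""

from __future__ import annotations

from importlib import resources

from .evaluation import FeeTable, WardPeriodSummary
from .rules import RuleSet, load_ruleset

# (ward, group, n_tests pre, n_tests post, cost pre, cost post)
_WARD_CELLS = [
    ("Cardiology", "INTERVENTION", 5007, 4820, 19122.35, 17980.35),
    ("Medicine", "INTERVENTION", 41499, 34040, 165002.5, 135712.9),
    ("Post-Acute and Long-term care", "CONTROL", 3959, 4125, 14950.75, 14674.9),
    ("Coronary Intensive Care", "CONTROL", 2989, 2559, 13309.5, 10643.9),
    ("Medicine (University)", "CONTROL", 9334, 10209, 41856.0, 46045.0),
]


def ward_period_summaries() -> list[WardPeriodSummary]:
    out: list[WardPeriodSummary] = []
    for ward, group, t_pre, t_post, c_pre, c_post in _WARD_CELLS:
        out.append(WardPeriodSummary(ward, group, "PRE", t_pre, c_pre))
        out.append(WardPeriodSummary(ward, group, "POST", t_post, c_post))
    return out


def default_rules_path():
    return resources.files("labguard").joinpath("data/default_rules.yaml")


def default_ruleset() -> RuleSet:
    with resources.as_file(default_rules_path()) as p:
        return load_ruleset(p)


def synthetic_fee_table() -> FeeTable:
    """Synthetic unit fees (euros/test) for the default analytes."""
    return FeeTable(
        {
            "APTT": 2.85,
            "VANCO": 11.10,
            "CBC": 3.17,
            "CRP": 4.05,
            "PT": 2.85,
            "FERRI": 5.16,
            "TSH": 7.75,
            "NA": 1.50,
            "ANA": 9.30,
            "ANA_REFLEX": 12.40,
        }
    )
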