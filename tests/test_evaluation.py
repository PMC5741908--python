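"""Impact analytics: percent deltas, costs, cohort, survey statistics.

Where an established statistics package implements the same quantity
(pingouin for Cronbach's alpha and Cohen's d, statsmodels for the
two-proportion z test), it serves as an independent oracle against the
in-package formula implementation.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from labguard.datasets import (
    default_ruleset,
    synthetic_fee_table,
    ward_period_summaries,
)
from labguard.evaluation import (
    FeeTable,
    LikertMatrix,
    UndefinedStatisticError,
    WardPeriodSummary,
    analyte_deltas,
    cohens_d,
    cohort_characteristics,
    cost_of_orders,
    cronbach_alpha,
    percent_change,
    survey_change_report,
    two_proportion_test,
    ward_comparison,
)

# the 16 published ward-period cells and their 14 printed percentages
TABLE3_PAIRS = [
    (5007, 4820, -3.73),
    (19122.35, 17980.35, -5.97),
    (41499, 34040, -17.97),
    (165002.5, 135712.9, -17.75),
    (46506, 38860, -16.44),
    (184124.85, 153693.0, -16.53),
    (3959, 4125, 4.19),
    (14950.75, 14674.9, -1.85),
    (2989, 2559, -14.39),
    (13309.5, 10643.9, -20.03),
    (9334, 10209, 9.37),
    (41856.0, 46045.0, 10.01),
    (16282, 16893, 3.75),
    (70116.25, 71363.8, 1.78),
]


class TestPercentChange:
    @pytest.mark.parametrize("pre,post,expected", TABLE3_PAIRS)
    def test_published_cells_reproduce_exactly(self, pre, post, expected):
        assert percent_change(pre, post) == expected

    @pytest.mark.parametrize("x", [1, 42, 2989.0])
    def test_identity(self, x):
        assert percent_change(x, x) == 0.00

    def test_half_away_from_zero_rounding(self):
        # -1.845 must round to -1.85 (away from zero), not -1.84
        assert percent_change(1000, 981.55) == -1.85
        assert percent_change(1000, 1018.45) == 1.85

    @pytest.mark.parametrize("pre", [0, -5])
    def test_nonpositive_pre_rejected(self, pre):
        with pytest.raises(ValueError):
            percent_change(pre, 10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(min_value=0.5, max_value=1e6),
           b=st.floats(min_value=0.5, max_value=1e6))
    def test_antisymmetric_in_sign(self, a, b):
        fwd, rev = percent_change(a, b), percent_change(b, a)
        if fwd > 0:
            assert rev < 0
        elif fwd < 0:
            assert rev > 0


class TestWardComparison:
    def test_reproduces_all_published_percentages(self):
        report = ward_comparison(ward_period_summaries())
        by_ward = {r.label: r for r in report.rows}
        assert by_ward["Cardiology"].pct_tests == -3.73
        assert by_ward["Cardiology"].pct_cost == -5.97
        assert by_ward["Medicine"].pct_tests == -17.97
        assert by_ward["Medicine"].pct_cost == -17.75
        assert by_ward["Post-Acute and Long-term care"].pct_tests == 4.19
        assert by_ward["Post-Acute and Long-term care"].pct_cost == -1.85
        assert by_ward["Coronary Intensive Care"].pct_tests == -14.39
        assert by_ward["Coronary Intensive Care"].pct_cost == -20.03
        assert by_ward["Medicine (University)"].pct_tests == 9.37
        assert by_ward["Medicine (University)"].pct_cost == 10.01
        tot_i = report.totals["INTERVENTION"]
        assert (tot_i.pre_tests, tot_i.post_tests) == (46506, 38860)
        assert tot_i.pct_tests == -16.44
        assert tot_i.pct_cost == -16.53
        tot_c = report.totals["CONTROL"]
        assert (tot_c.pre_tests, tot_c.post_tests) == (16282, 16893)
        assert tot_c.pct_tests == 3.75
        assert tot_c.pct_cost == 1.78

    def test_headline_absolute_deltas(self):
        report = ward_comparison(ward_period_summaries())
        tot = report.totals["INTERVENTION"]
        assert tot.delta_tests == -7646
        assert round(-tot.delta_cost, -2) == 30400.0  # euros, nearest hundred

    def test_single_ward_identity(self):
        report = ward_comparison([
            WardPeriodSummary("W", "CONTROL", "PRE", 100, 50.0),
            WardPeriodSummary("W", "CONTROL", "POST", 100, 50.0),
        ])
        row = report.rows[0]
        assert row.pct_tests == 0.00 and row.pct_cost == 0.00

    def test_missing_period_names_the_ward(self):
        with pytest.raises(ValueError, match="W2"):
            ward_comparison([
                WardPeriodSummary("W1", "CONTROL", "PRE", 1, 1.0),
                WardPeriodSummary("W1", "CONTROL", "POST", 1, 1.0),
                WardPeriodSummary("W2", "CONTROL", "PRE", 1, 1.0),
            ])

    def test_duplicate_cell_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ward_comparison([
                WardPeriodSummary("W", "CONTROL", "PRE", 1, 1.0),
                WardPeriodSummary("W", "CONTROL", "PRE", 2, 2.0),
            ])


class TestCostOfOrders:
    def test_empty_stream(self):
        assert cost_of_orders(pd.DataFrame(columns=["analyte"]),
                              synthetic_fee_table()) == 0.0

    def test_linearity(self):
        fees = FeeTable({"NA": 1.50})
        orders = pd.DataFrame({"analyte": ["NA"] * 3})
        assert cost_of_orders(orders, fees) == pytest.approx(4.50)

    def test_unpriced_analyte_listed(self):
        orders = pd.DataFrame({"analyte": ["NA", "XX", "YY"]})
        with pytest.raises(ValueError) as exc:
            cost_of_orders(orders, FeeTable({"NA": 1.0}))
        assert "XX" in str(exc.value) and "YY" in str(exc.value)

    def test_cost_delta_matches_brute_force_join(self):
        """Pre/post synthetic streams with the screening effect applied:
        cost delta equals the fee-weighted per-analyte count delta."""
        from labguard.engine import screen_stream
        from labguard.io import (
            orders_from_frame,
            patients_from_frame,
            results_from_frame,
        )
        from labguard.synthdata import SimConfig, apply_cdss_effect, generate_cohort

        ruleset = default_ruleset()
        cfg = SimConfig(n_patients=80, seed=33)
        patients, results, orders = generate_cohort(cfg, ruleset)
        events = screen_stream(
            orders_from_frame(orders), patients_from_frame(patients),
            results_from_frame(results), ruleset,
        )
        post, _ = apply_cdss_effect(orders, events, cfg.override_rate, seed=9)
        fees = synthetic_fee_table()
        delta = cost_of_orders(orders, fees) - cost_of_orders(post, fees)
        # brute force: join each removed request against the fee table
        removed = orders[~orders.order_id.isin(set(post.order_id))]
        brute = sum(fees.fees[a] for a in removed.analyte)
        assert delta == pytest.approx(brute)

    def test_nonpositive_fee_rejected(self):
        with pytest.raises(ValueError):
            FeeTable({"NA": 0.0})


class TestCohortCharacteristics:
    def test_two_admissions_one_female(self):
        patients = pd.DataFrame(
            {"patient_id": ["A", "B"], "sex": ["F", "M"], "age": [70, 80]}
        )
        admissions = pd.DataFrame(
            {"patient_id": ["A", "B"], "ward": ["W", "W"],
             "age_at_admission": [70, 80], "died": [False, True],
             "readmitted_30d": [False, False]}
        )
        out = cohort_characteristics(patients, admissions)
        assert out["pct_female"] == 50.00
        assert out["mean_age_by_ward"] == {"W": 75.00}
        assert out["mortality_rate_pct"] == 50.00

    def test_unknown_patient_rejected(self):
        patients = pd.DataFrame({"patient_id": ["A"], "sex": ["F"], "age": [70]})
        admissions = pd.DataFrame(
            {"patient_id": ["Z"], "ward": ["W"], "age_at_admission": [70],
             "died": [False], "readmitted_30d": [False]}
        )
        with pytest.raises(ValueError):
            cohort_characteristics(patients, admissions)

    def test_planted_rates_recovered_by_direct_tally(self):
        from labguard.synthdata import SimConfig, generate_admissions, generate_cohort

        cfg = SimConfig(n_patients=120, seed=77)
        patients, *_ = generate_cohort(cfg)
        admissions = generate_admissions(patients, cfg)
        out = cohort_characteristics(patients, admissions)
        # oracle: direct tally over the admission table
        assert out["n_inpatients"] == len(admissions)
        assert out["mortality_rate_pct"] == round(
            100.0 * admissions["died"].sum() / len(admissions), 2
        )
        assert out["readmission_30d_rate_pct"] == round(
            100.0 * admissions["readmitted_30d"].sum() / len(admissions), 2
        )
        merged = admissions.merge(patients, on="patient_id")
        assert out["pct_female"] == round(
            100.0 * (merged["sex"] == "F").mean(), 2
        )


class TestTwoProportion:
    def test_equal_rates_give_zero(self):
        z, p = two_proportion_test(5, 50, 10, 100)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        # mortality-style counts: rate x N reconstructions
        z, p = two_proportion_test(129, 1233, 147, 1222)
        z_ref, p_ref = proportions_ztest([129, 147], [1233, 1222])
        assert z == pytest.approx(z_ref)
        assert p == pytest.approx(p_ref)

    def test_extreme_split_maximizes_z(self):
        z_ext, _ = two_proportion_test(0, 50, 50, 50)
        z_mid, _ = two_proportion_test(10, 50, 40, 50)
        assert abs(z_ext) > abs(z_mid)

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(0, 0, 1, 10)


def _alpha_oracle(df):
    """Direct evaluation of the alpha formula, independent of the
    implementation under test."""
    k = df.shape[1]
    item_vars = [df[c].var(ddof=1) for c in df.columns]
    total_var = df.sum(axis=1).var(ddof=1)
    return k / (k - 1) * (1 - sum(item_vars) / total_var)


class TestCronbachAlpha:
    def test_duplicated_item_gives_one(self):
        base = pd.Series([1, 2, 4, 5, 3])
        df = pd.DataFrame({f"q{i}": base for i in range(4)})
        assert cronbach_alpha(df) == pytest.approx(1.0)

    def test_constructed_uncorrelated_matrix_gives_zero(self):
        df = pd.DataFrame({"q1": [1, 1, 5, 5], "q2": [1, 5, 1, 5]})
        assert cronbach_alpha(df) == pytest.approx(0.0)
        assert _alpha_oracle(df) == pytest.approx(0.0)

    def test_negatively_correlated_pair_is_negative(self):
        df = pd.DataFrame({"q1": [1, 2, 4, 5], "q2": [5, 4, 2, 2]})
        got = cronbach_alpha(df)
        assert got < 0
        assert got == pytest.approx(_alpha_oracle(df))

    def test_matches_pingouin_on_random_matrix(self):
        import pingouin as pg

        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            rng.integers(1, 6, size=(40, 6)), columns=[f"q{i}" for i in range(6)]
        )
        got = cronbach_alpha(df)
        ref = pg.cronbach_alpha(data=df)[0]
        assert got == pytest.approx(ref)

    def test_listwise_deletion(self):
        df = pd.DataFrame({"q1": [1, 2, 4, 5, np.nan], "q2": [1, 3, 4, 5, 2]})
        assert cronbach_alpha(df) == pytest.approx(
            _alpha_oracle(df.dropna())
        )

    def test_constant_shift_and_reordering_invariance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.integers(1, 6, size=(20, 5)))
        base = cronbach_alpha(df)
        shifted = df.copy()
        shifted[0] = shifted[0] + 7
        assert cronbach_alpha(shifted) == pytest.approx(base)
        shuffled = df.sample(frac=1.0, random_state=1)
        assert cronbach_alpha(shuffled) == pytest.approx(base)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_never_exceeds_one(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.integers(1, 6, size=(8, 4)))
        try:
            assert cronbach_alpha(df) <= 1.0 + 1e-12
        except UndefinedStatisticError:
            pass  # zero total variance is a legitimate signalled outcome

    def test_zero_total_variance_signalled(self):
        df = pd.DataFrame({"q1": [1, 2, 3], "q2": [3, 2, 1]})
        with pytest.raises(UndefinedStatisticError):
            cronbach_alpha(df)


class TestCohensD:
    def test_identical_groups_give_zero(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert cohens_d(a, a) == 0.0

    def test_shift_by_pooled_sd_gives_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s = a.std(ddof=1)
        assert cohens_d(a, a + s) == pytest.approx(1.0)

    def test_matches_direct_formula_on_arbitrary_vectors(self):
        a, b = [2.0, 3.0, 7.0], [1.0, 5.0, 6.0, 9.0]
        na, nb = len(a), len(b)
        pooled = math.sqrt(
            ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
            / (na + nb - 2)
        )
        expected = (np.mean(b) - np.mean(a)) / pooled
        assert cohens_d(a, b) == pytest.approx(expected)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(8)
        a = rng.normal(3.0, 1.0, 30)
        b = rng.normal(3.5, 1.2, 25)
        # pingouin's cohen effect size is (x - y) / pooled sd
        assert cohens_d(b, a) == pytest.approx(
            pg.compute_effsize(a, b, eftype="cohen")
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 5.0), st.floats(-10.0, 10.0))
    def test_antisymmetry_and_affine_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 12)
        d = cohens_d(a, b)
        assert cohens_d(b, a) == pytest.approx(-d)
        assert cohens_d(scale * a + shift, scale * b + shift) == pytest.approx(
            d, abs=1e-9
        )

    def test_zero_pooled_sd_signalled(self):
        with pytest.raises(UndefinedStatisticError):
            cohens_d([2.0, 2.0, 2.0], [3.0, 3.0])


class TestLikertMatrix:
    def test_item_count_enforced(self):
        with pytest.raises(ValueError):
            LikertMatrix(pd.DataFrame(np.ones((3, 5))))

    def test_score_domain_enforced(self):
        df = pd.DataFrame(np.full((3, 22), 6.0))
        with pytest.raises(ValueError):
            LikertMatrix(df)

    def test_survey_change_report_per_item_d(self):
        rng = np.random.default_rng(4)
        cols = [f"q{i}" for i in range(22)]
        t0 = LikertMatrix(pd.DataFrame(
            rng.integers(1, 6, size=(30, 22)), columns=cols))
        t6 = LikertMatrix(pd.DataFrame(
            rng.integers(1, 6, size=(20, 22)), columns=cols))
        report = survey_change_report(t0, t6)
        assert len(report) == 22
        row = report.iloc[0]
        assert row["cohens_d"] == pytest.approx(
            cohens_d(t0.scores["q0"], t6.scores["q0"])
        )


class TestAnalyteDeltas:
    def test_planted_deltas_recovered_exactly(self):
        pre = {"APTT": 200, "NA": 400, "TSH": 50}
        post = {"APTT": 150, "NA": 400, "TSH": 60}
        report = analyte_deltas(pre, post)
        by_label = {r.label: r for r in report.rows}
        assert by_label["APTT"].pct_tests == -25.00
        assert by_label["NA"].pct_tests == 0.00
        assert by_label["TSH"].pct_tests == 20.00
        assert report.totals["ALL"].pct_tests == percent_change(650, 610)

    def test_synthetic_stream_counts_recovered(self):
        """Planted per-analyte reductions on a synthetic stream round-trip
        through the counting + percent-change pipeline exactly."""
        from labguard.synthdata import SimConfig, generate_cohort

        cfg = SimConfig(n_patients=50, seed=55)
        *_, orders = generate_cohort(cfg)
        pre = orders[orders.period == "PRE"].analyte.value_counts().to_dict()
        post = orders[orders.period == "POST"].analyte.value_counts().to_dict()
        report = analyte_deltas(pre, post)
        for row in report.rows:
            expected = percent_change(pre.get(row.label, 0),
                                      post.get(row.label, 0))
            assert row.pct_tests == expected
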