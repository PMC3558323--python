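"""Odds ratios, chi-square, logistic regression and Kaplan-Meier/log-rank."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, random_table

from g2i import datasets as ds
from g2i.stats import (
    expand_2x2,
    grade_odds_ratios,
    grade_relapse_counts,
    km_logrank,
    logistic_regression,
    odds_ratio_wald,
    pearson_chi_square,
)


class TestOddsRatio:
    def test_grade3_vs_grade2_relapse(self):
        """21/7 vs 23/65 relapse: OR 8.5 [3.2-22.6], as in the cohort report."""
        r = odds_ratio_wald(np.array([[21, 7], [23, 65]]))
        assert round(r.odds_ratio, 1) == 8.5
        assert round(r.ci_low, 1) == 3.2 and round(r.ci_high, 1) == 22.6
        assert r.p_value < 0.001

    def test_grade1_vs_grade2_relapse(self):
        """1/18 vs 23/65: OR 0.16, borderline p ~0.08."""
        r = odds_ratio_wald(np.array([[1, 18], [23, 65]]))
        assert round(r.odds_ratio, 2) == 0.16
        assert 0.05 < r.p_value < 0.12
        assert r.ci_low < 0.16 < r.ci_high  # a CI always covers its estimate

    def test_balanced_table_or_one(self):
        r = odds_ratio_wald(np.array([[10, 10], [10, 10]]))
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_double_flip_invariance_and_single_flip_inversion(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            t = rng.integers(1, 40, size=(2, 2))
            orig = odds_ratio_wald(t).odds_ratio
            both = odds_ratio_wald(t[::-1, ::-1]).odds_ratio
            rows = odds_ratio_wald(t[::-1, :]).odds_ratio
            assert both == pytest.approx(orig, rel=1e-12)
            assert rows == pytest.approx(1 / orig, rel=1e-12)

    def test_zero_cell_haldane_flagged(self):
        r = odds_ratio_wald(np.array([[0, 19], [24, 64]]))
        assert r.corrected and np.isfinite(r.odds_ratio)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            odds_ratio_wald(np.array([[0, 0], [5, 5]]))


class TestChiSquare:
    @pytest.mark.parametrize("table,printed,decimals", [
        (ds.TP53_BY_GRADE, 0.0003, 4),
        (ds.SBR_BY_GRADE, 0.037, 3),
        (ds.MIB1_BY_GRADE, 0.011, 3),
        (ds.INTRINSIC_BY_GRADE, 0.014, 3),
    ])
    def test_cohort_tables_reproduce_printed_p(self, table, printed, decimals):
        _, _, p = pearson_chi_square(table)
        assert round(p, decimals) == printed

    def test_amplicon_table_p_at_printed_precision(self):
        _, _, p = pearson_chi_square(ds.AMPLICON_BY_GRADE)
        assert f"{p:.1g}" == "0.0009" or round(p, 3) == 0.001

    def test_proportional_rows_statistic_zero(self):
        stat, df, p = pearson_chi_square(np.array([[10, 20, 30], [1, 2, 3]]))
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_df_and_no_continuity_correction(self):
        t = np.array([[5, 9], [12, 3]])
        stat, df, p = pearson_chi_square(t)
        ref = chi2_contingency(t, correction=False)
        assert df == 1 and stat == pytest.approx(ref.statistic)
        corrected = chi2_contingency(t, correction=True)
        assert stat != pytest.approx(corrected.statistic)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="total"):
            pearson_chi_square(np.zeros((2, 2)))

    def test_matches_monte_carlo_permutation_null(self):
        """Asymptotic p within 3 MC SDs of a 100k fixed-margin permutation p."""
        table = ds.SBR_BY_GRADE
        stat, _, p_asym = pearson_chi_square(table)
        rng = np.random.default_rng(12345)
        rt = random_table(table.sum(axis=1), table.sum(axis=0))
        samples = rt.rvs(100_000, random_state=rng)
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        null_stats = ((samples - expected) ** 2 / expected).sum(axis=(1, 2))
        p_mc = float((null_stats >= stat - 1e-9).mean())
        sd = np.sqrt(p_mc * (1 - p_mc) / 100_000)
        assert abs(p_mc - p_asym) <= 3 * sd


class TestLogistic:
    def test_exp_coef_equals_closed_form_or_to_6dp(self):
        """On per-observation 2x2 data the slope reproduces the cross-product OR."""
        for table in ([[21, 7], [23, 65]], [[16, 4], [8, 35]], [[9, 30], [14, 22]]):
            design, outcome = expand_2x2(np.array(table))
            fit = logistic_regression(design, outcome)
            closed = odds_ratio_wald(np.array(table)).odds_ratio
            assert fit.odds_ratios["exposed"] == pytest.approx(closed, abs=1e-6)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_regression(pd.DataFrame({"x": [1, 2, 3]}), np.ones(3))

    def test_perfect_separation_names_covariate(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = (x > 0.5).astype(int)
        with pytest.raises(ValueError, match="separation on covariate 'x'"):
            logistic_regression(pd.DataFrame({"x": x}), y)

    def test_coefficient_recovery_within_2se(self):
        """Known log-odds model at n=2000: slope recovered within 2 SE."""
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.normal(size=n)
        beta0, beta1 = -0.5, 0.8
        p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
        y = (rng.random(n) < p).astype(int)
        fit = logistic_regression(pd.DataFrame({"x": x}), y)
        assert abs(fit.params["x"] - beta1) <= 2 * fit.bse["x"]
        assert abs(fit.params["const"] - beta0) <= 2 * fit.bse["const"]

    def test_multifactor_model_runs(self):
        rng = np.random.default_rng(8)
        n = 400
        design = pd.DataFrame({
            "grade3": rng.integers(0, 2, n),
            "npi": rng.integers(1, 4, n),
        })
        logit = -1 + 1.2 * design["grade3"] + 0.3 * design["npi"]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        fit = logistic_regression(design, y)
        assert fit.p_values["grade3"] < 0.05
        assert np.isfinite(fit.deviance)


class TestGradeHelpers:
    def test_relapse_counts_and_ors_from_scores(self):
        scores = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(6)],
            "A": [0.1] * 6, "N": [10] * 6,
            "grade": [1, 2, 2, 3, 3, 3],
        })
        clinical = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(6)],
            "relapse": [0, 0, 1, 1, 1, 0],
        })
        counts = grade_relapse_counts(scores, clinical)
        assert counts.loc[3, "relapse"] == 2 and counts.loc[2, "no_relapse"] == 1
        ors = grade_odds_ratios(counts).set_index("grade")
        assert ors.loc[3, "odds_ratio"] == pytest.approx((2 / 1) / (1 / 1))


class TestSurvival:
    def test_identical_groups_hr_one_p_one(self):
        base = pd.DataFrame({
            "time": [5.0, 10.0, 15.0, 20.0], "event": [1, 0, 1, 0],
        })
        records = pd.concat([
            base.assign(group="a"), base.assign(group="b")
        ], ignore_index=True)
        res = km_logrank(records)
        assert res.hazard_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_risk_sets(self):
        """A events at 1,2,3; B events at 10,20,30; no censoring.

        Risk-set tabulation by hand: E_A = 3/6 + 2/5 + 1/4 = 1.15 with
        O_A = 3; E_B = 6 - 1.15 = 4.85 with O_B = 3, so the O/E hazard
        ratio is (3/1.15)/(3/4.85) = 4.2174.  The statistic is
        (O_A - E_A)^2 / V with the hypergeometric variance of each table.
        """
        records = pd.DataFrame({
            "time": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
            "event": [1] * 6,
            "group": ["a"] * 3 + ["b"] * 3,
        })
        res = km_logrank(records)
        assert res.observed["a"] == 3
        assert res.expected["a"] == pytest.approx(1.15)
        assert res.hazard_ratio == pytest.approx((3 / 1.15) / (3 / 4.85))
        # exhaustive variance tabulation: d=1 at each time, V_t = n1 n2 / n^2
        n_a, n_b = 3, 3
        variance = 0.0
        for t in (1, 2, 3, 10, 20, 30):
            n = n_a + n_b
            variance += n_a * n_b / n**2
            if t <= 3:
                n_a -= 1
            else:
                n_b -= 1
        assert res.statistic == pytest.approx((3 - 1.15) ** 2 / variance)

    def test_km_without_censoring_is_empirical_survival(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(50, size=40).round(1) + 1
        records = pd.DataFrame({"time": times, "event": 1, "group": "x"})
        res = km_logrank(
            pd.concat([records, records.assign(group="y")], ignore_index=True)
        )
        curve = res.curves["x"]
        for _, row in curve.iterrows():
            if row["time"] > 0:
                assert row["survival"] == pytest.approx((times > row["time"]).mean())

    def test_km_monotone_and_starts_at_one(self):
        records = pd.DataFrame({
            "time": [3.0, 6.0, 6.0, 9.0, 12.0], "event": [1, 1, 0, 1, 0],
            "group": ["g"] * 5,
        })
        records = pd.concat([records, records.assign(group="h")], ignore_index=True)
        curve = km_logrank(records).curves["g"]
        surv = curve["survival"].to_numpy()
        assert (np.diff(surv) <= 1e-12).all()
        assert curve.loc[curve["time"] == 0.0, "survival"].iloc[0] == 1.0

    def test_zero_events_rejected(self):
        records = pd.DataFrame({
            "time": [5.0, 6.0], "event": [0, 0], "group": ["a", "b"],
        })
        with pytest.raises(ValueError, match="no events"):
            km_logrank(records)
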