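"""Association and survival statistics for instability-grade analyses.

Implements the statistics layer used to relate genomic grades to outcome
and clinicopathological factors: Wald odds ratios from 2x2 tables,
Pearson chi-square tests (no continuity correction), maximum-likelihood
logistic regression, and Kaplan-Meier / log-rank machinery with the
hazard ratio computed from observed/expected event ratios.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats as sps


@dataclasses.dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool  # Haldane-Anscombe +0.5 applied (some cell was zero)


def odds_ratio_wald(table: np.ndarray) -> OddsRatioResult:
    """Cross-product odds ratio with Wald 95% CI and p from a 2x2 table.

    Rows are the two exposure groups, columns (event, no event):
    OR = (a*d)/(b*c).  When any cell is zero, the Haldane-Anscombe +0.5
    correction is applied to every cell and flagged in the result.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("odds_ratio_wald needs a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: odds ratio undefined")
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    return OddsRatioResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - 1.959963984540054 * se)),
        ci_high=float(np.exp(log_or + 1.959963984540054 * se)),
        p_value=float(2 * sps.norm.sf(abs(z))),
        corrected=corrected,
    )


def pearson_chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (statistic, df, p)."""
    t = np.asarray(table, dtype=float)
    if t.sum() == 0:
        raise ValueError("zero grand total")
    statistic, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(statistic), int(df), float(p)


@dataclasses.dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    p_values: pd.Series
    deviance: float
    odds_ratios: pd.Series

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = sps.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "low": np.exp(self.params - z * self.bse),
            "high": np.exp(self.params + z * self.bse),
        })


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for col in X.columns:
        if col == "const":
            continue
        x = X[col].to_numpy(dtype=float)
        x0, x1 = x[y == 0], x[y == 1]
        if len(x0) and len(x1) and (x0.max() < x1.min() or x1.max() < x0.min()):
            raise ValueError(
                f"perfect separation on covariate {col!r}: "
                "logistic MLE does not exist"
            )


def logistic_regression(
    design: pd.DataFrame, outcome: np.ndarray, add_constant: bool = True
) -> LogisticFit:
    """Newton-Raphson maximum-likelihood logistic regression.

    Raises on a constant outcome and on perfect separation (naming the
    separating covariate).  ``exp(params)`` are odds ratios.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; logistic model undefined")
    X = pd.DataFrame(design).astype(float)
    if add_constant:
        X = sm.add_constant(X, has_constant="add")
    _check_separation(X, y)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(method="IRLS", tol=1e-10, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels-internal failures
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if np.abs(res.params.to_numpy()).max() > 30:
        raise ValueError("diverging coefficients: data are (quasi-)separated")
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        p_values=pd.Series(
            2 * sps.norm.sf(np.abs(res.params / res.bse)), index=res.params.index
        ),
        deviance=float(res.deviance),
        odds_ratios=np.exp(res.params),
    )


def expand_2x2(table: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-observation (exposure, outcome) rows for a 2x2 count table.

    Row 0 is the exposed group, column 0 the event; useful for checking
    the analytic identity exp(logistic slope) == cross-product OR.
    """
    t = np.asarray(table, dtype=int)
    exposure, outcome = [], []
    for i in (0, 1):
        for j in (0, 1):
            exposure += [1 - i] * t[i, j]
            outcome += [1 - j] * t[i, j]
    return pd.DataFrame({"exposed": exposure}), np.array(outcome)


# ---------------------------------------------------------------------------
# survival


@dataclasses.dataclass
class SurvivalResult:
    curves: dict[object, pd.DataFrame]  # group -> (time, survival) steps
    statistic: float
    p_value: float
    hazard_ratio: float | None          # two groups only: (O1/E1)/(O2/E2)
    observed: dict[object, float]
    expected: dict[object, float]


def _observed_expected(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[dict, dict]:
    """Log-rank O and E per group from the pooled risk-set tabulation."""
    groups = pd.unique(group)
    observed = {g: 0.0 for g in groups}
    expected = {g: 0.0 for g in groups}
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = ((time == t) & (event == 1)).sum()
        for g in groups:
            in_g = group == g
            observed[g] += float(((time == t) & (event == 1) & in_g).sum())
            expected[g] += float(d_t * (at_risk & in_g).sum() / n_t)
    return observed, expected


def km_logrank(records: pd.DataFrame, group_col: str = "group") -> SurvivalResult:
    """Kaplan-Meier curves per group plus the log-rank comparison.

    ``records`` needs columns ``time`` (months, > 0), ``event`` (0/1) and a
    group column.  For two groups the hazard ratio is the ratio of
    observed/expected event counts, in group order of first appearance.
    """
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    group = records[group_col].to_numpy()
    if (time <= 0).any():
        raise ValueError("times must be positive")
    if event.sum() == 0:
        raise ValueError("no events: survival comparison undefined")
    curves = {}
    for g in pd.unique(group):
        kmf = KaplanMeierFitter()
        kmf.fit(time[group == g], event[group == g], label=str(g))
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    groups = pd.unique(group)
    if len(groups) == 2:
        m0, m1 = group == groups[0], group == groups[1]
        lr = logrank_test(time[m0], time[m1], event[m0], event[m1])
        observed, expected = _observed_expected(time, event, group)
        rate0 = observed[groups[0]] / expected[groups[0]]
        rate1 = observed[groups[1]] / expected[groups[1]]
        hr = rate0 / rate1 if rate1 > 0 else np.inf
    else:
        lr = multivariate_logrank_test(time, group, event)
        observed, expected = _observed_expected(time, event, group)
        hr = None
    return SurvivalResult(
        curves=curves,
        statistic=float(lr.test_statistic),
        p_value=float(lr.p_value),
        hazard_ratio=hr,
        observed=observed,
        expected=expected,
    )


# ---------------------------------------------------------------------------
# grade-level convenience


def grade_relapse_counts(scores: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """(relapse, no relapse) counts per G2I grade, merged on sample_id."""
    merged = scores.merge(clinical[["sample_id", "relapse"]], on="sample_id")
    rows = []
    for grade in (1, 2, 3):
        sub = merged[merged["grade"] == grade]
        rows.append({
            "grade": grade,
            "relapse": int(sub["relapse"].sum()),
            "no_relapse": int((1 - sub["relapse"]).sum()),
        })
    return pd.DataFrame(rows).set_index("grade")


def grade_odds_ratios(counts: pd.DataFrame, reference: int = 2) -> pd.DataFrame:
    """Univariate OR of relapse for each grade against the reference grade."""
    rows = []
    ref = counts.loc[reference]
    for grade in counts.index:
        if grade == reference or counts.loc[grade].sum() == 0:
            continue
        table = np.array([
            [counts.loc[grade, "relapse"], counts.loc[grade, "no_relapse"]],
            [ref["relapse"], ref["no_relapse"]],
        ])
        r = odds_ratio_wald(table)
        rows.append({
            "grade": grade, "reference": reference, "odds_ratio": r.odds_ratio,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "p_value": r.p_value,
        })
    return pd.DataFrame(rows)
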