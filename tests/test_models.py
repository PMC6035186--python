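"""Risk-model kernel: single fits, fit statistics, VIF screen, stepwise."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diabench.models import (
    CollinearityError,
    FitError,
    ModelSpec,
    adjusted_r2,
    describe_odds_ratio,
    fit_glm,
    odds_ratio_percent_change,
    roc_auc,
    screen_collinearity,
    spec_for,
    stepwise_select,
)
from diabench.design import TERM_COLUMNS, build_design

from conftest import toy_records


# --------------------------------------------------------------------------
# fit_glm
# --------------------------------------------------------------------------


def test_exact_linear_fit_recovers_coefficients():
    df = toy_records(n=50, seed=1, beta=(2.0, 3.0), sd=0.0)
    m = fit_glm(df, "hba1c", ("age10",))
    assert m.table.loc["age10", "coef"] == pytest.approx(3.0, abs=1e-9)
    assert m.table.loc["intercept", "coef"] == pytest.approx(2.0, abs=1e-8)
    assert m.fit_stat == pytest.approx(1.0, abs=1e-12)


def test_logistic_fit_matches_contingency_cross_product():
    """2x2 table (exposed 30/70, unexposed 10/90): OR = 30*90/(70*10)."""
    rows = (
        [dict(smoking="ever", severe_hypo=1.0)] * 30
        + [dict(smoking="ever", severe_hypo=0.0)] * 70
        + [dict(smoking="never", severe_hypo=1.0)] * 10
        + [dict(smoking="never", severe_hypo=0.0)] * 90
    )
    df = pd.DataFrame(rows)
    m = fit_glm(df, "severe_hypo", ("smoking",), family="logistic")
    assert m.table.loc["smoking_ever", "odds_ratio"] == pytest.approx(
        30 * 90 / (70 * 10), rel=1e-6
    )
    # OR/coefficient duality
    assert m.table.loc["smoking_ever", "odds_ratio"] == pytest.approx(
        np.exp(m.table.loc["smoking_ever", "coef"]), abs=1e-10
    )


def test_t1dm_hypo_duration_or_recovered(t1dm_cohort):
    """Generating OR 1.39 per decade of duration is recovered within the
    fitted 95% CI on the audited T1DM stratum size."""
    m = fit_glm(t1dm_cohort, "severe_hypo", ("duration10", "bmi_category", "smoking"))
    lo, hi = m.table.loc["duration10", ["or_ci_low", "or_ci_high"]]
    assert lo <= 1.39 <= hi


def test_complete_case_behaviour():
    df = toy_records(n=100, seed=2)
    df.loc[:9, "hba1c"] = np.nan
    df.loc[10:19, "age"] = np.nan
    m = fit_glm(df, "hba1c", ("age10",))
    assert m.n_used == 80


def test_singular_design_errors_with_term_name():
    df = toy_records(n=60, seed=3)
    df["bmi_category"] = "healthy"  # all dummies zero -> constant columns
    with pytest.raises(FitError):
        fit_glm(df, "hba1c", ("age10", "bmi_category"))


def test_per_decade_convention_scales_per_year_coefficient():
    """Fitting on age/10 gives exactly 10x the per-year coefficient."""
    df = toy_records(n=300, seed=4, sd=0.5)
    m10 = fit_glm(df, "hba1c", ("age10",))
    X = np.column_stack([np.ones(len(df)), df["age"]])
    beta_yearly = np.linalg.lstsq(X, df["hba1c"], rcond=None)[0][1]
    assert m10.table.loc["age10", "coef"] == pytest.approx(10 * beta_yearly, rel=1e-10)


# --------------------------------------------------------------------------
# Fit statistics
# --------------------------------------------------------------------------


def test_adjusted_r2_formula():
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    yhat = y + np.array([0.1, -0.1, 0.2, -0.2, 0.0, 0.0])
    r2 = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
    expected = 1 - (1 - r2) * (6 - 1) / (6 - 2 - 1)
    assert adjusted_r2(y, yhat, 2) == pytest.approx(expected, abs=1e-12)
    with pytest.raises(FitError):
        adjusted_r2(y[:3], yhat[:3], 2)


def test_roc_auc_brute_force_over_pairs():
    """Events {0.9, 0.8}, non-events {0.1, 0.9}: the four event/non-event
    pairs score 1, 0.5, 1, 0 -> AUC 2.5/4 = 0.625."""
    y = np.array([1, 1, 0, 0])
    s = np.array([0.9, 0.8, 0.1, 0.9])
    assert roc_auc(y, s) == pytest.approx(0.625)
    # rank statistic agrees with exhaustive pair counting on random data
    rng = np.random.default_rng(5)
    y2 = rng.integers(0, 2, 200)
    s2 = rng.random(200).round(1)  # force ties
    pairs = [
        1.0 if a > b else 0.5 if a == b else 0.0
        for a in s2[y2 == 1]
        for b in s2[y2 == 0]
    ]
    assert roc_auc(y2, s2) == pytest.approx(np.mean(pairs), abs=1e-12)


def test_intercept_only_logistic_has_no_discrimination():
    rng = np.random.default_rng(6)
    df = pd.DataFrame({"severe_hypo": rng.integers(0, 2, 100).astype(float)})
    import statsmodels.api as sm

    probs = np.full(100, df["severe_hypo"].mean())
    assert roc_auc(df["severe_hypo"].to_numpy(), probs) == pytest.approx(0.5)


# --------------------------------------------------------------------------
# Collinearity screen
# --------------------------------------------------------------------------


def _records_from_matrix(cols: dict, y: np.ndarray) -> pd.DataFrame:
    """Map raw numeric columns onto record fields (age, duration carry them)."""
    df = pd.DataFrame({"hba1c": y})
    mapping = {"x1": "age", "x2": "duration"}
    for k, v in cols.items():
        df[mapping.get(k, k)] = v
    return df


def test_orthogonal_predictors_have_unit_vif():
    rng = np.random.default_rng(7)
    n = 400
    x1 = np.repeat([0.0, 1.0], n // 2)
    x2 = np.tile([0.0, 1.0], n // 2)  # orthogonal to x1 by construction
    y = x1 + x2 + rng.normal(0, 1, n)
    df = pd.DataFrame({"age": 10 * x1, "duration": 10 * x2, "hba1c": y})
    kept, report = screen_collinearity(df, "hba1c", ["age10", "duration10"])
    assert kept == ["age10", "duration10"]
    assert len(report) == 0


def test_near_duplicate_predictor_dropped_by_z():
    """x2 = x1 + tiny noise: huge VIFs, exactly one of the pair dropped,
    VIF matching the auxiliary-regression definition."""
    rng = np.random.default_rng(8)
    n = 500
    x1 = rng.normal(50, 10, n)
    x2 = x1 + rng.normal(0, 0.05, n)
    y = 0.1 * x1 + rng.normal(0, 1, n)
    df = pd.DataFrame({"age": x1, "duration": x2, "hba1c": y,
                       "smoking": rng.choice(["never", "ever"], n)})
    kept, report = screen_collinearity(df, "hba1c", ["age10", "duration10", "smoking"])
    assert len(report) == 1
    assert set(kept) >= {"smoking"}
    assert len(set(kept) & {"age10", "duration10"}) == 1
    # independent VIF oracle: R^2 of x1 on (x2, smoking dummy)
    smk = (df["smoking"] == "ever").astype(float)
    X = np.column_stack([np.ones(n), x2 / 10, smk])
    beta, *_ = np.linalg.lstsq(X, x1 / 10, rcond=None)
    resid = x1 / 10 - X @ beta
    r2 = 1 - resid.var() / (x1 / 10).var()
    assert report.iloc[0]["vif"] == pytest.approx(1 / (1 - r2), rel=1e-6)


def test_exact_duplicate_drops_later_term():
    rng = np.random.default_rng(9)
    n = 200
    x = rng.normal(40, 8, n)
    y = 0.2 * x + rng.normal(0, 1, n)
    df = pd.DataFrame({"age": x, "duration": x, "hba1c": y})
    kept, report = screen_collinearity(df, "hba1c", ["age10", "duration10"])
    assert kept == ["age10"]  # tie on |z| -> later term dropped
    assert np.isinf(report.iloc[0]["vif"])


def test_constant_column_raises():
    df = pd.DataFrame({"age": 50.0, "duration": np.arange(20) * 1.0,
                       "hba1c": np.arange(20) * 0.1})
    with pytest.raises(CollinearityError, match="age10"):
        screen_collinearity(df, "hba1c", ["age10", "duration10"])


# --------------------------------------------------------------------------
# Stepwise selection
# --------------------------------------------------------------------------


def test_null_candidate_not_selected():
    """One candidate with zero true effect at large n: intercept only."""
    df = toy_records(n=5000, seed=10, beta=(5.0, 0.0), sd=1.0)
    spec = ModelSpec(outcome="hba1c", candidates=("age10",))
    m = stepwise_select(df, spec)
    assert m.terms == ()


def test_forced_term_retained_regardless_of_p(t2dm_cohort):
    """Fasting status stays in the LDL-Ch model even when p ~ 0.9."""
    m = stepwise_select(t2dm_cohort, spec_for("ldl_ch", "t2dm"))
    assert "fasting_at_lipids" in m.terms
    assert "fasting" in m.table.index


def test_selection_invariant_to_row_order(t1dm_cohort):
    spec = spec_for("hba1c", "t1dm")
    m1 = stepwise_select(t1dm_cohort, spec)
    shuffled = t1dm_cohort.sample(frac=1.0, random_state=11).reset_index(drop=True)
    m2 = stepwise_select(shuffled, spec)
    assert set(m1.terms) == set(m2.terms)
    assert np.allclose(
        m1.table["coef"].sort_index(), m2.table["coef"].sort_index(), atol=1e-8
    )


def test_retained_terms_significant_at_removal_threshold(t2dm_cohort):
    """Every retained non-forced term has joint Wald p <= p_remove."""
    spec = spec_for("hba1c", "t2dm")
    m = stepwise_select(t2dm_cohort, spec)
    res = m._result
    X_cols = list(m.table.index)
    for t in m.terms:
        idx = [X_cols.index(c) for c in TERM_COLUMNS[t] if c in X_cols]
        theta = np.asarray(res.params)[idx]
        cov = np.asarray(res.cov_params())[np.ix_(idx, idx)]
        w = theta @ np.linalg.solve(cov, theta)
        p = stats.chi2.sf(w, len(idx))
        assert p <= spec.p_remove + 1e-12


def test_t2dm_hba1c_selection_retains_generating_terms(t2dm_cohort):
    """At the audited stratum size the generating terms are retained."""
    m = stepwise_select(t2dm_cohort, spec_for("hba1c", "t2dm"))
    assert {"age10", "sex", "duration10", "dcsi_category", "smoking"} <= set(m.terms)


# --- exhaustive rule-replay oracle -----------------------------------------


def oracle_stepwise(df, spec):
    """Direct replay of the enter/remove rules with hand-computed Wald
    chi-square tests; independent of the package's selection loop."""
    import statsmodels.api as sm

    sub = df.dropna(subset=[spec.outcome])

    def wald_p(terms, block):
        X = build_design(sub, terms)
        y = sub[spec.outcome].to_numpy(float)
        res = (sm.OLS(y, X).fit() if spec.family == "linear"
               else sm.Logit(y, X).fit(disp=0))
        cols = list(X.columns)
        idx = [cols.index(c) for c in TERM_COLUMNS[block]]
        th = np.asarray(res.params)[idx]
        cv = np.asarray(res.cov_params())[np.ix_(idx, idx)]
        return float(stats.chi2.sf(th @ np.linalg.solve(cv, th), len(idx)))

    current = list(spec.forced)
    while True:
        changed = False
        outside = [t for t in spec.candidates if t not in current and t not in spec.forced]
        ps = [(wald_p(current + [t], t), i, t) for i, t in enumerate(outside)]
        entrants = [x for x in ps if x[0] < spec.p_enter]
        if entrants:
            _, _, best = min(entrants)  # ties -> earlier candidate order
            current.append(best)
            changed = True
        while True:
            removable = [t for t in current if t not in spec.forced]
            if not removable:
                break
            ps = [(wald_p(current, t), -i, t)
                  for i, t in enumerate(t2 for t2 in current if t2 in removable)]
            p, _, worst = max(ps)
            if p > spec.p_remove:
                current.remove(worst)
                changed = True
            else:
                break
        if not changed:
            return tuple(sorted(current))


@pytest.mark.parametrize("seed", range(10))
def test_stepwise_matches_replay_oracle(seed):
    """Selected term sets identical to the rule-replay oracle on small
    designs (<= 4 candidates, n <= 200)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(80, 200))
    df = toy_records(n=n, seed=seed, beta=(5.0, 0.0), sd=1.0)
    # plant effects of varying strength so selection is non-trivial
    df["hba1c"] = (
        5.0
        + rng.choice([0.0, 0.3]) * (df["age"] / 10)
        + rng.choice([0.0, 0.5]) * (df["sex"] == "female")
        + rng.choice([0.0, 0.4]) * (df["smoking"] == "ever")
        + rng.normal(0, 1.0, n)
    )
    spec = ModelSpec(outcome="hba1c",
                     candidates=("age10", "sex", "smoking", "duration10"))
    got = stepwise_select(df, spec, screen=False)
    assert tuple(sorted(got.terms)) == oracle_stepwise(df, spec)


# --------------------------------------------------------------------------
# Odds-ratio prose conversion
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "odds_ratio,magnitude,direction",
    [(1.54, 54, "increase"), (1.39, 39, "increase"),
     (0.47, 53, "reduction"), (1.96, 96, "increase")],
)
def test_or_percent_change_prose(odds_ratio, magnitude, direction):
    assert describe_odds_ratio(odds_ratio) == (magnitude, direction)


def test_or_percent_change_signed():
    assert odds_ratio_percent_change(1.5) == pytest.approx(50.0)
    assert odds_ratio_percent_change(0.5) == pytest.approx(-50.0)
    with pytest.raises(ValueError):
        odds_ratio_percent_change(0.0)
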