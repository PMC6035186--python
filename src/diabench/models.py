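"""Diabetes-type-stratified risk models for the four health outcomes.

The modelling procedure is the one used for case-mix adjustment in provider
profiling: per diabetes type and outcome, a multivariate stepwise
linear (continuous outcomes) or logistic (severe hypoglycaemia) regression
with forward entry at p < 0.01 and backward removal at p > 0.05, a-priori
forced covariates (fasting status for LDL-cholesterol), and variance-
inflation-factor screening (cut-off 10) of the candidate design before
selection.  Multi-level categorical factors enter and leave as blocks
judged by a joint Wald chi-square test; single terms by the Wald z.

Reported per-term statistics are Wald: normal-based z, two-sided p and 95%
confidence intervals for both families.  Model fit is summarised by
adjusted R-squared (linear) or the area under the ROC curve (logistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .design import TERM_COLUMNS, build_design, required_fields

__all__ = [
    "ModelSpec",
    "FittedRiskModel",
    "FitError",
    "StepwiseError",
    "CollinearityError",
    "spec_for",
    "fit_glm",
    "stepwise_select",
    "screen_collinearity",
    "adjusted_r2",
    "roc_auc",
    "fit_statistic",
    "odds_ratio_percent_change",
    "describe_odds_ratio",
]

DEFAULT_CANDIDATES = (
    "age10",
    "sex",
    "duration10",
    "dcsi_category",
    "bmi_category",
    "country_of_birth",
    "smoking",
)

CONTINUOUS_OUTCOMES = ("hba1c", "ldl_ch", "sbp")


class FitError(RuntimeError):
    """Singular design, separation, or otherwise unfittable model."""


class StepwiseError(RuntimeError):
    """Stepwise selection failed to converge."""


class CollinearityError(ValueError):
    """Degenerate column in the collinearity screen."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one stratum risk model."""

    outcome: str
    diabetes_type: str | None = None
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    forced: tuple[str, ...] = ()
    p_enter: float = 0.01
    p_remove: float = 0.05
    vif_cutoff: float = 10.0
    family_override: str | None = None

    @property
    def family(self) -> str:
        if self.family_override is not None:
            return self.family_override
        return "logistic" if self.outcome == "severe_hypo" else "linear"

    def __post_init__(self):
        if self.p_enter > self.p_remove:
            raise ValueError("p_enter must be <= p_remove")
        pool = set(self.candidates) | {"fasting_at_lipids"}
        if not set(self.forced) <= pool:
            raise ValueError("forced terms must be candidates (or fasting status)")


def spec_for(outcome: str, diabetes_type: str | None = None, **kw) -> ModelSpec:
    """Default spec for an outcome: LDL-Ch carries fasting status as a
    forced covariate; severe hypoglycaemia is logistic."""
    forced: tuple[str, ...] = ()
    candidates = DEFAULT_CANDIDATES
    if outcome == "ldl_ch":
        forced = ("fasting_at_lipids",)
        candidates = DEFAULT_CANDIDATES + ("fasting_at_lipids",)
    return ModelSpec(outcome=outcome, diabetes_type=diabetes_type,
                     candidates=candidates, forced=forced, **kw)


@dataclass
class FittedRiskModel:
    """A fitted (possibly selected) risk model.

    ``table`` has one row per design column with columns
    ``coef, se, z, pvalue, ci_low, ci_high`` and, for logistic models,
    ``odds_ratio, or_ci_low, or_ci_high``.
    """

    spec: ModelSpec
    terms: tuple[str, ...]
    table: pd.DataFrame
    fit_stat: float
    fit_stat_name: str
    n_used: int
    vif_report: pd.DataFrame | None = None
    selection_log: list = field(default_factory=list)
    _result: object = field(default=None, repr=False, compare=False)

    @property
    def params(self) -> pd.Series:
        return self.table["coef"]

    def predict(self, records: pd.DataFrame) -> pd.Series:
        """Expected outcome (linear) or event probability (logistic) for
        rows complete on the model's covariates; NaN elsewhere."""
        fields = required_fields(self.terms)
        ok = records[fields].notna().all(axis=1) if fields else pd.Series(True, index=records.index)
        X = build_design(records.loc[ok], self.terms)[list(self.table.index)]
        lp = X.to_numpy() @ self.params.to_numpy()
        if self.spec.family == "logistic":
            lp = 1.0 / (1.0 + np.exp(-lp))
        out = pd.Series(np.nan, index=records.index, dtype=float)
        out.loc[ok] = lp
        return out


def _complete_cases(records: pd.DataFrame, outcome: str, terms) -> pd.DataFrame:
    fields = required_fields(terms)
    sub = records.dropna(subset=[outcome, *fields])
    return sub


NUMERIC_COLUMNS = {"age10", "duration10"}


def _drop_degenerate(X: pd.DataFrame, terms, exc=FitError) -> pd.DataFrame:
    """Drop dummy columns for category levels absent (or universal) in the
    data; a constant numeric column, or a term losing *all* its columns,
    raises.  Absent levels simply cannot be estimated and are the norm in
    small strata."""
    arr = X.to_numpy(dtype=float)
    keep = []
    for j, c in enumerate(X.columns):
        if c == "intercept" or np.ptp(arr[:, j]) > 0:
            keep.append(c)
        elif c in NUMERIC_COLUMNS:
            raise exc(f"constant column: {c}")
    for t in terms:
        cols = TERM_COLUMNS[t]
        if not any(c in keep for c in cols):
            raise exc(f"term {t!r} has no estimable level in the data")
    return X[keep]


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name a column involved in the dependency: smallest R diagonal in QR
        _, rmat = np.linalg.qr(arr)
        bad = X.columns[int(np.argmin(np.abs(np.diag(rmat))))]
        raise FitError(f"singular design matrix (collinear term involving {bad})")


def _raw_fit(y: np.ndarray, X: pd.DataFrame, family: str):
    if family == "linear":
        return sm.OLS(y, X).fit()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise FitError("logistic fit did not converge")
    return res


def fit_glm(records: pd.DataFrame, outcome: str, terms: Sequence[str],
            family: str | None = None, diabetes_type: str | None = None,
            spec: ModelSpec | None = None) -> FittedRiskModel:
    """Single maximum-likelihood / least-squares fit, complete cases only."""
    terms = tuple(terms)
    if spec is None:
        spec = ModelSpec(outcome=outcome, diabetes_type=diabetes_type,
                         candidates=terms or DEFAULT_CANDIDATES,
                         forced=(), family_override=family)
    fam = family or spec.family
    sub = _complete_cases(records, outcome, terms)
    X = _drop_degenerate(build_design(sub, terms), terms)
    n, p = X.shape
    if n < p + 1:
        raise FitError(f"{n} complete cases insufficient for {p} parameters")
    _check_design(X)
    y = pd.to_numeric(sub[outcome]).to_numpy(dtype=float)
    res = _raw_fit(y, X, fam)

    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = 2 * stats.norm.sf(np.abs(z))
    zc = stats.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "z": z,
            "pvalue": pvals,
            "ci_low": coef - zc * se,
            "ci_high": coef + zc * se,
        },
        index=X.columns,
    )
    if fam == "logistic":
        table["odds_ratio"] = np.exp(table["coef"])
        table["or_ci_low"] = np.exp(table["ci_low"])
        table["or_ci_high"] = np.exp(table["ci_high"])
        fit_stat = roc_auc(y, np.asarray(res.predict(X)))
        fit_name = "roc_auc"
    else:
        fit_stat = adjusted_r2(y, np.asarray(res.predict(X)), p - 1)
        fit_name = "adj_r2"
    return FittedRiskModel(spec=spec, terms=terms, table=table, fit_stat=fit_stat,
                           fit_stat_name=fit_name, n_used=n, _result=res)


# --------------------------------------------------------------------------
# Fit statistics
# --------------------------------------------------------------------------


def adjusted_r2(y: np.ndarray, yhat: np.ndarray, n_predictors: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1); errors when the correction is undefined."""
    y = np.asarray(y, float)
    n = len(y)
    p = int(n_predictors)
    if n <= p + 1:
        raise FitError(f"adjusted R^2 undefined for n={n}, p={p}")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def roc_auc(events: np.ndarray, scores: np.ndarray) -> float:
    """Probability a random event outranks a random non-event (ties = 1/2),
    via the Mann-Whitney rank statistic."""
    y = np.asarray(events, float)
    s = np.asarray(scores, float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise FitError("ROC AUC needs both events and non-events")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def fit_statistic(model: FittedRiskModel, records: pd.DataFrame) -> float:
    """Recompute the model's fit statistic on a set of records."""
    sub = _complete_cases(records, model.spec.outcome, model.terms)
    y = pd.to_numeric(sub[model.spec.outcome]).to_numpy(float)
    yhat = model.predict(sub).to_numpy()
    if model.spec.family == "logistic":
        return roc_auc(y, yhat)
    return adjusted_r2(y, yhat, len(model.table) - 1)


# --------------------------------------------------------------------------
# Joint Wald tests and stepwise selection
# --------------------------------------------------------------------------


def _joint_wald_p(res, X_columns, block_cols) -> float:
    """Wald chi-square p-value that all coefficients of a block are zero."""
    idx = [list(X_columns).index(c) for c in block_cols]
    theta = np.asarray(res.params, float)[idx]
    cov = np.asarray(res.cov_params(), float)[np.ix_(idx, idx)]
    try:
        w = float(theta @ np.linalg.solve(cov, theta))
    except np.linalg.LinAlgError:
        return 1.0
    return float(stats.chi2.sf(w, len(idx)))


def _fit_terms(sub: pd.DataFrame, outcome: str, terms, family: str):
    X = _drop_degenerate(build_design(sub, terms), terms)
    y = pd.to_numeric(sub[outcome]).to_numpy(float)
    return _raw_fit(y, X, family), X


def stepwise_select(records: pd.DataFrame, spec: ModelSpec,
                    screen: bool = True, max_iter: int = 50) -> FittedRiskModel:
    """Forward-stepwise selection with backward pruning.

    Complete cases are taken once over the outcome and *all* candidate
    fields, so p-values are comparable across steps.  Each cycle enters the
    most significant absent candidate if its joint Wald p < ``p_enter``
    (ties go to the earlier candidate), then repeatedly removes the least
    significant retained non-forced term while its p > ``p_remove``.
    Forced terms are present from the start and never removed.
    """
    candidates = [t for t in spec.candidates if t not in spec.forced]
    sub = _complete_cases(records, spec.outcome, spec.candidates + spec.forced)
    vif_report = None
    if screen and len(spec.candidates) >= 2:
        kept, vif_report = screen_collinearity(
            sub, spec.outcome, list(spec.candidates), family=spec.family,
            cutoff=spec.vif_cutoff, protected=spec.forced,
        )
        candidates = [t for t in candidates if t in kept]

    current: list[str] = list(spec.forced)
    log: list[tuple] = []
    history: set[tuple] = set()
    for it in range(max_iter):
        changed = False
        # forward entry
        best_term, best_p = None, np.inf
        for t in candidates:
            if t in current:
                continue
            trial = current + [t]
            try:
                res, X = _fit_terms(sub, spec.outcome, trial, spec.family)
            except FitError:
                continue
            block = [c for c in TERM_COLUMNS[t] if c in X.columns]
            p = _joint_wald_p(res, X.columns, block)
            if p < best_p - 1e-15:
                best_term, best_p = t, p
        if best_term is not None and best_p < spec.p_enter:
            current.append(best_term)
            log.append(("enter", best_term, best_p))
            changed = True
        # backward pruning
        while True:
            removable = [t for t in current if t not in spec.forced]
            if not removable:
                break
            res, X = _fit_terms(sub, spec.outcome, current, spec.family)
            worst_term, worst_p = None, -np.inf
            for t in removable:
                block = [c for c in TERM_COLUMNS[t] if c in X.columns]
                p = _joint_wald_p(res, X.columns, block)
                if p > worst_p + 1e-15 or worst_term is None:
                    worst_term, worst_p = t, p
            if worst_p > spec.p_remove:
                current.remove(worst_term)
                log.append(("remove", worst_term, worst_p))
                changed = True
            else:
                break
        state = tuple(sorted(current))
        if not changed:
            break
        if state in history:
            raise StepwiseError(
                f"selection oscillates among terms {sorted(set(t for _, t, _ in log[-4:]))}"
            )
        history.add(state)
    else:
        raise StepwiseError(
            f"no convergence after {max_iter} cycles; recent terms "
            f"{sorted(set(t for _, t, _ in log[-6:]))}"
        )

    # keep candidate order in the final model for reproducible reporting
    order = list(spec.forced) + [t for t in spec.candidates if t in current and t not in spec.forced]
    model = fit_glm(sub, spec.outcome, order, family=spec.family, spec=spec)
    model.vif_report = vif_report
    model.selection_log = log
    return model


# --------------------------------------------------------------------------
# Collinearity screening
# --------------------------------------------------------------------------


def _column_vifs(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1 - R^2) of column j regressed on the others (+ intercept)."""
    arr = X.to_numpy(float)
    n, p = arr.shape
    vifs = {}
    ones = np.ones((n, 1))
    for j, col in enumerate(X.columns):
        yj = arr[:, j]
        others = np.hstack([ones, np.delete(arr, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0:
            raise CollinearityError(f"constant column: {col}")
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        vifs[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs)


def screen_collinearity(records: pd.DataFrame, outcome: str, terms: Sequence[str],
                        family: str = "linear", cutoff: float = 10.0,
                        protected: Sequence[str] = ()) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop collinear terms (VIF above ``cutoff``).

    A term's VIF is the maximum over its design columns.  While any
    unprotected term exceeds the cut-off, the offender with the smaller
    maximum Wald ``|z|`` in an outcome fit on the current terms is removed
    (ties drop the later term in the given order).  Returns the retained
    terms and a report of drops with their VIF and |z|.
    """
    current = list(terms)
    drops = []
    while True:
        sub = _complete_cases(records, outcome, current)
        X = build_design(sub, current, intercept=False)
        # absent category levels are not collinearity: drop their all-zero
        # dummies; a constant numeric column is a data error
        arr = X.to_numpy(float)
        keep = []
        for j, c in enumerate(X.columns):
            if np.ptp(arr[:, j]) > 0:
                keep.append(c)
            elif c in NUMERIC_COLUMNS:
                raise CollinearityError(f"constant column: {c}")
        X = X[keep]
        if X.shape[1] < 2:
            break
        vifs = _column_vifs(X)
        term_vif = {
            t: float(vifs[[c for c in TERM_COLUMNS[t] if c in vifs.index]].max())
            if any(c in vifs.index for c in TERM_COLUMNS[t]) else 1.0
            for t in current
        }
        offenders = [t for t in current if term_vif[t] > cutoff and t not in protected]
        if not offenders:
            break
        # |z| from an outcome fit on all current terms (pinv handles exact
        # collinearity; duplicated columns then tie on |z|)
        y = pd.to_numeric(sub[outcome]).to_numpy(float)
        Xi = _drop_degenerate(build_design(sub, current), current, CollinearityError)
        if family == "linear":
            res = sm.OLS(y, Xi).fit()
        else:
            try:
                res = _raw_fit(y, Xi, family)
            except FitError:
                res = sm.OLS(y, Xi).fit()  # fallback ranking when MLE breaks down
        with np.errstate(divide="ignore", invalid="ignore"):
            zvals = pd.Series(np.abs(np.asarray(res.params) / np.asarray(res.bse)),
                              index=Xi.columns).fillna(0.0)
        term_z = {
            t: float(zvals[[c for c in TERM_COLUMNS[t] if c in zvals.index]].max())
            for t in offenders
        }
        min_z = min(term_z.values())
        # smaller |z| goes; ties broken towards the later term in order
        victims = [t for t in offenders if term_z[t] <= min_z + 1e-12]
        victim = victims[-1]
        drops.append({"term": victim, "vif": term_vif[victim], "abs_z": term_z[victim]})
        current.remove(victim)
    report = pd.DataFrame(drops, columns=["term", "vif", "abs_z"])
    return current, report


# --------------------------------------------------------------------------
# Odds-ratio reporting
# --------------------------------------------------------------------------


def odds_ratio_percent_change(odds_ratio: float) -> float:
    """Signed percent change in odds: (OR - 1) * 100."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    return (odds_ratio - 1.0) * 100.0


def describe_odds_ratio(odds_ratio: float) -> tuple[int, str]:
    """Prose-style magnitude and direction: OR 1.54 -> (54, 'increase'),
    OR 0.47 -> (53, 'reduction')."""
    change = odds_ratio_percent_change(odds_ratio)
    if change >= 0:
        return int(round(change)), "increase"
    return int(round(-change)), "reduction"
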