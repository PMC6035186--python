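"""Robustness analyses around the risk models.

Three re-runnable wrappers:

* Tukey-fence exclusion of extreme outcome values followed by a refit,
  with a report of terms gained or lost;
* multiple imputation of numeric variables under a multivariate-normal
  model (data-augmentation MCMC) with Rubin's rules for pooling the
  per-dataset fits;
* stratified refits by treatment status (on insulin vs not) with a report
  of coefficient sign flips against the pooled model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.imputation.bayes_mi import BayesGaussMI

from .models import FitError, FittedRiskModel, ModelSpec, fit_glm, stepwise_select
from .design import CATEGORY_LEVELS, required_fields

__all__ = [
    "tukey_fences",
    "refit_without_outliers",
    "impute_mvn",
    "rubin_pool",
    "pool_models",
    "stratified_refit",
    "ImputationSet",
    "PooledEstimate",
    "RefitError",
]


class RefitError(RuntimeError):
    """Outlier exclusion left the design unfittable."""


# --------------------------------------------------------------------------
# Tukey fences
# --------------------------------------------------------------------------


def tukey_fences(values, k: float = 1.5) -> tuple[float, float, np.ndarray]:
    """Quartile fences ``(Q1 - k*IQR, Q3 + k*IQR)`` and the inlier mask.

    Quartiles use linear interpolation between order statistics (the numpy
    default).  The mask is True where ``lower <= value <= upper``; missing
    values are False in the mask but do not affect the fences.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    v = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), dtype=float)
    obs = v[~np.isnan(v)]
    if obs.size == 0:
        raise ValueError("all values missing")
    if obs.size < 4:
        raise ValueError(f"need >= 4 non-missing values, got {obs.size}")
    q1, q3 = np.quantile(obs, [0.25, 0.75])
    iqr = q3 - q1
    lower, upper = q1 - k * iqr, q3 + k * iqr
    with np.errstate(invalid="ignore"):
        mask = (v >= lower) & (v <= upper)
    return float(lower), float(upper), mask


def refit_without_outliers(records: pd.DataFrame, spec: ModelSpec,
                           k: float = 1.5) -> tuple[FittedRiskModel, dict]:
    """Refit after excluding Tukey-fence outliers of the outcome variable.

    Returns the outlier-excluded model and a comparison report against the
    full-data model: fences, exclusion count, and terms gained/lost.
    Raises :class:`RefitError` naming the level if exclusion empties a
    categorical level that the full-data complete cases contained.
    """
    if spec.family != "linear":
        raise ValueError("outlier exclusion applies to continuous outcomes")
    original = stepwise_select(records, spec)
    lower, upper, mask = tukey_fences(records[spec.outcome], k=k)
    kept = records[mask]
    # emptied-level check over fields the candidate set uses
    full_cc = records.dropna(subset=[spec.outcome, *required_fields(spec.candidates + spec.forced)])
    kept_cc = kept.dropna(subset=[spec.outcome, *required_fields(spec.candidates + spec.forced)])
    for fld in required_fields(spec.candidates + spec.forced):
        if fld not in CATEGORY_LEVELS:
            continue
        before = set(full_cc[fld].dropna().unique())
        after = set(kept_cc[fld].dropna().unique())
        emptied = before - after
        if emptied:
            raise RefitError(
                f"outlier exclusion emptied {fld} level {sorted(emptied)[0]!r}"
            )
    excluded_model = stepwise_select(kept, spec)
    report = {
        "fences": (lower, upper),
        "n_excluded": int(len(records.dropna(subset=[spec.outcome])) - mask.sum()),
        "terms_lost": [t for t in original.terms if t not in excluded_model.terms],
        "terms_gained": [t for t in excluded_model.terms if t not in original.terms],
    }
    return excluded_model, report


# --------------------------------------------------------------------------
# Multiple imputation (multivariate normal, data-augmentation MCMC)
# --------------------------------------------------------------------------


@dataclass
class ImputationSet:
    """m completed copies of the records; observed cells are untouched."""

    m: int
    datasets: list[pd.DataFrame]
    fields: list[str]
    rng_seed: int
    burn_in: int
    thin: int


def impute_mvn(records: pd.DataFrame, fields, m: int = 10, seed: int = 0,
               burn_in: int = 200, thin: int = 50) -> ImputationSet:
    """Impute missing numeric cells under a joint Gaussian model.

    A Gibbs data-augmentation chain alternates drawing the missing cells
    from their conditional normals with drawing the mean and covariance;
    ``m`` completed datasets are taken every ``thin`` iterations after
    ``burn_in``.  Include fully (or nearly fully) observed predictor
    columns in ``fields`` to inform the imputations.
    """
    fields = list(fields)
    if m < 1:
        raise ValueError("m must be >= 1")
    block = records[fields].apply(pd.to_numeric, errors="raise").astype(float)
    if not block.isna().any().any():
        return ImputationSet(m, [records.copy() for _ in range(m)], fields, seed, burn_in, thin)
    if block.dropna(how="any").shape[0] < len(fields) + 1:
        raise ValueError("too few complete rows to anchor the working covariance")

    state = np.random.get_state()
    datasets: list[pd.DataFrame] = []
    try:
        np.random.seed(seed % (2**32))
        try:
            mi = BayesGaussMI(block.to_numpy().copy())
            for _ in range(burn_in):
                mi.update()
            while len(datasets) < m:
                for _ in range(thin):
                    mi.update()
                completed = records.copy()
                filled = pd.DataFrame(mi.data, columns=fields, index=records.index) \
                    if not isinstance(mi.data, pd.DataFrame) \
                    else mi.data.set_axis(records.index, axis=0)
                for f in fields:
                    col = block[f]
                    out = col.copy()
                    out[col.isna()] = filled[f][col.isna().to_numpy()]
                    completed[f] = out
                datasets.append(completed)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                "working covariance not positive definite; consider dropping "
                "near-constant fields or adding a small ridge to the data"
            ) from exc
    finally:
        np.random.set_state(state)
    return ImputationSet(m, datasets, fields, seed, burn_in, thin)


# --------------------------------------------------------------------------
# Rubin's rules
# --------------------------------------------------------------------------


@dataclass
class PooledEstimate:
    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Combine per-dataset estimates: mean, within + (1 + 1/m) * between
    variance, and the standard small-sample degrees of freedom."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-D")
    mm = len(q)
    if mm < 2:
        raise ValueError("need m >= 2 datasets to pool")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / mm) * b
    if b > 0:
        df = (mm - 1) * (1.0 + w / ((1.0 + 1.0 / mm) * b)) ** 2
    else:
        df = np.inf
    return PooledEstimate(qbar, w, b, t, float(df))


def pool_models(models: list[FittedRiskModel]) -> pd.DataFrame:
    """Rubin-pool coefficient tables of models fitted to the m completed
    datasets; all models must share the same term set."""
    term_sets = {tuple(m.table.index) for m in models}
    if len(term_sets) != 1:
        raise ValueError(f"mismatched term sets across imputed datasets: {term_sets}")
    rows = {}
    for name in models[0].table.index:
        est = [m.table.loc[name, "coef"] for m in models]
        var = [m.table.loc[name, "se"] ** 2 for m in models]
        p = rubin_pool(est, var)
        rows[name] = {
            "coef": p.estimate, "se": p.se, "within_var": p.within_var,
            "between_var": p.between_var, "total_var": p.total_var, "df": p.df,
        }
    return pd.DataFrame(rows).T


# --------------------------------------------------------------------------
# Treatment-stratified refits
# --------------------------------------------------------------------------


def stratified_refit(records: pd.DataFrame, spec: ModelSpec,
                     stratifier: str = "on_insulin") -> tuple[dict, pd.DataFrame]:
    """Rerun selection within each stratum of ``stratifier``.

    Returns ``(models, flips)`` where ``models`` maps stratum value to its
    :class:`FittedRiskModel` (strata too small to fit are skipped with a
    warning) and ``flips`` lists design columns whose coefficient sign
    differs from the pooled-data model.
    """
    strata = records[stratifier].dropna().unique()
    if len(strata) < 2:
        raise ValueError(f"need both strata of {stratifier} non-empty")
    pooled = stepwise_select(records, spec)
    models: dict = {}
    flip_rows = []
    for value in sorted(strata, key=str):
        sub = records[records[stratifier] == value]
        try:
            model = stepwise_select(sub, spec)
        except (FitError, ValueError) as exc:
            warnings.warn(f"stratum {stratifier}={value} skipped: {exc}")
            continue
        models[value] = model
        shared = [c for c in model.table.index
                  if c in pooled.table.index and c != "intercept"]
        for c in shared:
            a, b = pooled.table.loc[c, "coef"], model.table.loc[c, "coef"]
            if a * b < 0:
                flip_rows.append({"stratum": value, "column": c,
                                  "pooled_coef": a, "stratum_coef": b})
    flips = pd.DataFrame(flip_rows, columns=["stratum", "column", "pooled_coef", "stratum_coef"])
    return models, flips
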