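"""Design-matrix construction shared by the cohort generator and the risk models.

Covariates enter the risk models as *terms*.  A term is either a single
numeric column (age and disease duration, both rescaled to decades so that
coefficients read "per 10 years") or a block of treatment-coded dummy
columns for a categorical factor.  Reference levels follow the audit
convention: male sex, Australian-born, never-smoker, DCSI score 0, healthy
BMI, non-fasting lipid draw.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Category level orderings (reference level first).
SEX_LEVELS = ["male", "female"]
COUNTRY_LEVELS = ["Australia", "overseas"]
BMI_LEVELS = ["healthy", "underweight", "overweight", "obese", "morbidly_obese"]
DCSI_LEVELS = ["0", "1-2", "3-4", "5+"]
SMOKING_LEVELS = ["never", "ever"]

CATEGORY_LEVELS = {
    "sex": SEX_LEVELS,
    "country_of_birth": COUNTRY_LEVELS,
    "bmi_category": BMI_LEVELS,
    "dcsi_category": DCSI_LEVELS,
    "smoking": SMOKING_LEVELS,
}

#: term name -> design column names it expands to
TERM_COLUMNS: dict[str, tuple[str, ...]] = {
    "age10": ("age10",),
    "duration10": ("duration10",),
    "sex": ("sex_female",),
    "country_of_birth": ("country_overseas",),
    "smoking": ("smoking_ever",),
    "bmi_category": (
        "bmi_underweight",
        "bmi_overweight",
        "bmi_obese",
        "bmi_morbidly_obese",
    ),
    "dcsi_category": ("dcsi_1-2", "dcsi_3-4", "dcsi_5+"),
    "fasting_at_lipids": ("fasting",),
    "on_insulin": ("insulin",),
}

#: term name -> patient-record fields it reads
TERM_FIELDS: dict[str, tuple[str, ...]] = {
    "age10": ("age",),
    "duration10": ("duration",),
    "sex": ("sex",),
    "country_of_birth": ("country_of_birth",),
    "smoking": ("smoking",),
    "bmi_category": ("bmi_category",),
    "dcsi_category": ("dcsi_category",),
    "fasting_at_lipids": ("fasting_at_lipids",),
    "on_insulin": ("on_insulin",),
}

#: every design column any term can produce
ALL_COLUMNS = tuple(c for cols in TERM_COLUMNS.values() for c in cols)


class DesignError(ValueError):
    """Raised for unknown terms or malformed covariate values."""


def required_fields(terms) -> list[str]:
    """Patient-record fields needed to build the given terms."""
    fields: list[str] = []
    for t in terms:
        if t not in TERM_FIELDS:
            raise DesignError(f"unknown model term: {t!r}")
        for f in TERM_FIELDS[t]:
            if f not in fields:
                fields.append(f)
    return fields


def _dummy(series: pd.Series, level: str, field: str) -> np.ndarray:
    values = series.to_numpy()
    known = CATEGORY_LEVELS[field]
    bad = ~np.isin(values, known)
    if bad.any():
        first = values[np.argmax(bad)]
        raise DesignError(f"unknown {field} level: {first!r}")
    return (values == level).astype(float)


def term_matrix(records: pd.DataFrame, term: str) -> pd.DataFrame:
    """Expand one term into its design column(s) for the given records."""
    if term == "age10":
        data = {"age10": records["age"].to_numpy(dtype=float) / 10.0}
    elif term == "duration10":
        data = {"duration10": records["duration"].to_numpy(dtype=float) / 10.0}
    elif term == "sex":
        data = {"sex_female": _dummy(records["sex"], "female", "sex")}
    elif term == "country_of_birth":
        data = {"country_overseas": _dummy(records["country_of_birth"], "overseas", "country_of_birth")}
    elif term == "smoking":
        data = {"smoking_ever": _dummy(records["smoking"], "ever", "smoking")}
    elif term == "bmi_category":
        data = {
            f"bmi_{lvl}": _dummy(records["bmi_category"], lvl, "bmi_category")
            for lvl in BMI_LEVELS
            if lvl != "healthy"
        }
    elif term == "dcsi_category":
        data = {
            f"dcsi_{lvl}": _dummy(records["dcsi_category"], lvl, "dcsi_category")
            for lvl in DCSI_LEVELS
            if lvl != "0"
        }
    elif term == "fasting_at_lipids":
        data = {"fasting": records["fasting_at_lipids"].to_numpy(dtype=float)}
    elif term == "on_insulin":
        data = {"insulin": records["on_insulin"].to_numpy(dtype=float)}
    else:
        raise DesignError(f"unknown model term: {term!r}")
    return pd.DataFrame(data, index=records.index)


def build_design(records: pd.DataFrame, terms, intercept: bool = True) -> pd.DataFrame:
    """Assemble the design matrix for an ordered collection of terms.

    Rows are assumed complete for every field the terms read; use
    :func:`required_fields` with ``DataFrame.dropna`` beforehand.
    """
    parts = []
    if intercept:
        parts.append(pd.DataFrame({"intercept": np.ones(len(records))}, index=records.index))
    for t in terms:
        parts.append(term_matrix(records, t))
    if not parts:
        return pd.DataFrame(index=records.index)
    return pd.concat(parts, axis=1)


def linear_predictor(records: pd.DataFrame, coefficients: dict[str, float]) -> np.ndarray:
    """Evaluate ``intercept + sum(coef * column)`` over the records.

    ``coefficients`` is keyed by design column name (plus optional
    ``"intercept"``); unknown keys raise :class:`DesignError` naming the
    offending term.
    """
    lp = np.full(len(records), float(coefficients.get("intercept", 0.0)))
    col_to_term = {c: t for t, cols in TERM_COLUMNS.items() for c in cols}
    cache: dict[str, pd.DataFrame] = {}
    for name, coef in coefficients.items():
        if name == "intercept":
            continue
        if name not in col_to_term:
            raise DesignError(f"coefficient refers to unknown covariate: {name!r}")
        term = col_to_term[name]
        if term not in cache:
            cache[term] = term_matrix(records, term)
        lp += float(coef) * cache[term][name].to_numpy()
    return lp
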