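"""Funnel-plot benchmarking of centre performance, before and after
risk adjustment.

Each centre's performance measure is the mean outcome level (HbA1c %,
LDL-Ch mmol/L, SBP mmHg) or the severe-hypoglycaemia rate per 100
patients.  Measures are plotted against centre sample size with control
limits at the pooled value plus/minus z * SE(n): 95% inner limits
(z = 1.96) and 99.8% outer limits, taken as three standard deviations
(z = 3).  A centre strictly above the upper outer limit is a
low-performing outlier (higher levels and rates are worse), strictly
below the lower outer limit a high-performing outlier; values exactly on
a limit are inliers.

Risk adjustment:

* continuous outcomes — residual adjustment, ``observed - expected +
  grand mean``; the stratum mean is preserved exactly;
* event rates — indirect standardisation, ``(observed events / expected
  events) * overall rate``; with model-based expected events summing to
  the observed total, the pooled rate is preserved.

Comparing the unadjusted with the adjusted classification yields the
false-positive / false-negative accounting: an unadjusted outlier that
becomes an inlier after adjustment is a false positive; an unadjusted
inlier that becomes an outlier is a false negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import FittedRiskModel

__all__ = [
    "risk_adjust_continuous",
    "risk_adjust_rate",
    "centre_measures",
    "FunnelLimits",
    "funnel_limits",
    "classify",
    "classify_centres",
    "compare_classifications",
    "reclassification_summary",
    "misclassification_rate",
    "funnel_plot",
    "INLIER",
    "LOW_PERFORMING",
    "HIGH_PERFORMING",
]

INLIER = "inlier"
LOW_PERFORMING = "low_performing_outlier"
HIGH_PERFORMING = "high_performing_outlier"


# --------------------------------------------------------------------------
# Risk adjustment
# --------------------------------------------------------------------------


def risk_adjust_continuous(records: pd.DataFrame, model: FittedRiskModel,
                           outcome: str | None = None) -> tuple[pd.Series, dict]:
    """Residual-adjusted values: ``observed - expected + grand mean``.

    Rows missing the outcome or any model covariate are NaN in the result
    and counted in the coverage report.  The mean of the adjusted values
    equals the mean of the observed values over the covered rows.
    """
    outcome = outcome or model.spec.outcome
    y = pd.to_numeric(records[outcome], errors="coerce")
    expected = model.predict(records)
    ok = y.notna() & expected.notna()
    grand = float(y[ok].mean())
    adjusted = pd.Series(np.nan, index=records.index, dtype=float)
    adjusted[ok] = y[ok] - expected[ok] + grand
    coverage = {"n_used": int(ok.sum()), "n_excluded": int(len(records) - ok.sum())}
    return adjusted, coverage


def risk_adjust_rate(observed_events: float, expected_events: float,
                     overall_rate: float) -> float:
    """Indirectly standardised rate per 100: ``(O / E) * overall_rate * 100``.

    ``overall_rate`` is the pooled event proportion.  A centre with
    expected = 0 but observed > 0 cannot be standardised: NaN with a
    warning, to be excluded from classification.
    """
    if expected_events <= 0:
        if observed_events > 0:
            warnings.warn("expected events = 0 with observed > 0; centre excluded")
            return float("nan")
        return 0.0
    return float(observed_events / expected_events * overall_rate * 100.0)


# --------------------------------------------------------------------------
# Centre performance measures
# --------------------------------------------------------------------------


def centre_measures(values, centre_ids, kind: str, adjusted: bool = False) -> pd.DataFrame:
    """Per-centre performance: mean level (continuous) or events per 100
    patients (rate).  Missing values drop out of that centre's n."""
    if kind not in ("continuous", "rate"):
        raise ValueError("kind must be 'continuous' or 'rate'")
    df = pd.DataFrame({
        "centre_id": np.asarray(centre_ids, dtype=object),
        "value": pd.to_numeric(pd.Series(values).reset_index(drop=True), errors="coerce"),
    }).dropna(subset=["value"])
    grouped = df.groupby("centre_id")["value"]
    if kind == "continuous":
        measure = grouped.mean()
    else:
        measure = 100.0 * grouped.mean()  # mean of 0/1 flags = event proportion
    out = pd.DataFrame({
        "centre_id": measure.index,
        "n": grouped.size().to_numpy(),
        "measure": measure.to_numpy(),
    }).reset_index(drop=True)
    out["adjusted"] = adjusted
    return out


# --------------------------------------------------------------------------
# Funnel limits
# --------------------------------------------------------------------------


@dataclass
class FunnelLimits:
    """Control-limit curves as a function of centre size.

    ``grand`` is on the measure scale (mean level, or rate per 100);
    ``dispersion`` is the patient-level SD for continuous measures or the
    pooled event proportion for rates.
    """

    kind: str
    grand: float
    dispersion: float
    z_inner: float = 1.96
    z_outer: float = 3.0
    degenerate: bool = False

    def interval(self, n, z: float) -> tuple[np.ndarray, np.ndarray]:
        n = np.asarray(n, dtype=float)
        if self.kind == "continuous":
            half = z * self.dispersion / np.sqrt(n)
            return self.grand - half, self.grand + half
        p = self.dispersion
        half = z * np.sqrt(p * (1.0 - p) / n) * 100.0
        lo = np.clip(self.grand - half, 0.0, 100.0)
        hi = np.clip(self.grand + half, 0.0, 100.0)
        return lo, hi

    def curve(self, ns) -> pd.DataFrame:
        ns = np.asarray(ns)
        ilo, ihi = self.interval(ns, self.z_inner)
        olo, ohi = self.interval(ns, self.z_outer)
        return pd.DataFrame({
            "n": ns, "inner_low": ilo, "inner_high": ihi,
            "outer_low": olo, "outer_high": ohi,
        })


def funnel_limits(performances: pd.DataFrame, kind: str,
                  patient_values=None, z_inner: float = 1.96,
                  z_outer: float = 3.0) -> FunnelLimits:
    """Build control limits from centre performances.

    Continuous measures need the patient-level values (``patient_values``)
    for the pooled SD; the grand value is the patient-weighted mean.  Rate
    measures derive the pooled proportion from the centre rates and sizes.
    """
    if len(performances) < 2:
        raise ValueError("need >= 2 centres for funnel limits")
    n = performances["n"].to_numpy(dtype=float)
    m = performances["measure"].to_numpy(dtype=float)
    keep = ~np.isnan(m)
    n, m = n[keep], m[keep]
    if kind == "continuous":
        if patient_values is None:
            raise ValueError("patient_values required for continuous limits")
        v = pd.to_numeric(pd.Series(patient_values), errors="coerce").dropna().to_numpy()
        grand = float((n * m).sum() / n.sum())
        sigma = float(np.std(v, ddof=1))
        degenerate = sigma == 0.0
    elif kind == "rate":
        p = float((n * m / 100.0).sum() / n.sum())
        grand = 100.0 * p
        sigma = p
        degenerate = p in (0.0, 1.0)
    else:
        raise ValueError("kind must be 'continuous' or 'rate'")
    if degenerate:
        warnings.warn("zero dispersion: funnel limits degenerate at the grand value")
    return FunnelLimits(kind=kind, grand=grand, dispersion=sigma,
                        z_inner=z_inner, z_outer=z_outer, degenerate=degenerate)


# --------------------------------------------------------------------------
# Classification and reclassification accounting
# --------------------------------------------------------------------------


def classify(measure: float, n: float, limits: FunnelLimits) -> str:
    """Status against the outer limits; exactly-on-limit counts as inlier."""
    if np.isnan(measure):
        return INLIER
    lo, hi = limits.interval(n, limits.z_outer)
    if measure > hi:
        return LOW_PERFORMING
    if measure < lo:
        return HIGH_PERFORMING
    return INLIER


def classify_centres(performances: pd.DataFrame, limits: FunnelLimits) -> pd.DataFrame:
    out = performances.copy()
    out["status"] = [
        classify(m, n, limits) for m, n in zip(out["measure"], out["n"])
    ]
    return out


def compare_classifications(unadjusted: pd.Series, adjusted: pd.Series) -> dict:
    """Transition counts between the unadjusted and adjusted statuses.

    Both inputs are centre-indexed; a centre present in only one raises.
    Every centre lands in exactly one transition cell.
    """
    if set(unadjusted.index) != set(adjusted.index):
        only = set(unadjusted.index) ^ set(adjusted.index)
        raise ValueError(f"centres present in one classification only: {sorted(only)}")
    adj = adjusted.reindex(unadjusted.index)
    total_low = int((unadjusted == LOW_PERFORMING).sum())
    total_high = int((unadjusted == HIGH_PERFORMING).sum())
    fp_low = int(((unadjusted == LOW_PERFORMING) & (adj == INLIER)).sum())
    fp_high = int(((unadjusted == HIGH_PERFORMING) & (adj == INLIER)).sum())
    fn_low = int(((unadjusted == INLIER) & (adj == LOW_PERFORMING)).sum())
    fn_high = int(((unadjusted == INLIER) & (adj == HIGH_PERFORMING)).sum())
    return {
        "total_low": total_low, "fp_low": fp_low, "fn_low": fn_low,
        "total_high": total_high, "fp_high": fp_high, "fn_high": fn_high,
        "n_centres": int(len(unadjusted)),
    }


def misclassification_rate(false_positives: int, total_outliers: int):
    """Percent of unadjusted outliers that were false positives.

    Returns ``(raw, rounded)``; ``(nan, None)`` when there were no
    unadjusted outliers (reported as not-applicable).
    """
    if false_positives < 0 or total_outliers < 0:
        raise ValueError("counts must be non-negative")
    if false_positives > total_outliers:
        raise ValueError("false positives cannot exceed total outliers")
    if total_outliers == 0:
        return float("nan"), None
    raw = 100.0 * false_positives / total_outliers
    return raw, int(round(raw))


def reclassification_summary(strata: dict) -> pd.DataFrame:
    """Table of outlier reclassification per stratum plus an overall row.

    ``strata`` maps a label (e.g. ``("t2dm", "hba1c")``) to the dict
    returned by :func:`compare_classifications`.
    """
    rows = []
    tot = {k: 0 for k in ("total_low", "fp_low", "fn_low", "total_high", "fp_high", "fn_high")}
    for label, c in strata.items():
        for k in tot:
            tot[k] += c[k]
        _, r_low = misclassification_rate(c["fp_low"], c["total_low"])
        _, r_high = misclassification_rate(c["fp_high"], c["total_high"])
        lbl = label if isinstance(label, tuple) else (label,)
        rows.append({
            "stratum": " / ".join(str(x) for x in lbl),
            **c, "fp_low_pct": r_low, "fp_high_pct": r_high,
        })
    _, r_low = misclassification_rate(tot["fp_low"], tot["total_low"])
    _, r_high = misclassification_rate(tot["fp_high"], tot["total_high"])
    rows.append({"stratum": "overall", **tot, "n_centres": np.nan,
                 "fp_low_pct": r_low, "fp_high_pct": r_high})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Plotting
# --------------------------------------------------------------------------


def funnel_plot(performances: pd.DataFrame, limits: FunnelLimits,
                ax=None, title: str | None = None, ylabel: str | None = None):
    """Render a funnel plot: centre points, centre line, inner (95%) and
    outer (99.8%/3SD) limit curves."""
    import matplotlib
    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ns = np.linspace(max(performances["n"].min() * 0.8, 1), performances["n"].max() * 1.1, 200)
    curve = limits.curve(ns)
    ax.plot(ns, curve["inner_low"], "--", color="grey", lw=1, label="95% limits")
    ax.plot(ns, curve["inner_high"], "--", color="grey", lw=1)
    ax.plot(ns, curve["outer_low"], "-", color="black", lw=1, label="99.8% (3SD) limits")
    ax.plot(ns, curve["outer_high"], "-", color="black", lw=1)
    ax.axhline(limits.grand, color="steelblue", lw=1, label="pooled value")
    flagged = classify_centres(performances, limits)
    colours = flagged["status"].map({
        INLIER: "steelblue", LOW_PERFORMING: "crimson", HIGH_PERFORMING: "seagreen",
    })
    ax.scatter(flagged["n"], flagged["measure"], c=colours, s=18, zorder=3)
    ax.set_xlabel("centre sample size (n)")
    if ylabel:
        ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, loc="best")
    return ax
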