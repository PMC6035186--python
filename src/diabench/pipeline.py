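"""End-to-end orchestration: simulate -> fit -> (sensitivity) -> benchmark -> report.

A run produces, under ``outdir``:

* ``cohort.csv`` — the generated (or loaded) patient records;
* ``table1_summary.csv`` — audit-style population summary;
* ``risk_models.csv`` — coefficient tables of the stratum models
  (one per diabetes type x outcome, eight under the default config);
* ``funnel_<type>_<outcome>.csv`` — per-centre measures, limits and
  status for the unadjusted and adjusted funnels;
* ``funnel_<type>_<outcome>.png`` — the paired funnel plots (optional);
* ``reclassification.csv`` / ``.txt`` — the false-positive/negative
  accounting per stratum and overall;
* ``manifest.json`` — seed, config snapshot, stage record counts and
  output paths; re-running with the same manifest reproduces all outputs.

Every random stage consumes a seed derived deterministically from the
single top-level seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .benchmarking import (
    centre_measures,
    classify_centres,
    compare_classifications,
    funnel_limits,
    funnel_plot,
    reclassification_summary,
    risk_adjust_continuous,
    risk_adjust_rate,
)
from .cohort import (
    CohortConfig,
    default_config,
    generate_cohort,
    summarise_cohort,
    table1_frame,
)
from .models import FittedRiskModel, spec_for, stepwise_select
from .sensitivity import impute_mvn, pool_models, refit_without_outliers, stratified_refit

__all__ = ["RunManifest", "PipelineError", "run_pipeline", "fit_all_models", "benchmark_stratum"]

CONTINUOUS = ("hba1c", "ldl_ch", "sbp")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and seed."""


@dataclass
class RunManifest:
    seed: int
    version: str
    config: dict
    counts: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _stage(name: str, seed: int):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed (seed {seed}): {exc}") from exc
    return _Ctx()


def fit_all_models(records: pd.DataFrame, diabetes_types=("t2dm", "t1dm"),
                   outcomes=("hba1c", "ldl_ch", "sbp", "severe_hypo"),
                   ) -> dict[tuple[str, str], FittedRiskModel]:
    """Stepwise-selected risk model per (diabetes type, outcome) stratum."""
    models = {}
    for dt in diabetes_types:
        sub = records[records["diabetes_type"] == dt]
        for oc in outcomes:
            models[(dt, oc)] = stepwise_select(sub, spec_for(oc, dt))
    return models


def models_frame(models: dict) -> pd.DataFrame:
    rows = []
    for (dt, oc), m in models.items():
        t = m.table.reset_index(names="column")
        t.insert(0, "outcome", oc)
        t.insert(0, "diabetes_type", dt)
        t["fit_stat"] = m.fit_stat
        t["fit_stat_name"] = m.fit_stat_name
        t["n_used"] = m.n_used
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


def benchmark_stratum(records: pd.DataFrame, model: FittedRiskModel,
                      z_inner: float = 1.96, z_outer: float = 3.0,
                      min_centre_n: int | None = None) -> dict:
    """Unadjusted and adjusted funnel for one (type, outcome) stratum.

    Returns the classified performance frames, both limit objects, and the
    transition counts.  Adjusted limits recompute dispersion from the
    adjusted values.
    """
    oc = model.spec.outcome
    sub = records
    if min_centre_n:
        sizes = sub.groupby("centre_id").size()
        sub = sub[sub["centre_id"].isin(sizes[sizes >= min_centre_n].index)]
    kind = "rate" if oc == "severe_hypo" else "continuous"
    y = pd.to_numeric(sub[oc], errors="coerce")

    unadj = centre_measures(y, sub["centre_id"], kind=kind, adjusted=False)
    if kind == "continuous":
        lim_u = funnel_limits(unadj, kind, patient_values=y, z_inner=z_inner, z_outer=z_outer)
        adj_values, _ = risk_adjust_continuous(sub, model, oc)
        adj = centre_measures(adj_values, sub["centre_id"], kind=kind, adjusted=True)
        lim_a = funnel_limits(adj, kind, patient_values=adj_values, z_inner=z_inner, z_outer=z_outer)
    else:
        lim_u = funnel_limits(unadj, kind, z_inner=z_inner, z_outer=z_outer)
        expected = model.predict(sub)
        ok = y.notna() & expected.notna()
        overall = float(y[ok].mean())
        per_centre = pd.DataFrame({
            "centre_id": sub.loc[ok, "centre_id"].to_numpy(),
            "obs": y[ok].to_numpy(), "exp": expected[ok].to_numpy(),
        }).groupby("centre_id").agg(n=("obs", "size"), obs=("obs", "sum"), exp=("exp", "sum"))
        adj = pd.DataFrame({
            "centre_id": per_centre.index,
            "n": per_centre["n"].to_numpy(),
            "measure": [risk_adjust_rate(o, e, overall)
                        for o, e in zip(per_centre["obs"], per_centre["exp"])],
        }).reset_index(drop=True)
        adj["adjusted"] = True
        lim_a = funnel_limits(adj, kind, z_inner=z_inner, z_outer=z_outer)

    unadj = classify_centres(unadj, lim_u)
    adj = classify_centres(adj, lim_a)
    both = set(unadj["centre_id"]) & set(adj["centre_id"])
    u_status = unadj.set_index("centre_id").loc[sorted(both), "status"]
    a_status = adj.set_index("centre_id").loc[sorted(both), "status"]
    counts = compare_classifications(u_status, a_status)
    return {"unadjusted": unadj, "adjusted": adj,
            "limits_unadjusted": lim_u, "limits_adjusted": lim_a,
            "counts": counts}


def run_pipeline(config: CohortConfig | None = None, seed: int = 0,
                 outdir: str | Path = "diabench_run", records: pd.DataFrame | None = None,
                 diabetes_types=("t2dm", "t1dm"),
                 outcomes=("hba1c", "ldl_ch", "sbp", "severe_hypo"),
                 z_inner: float = 1.96, z_outer: float = 3.0,
                 min_centre_n: int | None = None, sensitivity: bool = False,
                 plots: bool = True) -> RunManifest:
    """Run the full benchmarking analysis and write all artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or default_config()
    root = np.random.SeedSequence(seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)]
    manifest = RunManifest(seed=seed, version=__version__,
                           config=_config_snapshot(config))

    with _stage("simulate", seed):
        if records is None:
            records = generate_cohort(config, seed=stage_seeds[0])
        path = outdir / "cohort.csv"
        from .io import write_cohort
        write_cohort(records, path)
        manifest.counts["patients"] = int(len(records))
        manifest.counts["centres"] = int(records["centre_id"].nunique())
        manifest.outputs.append(str(path))

    with _stage("summarise", seed):
        summary = table1_frame(summarise_cohort(records))
        path = outdir / "table1_summary.csv"
        summary.to_csv(path, index=False)
        manifest.outputs.append(str(path))

    with _stage("fit", seed):
        models = fit_all_models(records, diabetes_types, outcomes)
        path = outdir / "risk_models.csv"
        models_frame(models).to_csv(path, index=False)
        manifest.counts["risk_models"] = len(models)
        manifest.outputs.append(str(path))

    if sensitivity:
        with _stage("sensitivity", seed):
            sens_rows = []
            for (dt, oc), model in models.items():
                if oc not in CONTINUOUS:
                    continue
                sub = records[records["diabetes_type"] == dt]
                _, rep = refit_without_outliers(sub, model.spec)
                sens_rows.append({"diabetes_type": dt, "outcome": oc,
                                  "analysis": "tukey_refit",
                                  "detail": f"lost={rep['terms_lost']} gained={rep['terms_gained']} "
                                            f"n_excluded={rep['n_excluded']}"})
            path = outdir / "sensitivity.csv"
            pd.DataFrame(sens_rows).to_csv(path, index=False)
            manifest.outputs.append(str(path))

    with _stage("benchmark", seed):
        strata_counts = {}
        for (dt, oc), model in models.items():
            sub = records[records["diabetes_type"] == dt]
            res = benchmark_stratum(sub, model, z_inner=z_inner, z_outer=z_outer,
                                    min_centre_n=min_centre_n)
            strata_counts[(dt, oc)] = res["counts"]
            frame = pd.concat([
                _funnel_frame(res["unadjusted"], res["limits_unadjusted"]),
                _funnel_frame(res["adjusted"], res["limits_adjusted"]),
            ], ignore_index=True)
            path = outdir / f"funnel_{dt}_{oc}.csv"
            frame.to_csv(path, index=False)
            manifest.outputs.append(str(path))
            if plots:
                import matplotlib
                matplotlib.use("Agg", force=False)
                import matplotlib.pyplot as plt
                fig, axes = plt.subplots(1, 2, figsize=(11, 4))
                funnel_plot(res["unadjusted"], res["limits_unadjusted"], ax=axes[0],
                            title=f"{dt.upper()} {oc} unadjusted", ylabel=oc)
                funnel_plot(res["adjusted"], res["limits_adjusted"], ax=axes[1],
                            title=f"{dt.upper()} {oc} risk-adjusted", ylabel=oc)
                fig.tight_layout()
                ppath = outdir / f"funnel_{dt}_{oc}.png"
                fig.savefig(ppath, dpi=120)
                plt.close(fig)
                manifest.outputs.append(str(ppath))

    with _stage("report", seed):
        summary = reclassification_summary(strata_counts)
        path = outdir / "reclassification.csv"
        summary.to_csv(path, index=False)
        manifest.outputs.append(str(path))
        txt = outdir / "reclassification.txt"
        txt.write_text(format_reclassification(summary))
        manifest.outputs.append(str(txt))

    (outdir / "manifest.json").write_text(manifest.to_json())
    manifest.outputs.append(str(outdir / "manifest.json"))
    return manifest


def _funnel_frame(classified: pd.DataFrame, limits) -> pd.DataFrame:
    out = classified.copy()
    ilo, ihi = limits.interval(out["n"].to_numpy(), limits.z_inner)
    olo, ohi = limits.interval(out["n"].to_numpy(), limits.z_outer)
    out["inner_low"], out["inner_high"] = ilo, ihi
    out["outer_low"], out["outer_high"] = olo, ohi
    out["grand_value"] = limits.grand
    return out


def format_reclassification(summary: pd.DataFrame) -> str:
    """Fixed-width text rendering of the reclassification table
    (percentages rounded to integers; blank where undefined)."""
    lines = [
        f"{'stratum':<24}{'low total':>10}{'low FP':>8}{'FP%':>6}"
        f"{'high total':>12}{'high FP':>9}{'FP%':>6}{'low FN':>8}{'high FN':>9}"
    ]
    for _, r in summary.iterrows():
        fpl = "" if r["fp_low_pct"] is None or pd.isna(r["fp_low_pct"]) else f"{int(r['fp_low_pct'])}"
        fph = "" if r["fp_high_pct"] is None or pd.isna(r["fp_high_pct"]) else f"{int(r['fp_high_pct'])}"
        lines.append(
            f"{r['stratum']:<24}{r['total_low']:>10}{r['fp_low']:>8}{fpl:>6}"
            f"{r['total_high']:>12}{r['fp_high']:>9}{fph:>6}{r['fn_low']:>8}{r['fn_high']:>9}"
        )
    return "\n".join(lines) + "\n"


def _config_snapshot(config: CohortConfig) -> dict:
    snap = dataclasses.asdict(config)

    def clean(obj):
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return clean(snap)
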