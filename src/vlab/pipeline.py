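"""End-to-end pipeline driver: synth → prep → cluster → match → fit →
simulate → extrapolate → evaluate, with every artifact written to disk and
the whole run reproducible from (config, seed)."""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import evaluate as ev
from . import matching as mt
from .monotonicity import (CATEGORIES, build_long_pool,
                           evaluate_extrapolation)
from .monotonicity import extrapolate as extrapolate_patient
from .cohort import CohortSpec, generate_cohort, inject_selection_bias, write_cohort
from .preprocess import interpolate_series, responder_table
from .regression import (FittedClusterModel, build_design,
                         cross_correlation_screen, fit_penalized,
                         fit_stepwise_ml, validate_holdout)
from .simulate import ClusterSimulationContext, assign_cluster, simulate


@dataclass
class PipelineConfig:
    """Scale, method, and seed settings for one pipeline run."""

    n_os: int = 600
    n_rct: int = 300
    n_clusters: int = 6
    bias_strength: float = 0.5
    noise_sd: float = 0.5
    method: str = "lasso"          # final re-estimation method
    n_instances: int = 100         # virtual instances per novel patient
    n_novel: int = 40              # validation patients pushed through simulation
    responder_majority: float = 0.5
    fisher_mc: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


FISHER_VARIABLES = ("gender", "age_group", "bmi_group", "insulin", "depression",
                    "gabapentin", "monotherapy", "prsi_category",
                    "pain_category", "maintenance_dose")


def _fisher_frame(patients: pd.DataFrame, series: pd.DataFrame) -> pd.DataFrame:
    """Categorical view of the covariates used for cluster comparisons."""
    frame = patients.copy().set_index("patient_id")
    frame["pain_category"] = frame["baseline_pain"].map(mt.pain_category)
    frame["prsi_category"] = frame["baseline_prsi"].map(mt.prsi_category)
    dose_mode = (series[series["week"] >= 1]
                 .groupby("patient_id")["dose_mg"].median())
    frame["maintenance_dose"] = dose_mode.reindex(frame.index).astype(int)
    return frame


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage; returns the report dict written to report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict()}
    rng_fisher = np.random.default_rng(config.seed + 101)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        return deco

    # ---- synth ----------------------------------------------------------
    spec = CohortSpec(n_os=config.n_os, n_rct=config.n_rct,
                      noise_sd=config.noise_sd, seed=config.seed)
    patients, series = stage("synth")(lambda: generate_cohort(spec))
    patients = inject_selection_bias(patients, config.bias_strength,
                                     seed=config.seed + 1)
    write_cohort(patients, series, out)

    # ---- prep -----------------------------------------------------------
    series = stage("prep")(lambda: interpolate_series(series))
    responders = responder_table(series)

    # ---- cluster --------------------------------------------------------
    os_patients = patients[patients["source"] == "OS"].reset_index(drop=True)
    model = stage("cluster")(
        lambda: cl.hierarchical_cluster(os_patients, config.n_clusters))
    model.labels.rename_axis("patient_id").reset_index().to_csv(
        out / "clusters.csv", index=False)
    (out / "tree.nwk").write_text(cl.to_newick(model))
    report["clustering"] = {
        "n_clusters": config.n_clusters,
        "cluster_sizes": {int(k): int(v)
                          for k, v in model.cluster_sizes().items()},
        "semipartial_r2_last_merges": [round(float(x), 6)
                                       for x in model.semipartial_r2[-8:]],
    }

    # ---- match ----------------------------------------------------------
    matches = stage("match")(lambda: mt.match_all(patients, model.labels))
    matched_os = sorted({p for m in matches.values() for p in m.matched_os})
    matched_rct = sorted({p for m in matches.values() for p in m.matched_rct})
    match_report = {
        str(c): {
            "n_os": len({p for p in m.matched_os}),
            "n_rct": len({p for p in m.matched_rct}),
            "l1_before": m.l1_before,
            "l1_after_weighted": m.l1_after,
            "l1_after_unweighted": m.l1_after_unweighted,
            "imbalance_reduction_pct": m.imbalance_reduction_pct,
        } for c, m in matches.items()}
    (out / "match_report.json").write_text(
        json.dumps(match_report, indent=2, sort_keys=True))
    rows = []
    for c, m in matches.items():
        for pid in m.matched_os + m.matched_rct:
            rows.append({"patient_id": pid, "cluster": c, "matched_flag": 1})
    pd.DataFrame(rows).to_csv(out / "matched.csv", index=False)
    accounting = ev.cohort_accounting(config.n_os, len(matched_os),
                                      config.n_rct, len(matched_rct))
    report["matching"] = {"per_cluster": match_report, "accounting": accounting}

    # ---- fit ------------------------------------------------------------
    def fit_stage():
        models: dict[int, FittedClusterModel] = {}
        fit_meta = {}
        for c, m in matches.items():
            ids = set(m.matched_os) | set(m.matched_rct)
            if not ids:
                warnings.warn(f"cluster {c}: empty match; no model fitted")
                continue
            members = patients[patients["patient_id"].isin(ids)]
            sub = series[series["patient_id"].isin(ids) & (series["week"] <= 6)]
            design = build_design(members, sub)
            candidates = [col for col in design.columns
                          if col not in ("patient_id", "week", "y")]
            if len(design) < len(candidates) + 5:
                # small matched set: screen candidates by cross-correlation
                if len(design) >= 10:
                    n_keep = max(3, len(design) // 4 - 2)
                    screen = cross_correlation_screen(design)
                    candidates = sorted(screen["candidate"].head(n_keep))
                else:
                    warnings.warn(f"cluster {c}: too few design rows "
                                  f"({len(design)}); no model fitted")
                    continue
            step = fit_stepwise_ml(design, candidates=candidates, cluster_id=c)
            final = fit_penalized(design, method=config.method,
                                  candidates=candidates, cluster_id=c,
                                  random_state=config.seed)
            if not final.coefficients:
                warnings.warn(f"cluster {c}: penalized model empty; "
                              "keeping stepwise fit")
                final = step
            models[c] = final
            fit_meta[str(c)] = {
                "stepwise": step.to_dict() | {"trace": step.selection_trace},
                "final": final.to_dict(),
                "equation": final.equation(),
            }
        return models, fit_meta

    models, fit_meta = stage("fit")(fit_stage)
    (out / "models.json").write_text(json.dumps(
        {str(c): m.to_dict() for c, m in models.items()},
        indent=2, sort_keys=True))
    report["models"] = {
        c: {"adjusted_r2": meta["final"]["adjusted_r2"],
            "rmse": meta["final"]["rmse"],
            "n_predictors": len(meta["final"]["predictors"]),
            "equation": meta["equation"]}
        for c, meta in fit_meta.items()}

    # ---- validate -------------------------------------------------------
    unmatched_os = os_patients[~os_patients["patient_id"].isin(matched_os)]
    validation = stage("validate")(
        lambda: validate_holdout(models, unmatched_os, series, model.labels))
    report["validation"] = {str(c): v for c, v in validation.items()}

    # ---- simulate -------------------------------------------------------
    def simulate_stage():
        contexts = {}
        for c, m in matches.items():
            if c not in models:
                continue
            ids = set(m.matched_os) | set(m.matched_rct)
            members = patients[patients["patient_id"].isin(ids)]
            contexts[c] = ClusterSimulationContext.build(c, members, series)
        novel_pool = unmatched_os.merge(responders, on="patient_id")
        novel_pool = novel_pool.sort_values("patient_id").head(config.n_novel)
        sims, rows = [], []
        for i, (_, novel) in enumerate(novel_pool.iterrows()):
            c, conf, _detail = assign_cluster(novel, model, os_patients)
            if c not in models:
                warnings.warn(f"novel patient {novel['patient_id']}: assigned "
                              f"cluster {c} has no fitted model; skipped")
                continue
            res = simulate(novel, models[c], contexts[c],
                           n_instances=config.n_instances,
                           seed=config.seed + 1000 + i)
            res.confidence = conf
            sims.append(res)
            rows.append(res.summary()
                        | {"true_responder_50": bool(novel["responder_50"]),
                           "true_responder_30": bool(novel["responder_30"])})
        return sims, rows

    sims, sim_rows = stage("simulate")(simulate_stage)
    (out / "simulations.json").write_text(
        json.dumps(sim_rows, indent=2, sort_keys=True))

    def prediction_metrics():
        out_m = {}
        for thr, frac_col in ((0.5, "responder_fraction_50"),
                              (0.3, "responder_fraction_30")):
            pred = [r[frac_col] > config.responder_majority for r in sim_rows]
            true = [r[f"true_responder_{int(thr * 100)}"] for r in sim_rows]
            out_m[f"{int(thr * 100)}"] = ev.confusion(pred, true, thr).to_dict()
        return out_m

    report["prediction"] = stage("evaluate")(prediction_metrics)

    # ---- extrapolate ----------------------------------------------------
    def extrapolate_stage():
        pool = build_long_pool(patients, series)
        if pool.empty:
            return {"note": "no long-duration RCT patients"}, None
        ex_rows = []
        for res in sims:
            rep = extrapolate_patient(res.median_final_pain,
                                      res.cloud_monotonicity, pool)
            ex_rows.append({"patient_id": res.patient_id,
                            "monotonicity": rep.value,
                            "category": rep.category,
                            "horizon_prediction": rep.horizon_prediction,
                            "histogram": rep.neighbor_histogram})
        # held-out evaluation: split the pool, predict one half from the other
        rng = np.random.default_rng(config.seed + 7)
        perm = rng.permutation(len(pool))
        ref, test = pool.iloc[perm[len(pool) // 2:]], pool.iloc[perm[:len(pool) // 2]]
        preds, scores = [], []
        for _, row in test.iterrows():
            rep = extrapolate_patient(row["pain_week6"], row["mono06"], ref)
            preds.append(rep.horizon_prediction)
            scores.append(rep.vote_fractions)
        evaluation = evaluate_extrapolation(
            preds, test["transition"].tolist(),
            scores=pd.DataFrame(scores))
        evaluation["n_test"] = int(len(test))
        evaluation["pool_transition_counts"] = {
            c: int((pool["transition"] == c).sum()) for c in CATEGORIES}
        return {"novel_patients": ex_rows, "holdout_evaluation": evaluation}, pool

    extrap, _pool = stage("extrapolate")(extrapolate_stage)
    (out / "extrapolation.json").write_text(
        json.dumps(extrap, indent=2, sort_keys=True, default=str))
    report["extrapolation"] = extrap.get("holdout_evaluation", extrap)

    # ---- fisher + coverage ---------------------------------------------
    def fisher_stage():
        fisher_view = _fisher_frame(patients, series)
        calib_groups, valid_groups = {}, {}
        for c, m in matches.items():
            calib_groups[c] = m.matched_os + m.matched_rct
        unmatched_ids = unmatched_os["patient_id"]
        for c in sorted(matches):
            ids = [p for p in unmatched_ids
                   if model.labels.get(p) == c]
            if ids:
                valid_groups[c] = ids
        counts = {}
        for var in FISHER_VARIABLES:
            vals = fisher_view[var]
            counts[var] = {
                "calibration": ev.pairwise_fisher(
                    calib_groups, vals, rng=rng_fisher)["n_significant"],
                "validation": ev.pairwise_fisher(
                    valid_groups, vals, rng=rng_fisher)["n_significant"],
                "cross": ev.cross_dataset_fisher(
                    calib_groups, vals, valid_groups, vals,
                    rng=rng_fisher)["n_significant"],
            }
        return counts

    report["fisher_significant_pairs"] = stage("fisher")(fisher_stage)
    report["coverage"] = {
        "os": ev.combination_coverage(
            patients[patients["source"] == "OS"]).to_dict(),
        "rct": ev.combination_coverage(
            patients[patients["source"] == "RCT"]).to_dict(),
        "combined": ev.combination_coverage(patients).to_dict(),
    }

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str))
    (out / "report.md").write_text(_report_md(report))
    return report


def _report_md(report: dict) -> str:
    acc = report["matching"]["accounting"]
    lines = [
        "# Pipeline report", "",
        f"OS patients: {acc['n_os']} (matched {acc['n_matched_os']}, "
        f"{acc['os_match_pct']:.1f}%)",
        f"RCT patients: {acc['n_rct']} (matched {acc['n_matched_rct']}, "
        f"{acc['rct_match_pct']:.1f}%)",
        f"Matched dataset: {acc['n_matched_total']} patients", "",
        "## Per-cluster models", "",
    ]
    for c, m in sorted(report["models"].items()):
        lines.append(f"- cluster {c}: adj R2 {m['adjusted_r2']:.3f}, "
                     f"RMSE {m['rmse']:.3f}, {m['equation']}")
    lines += ["", "## Responder prediction", ""]
    for thr, d in sorted(report["prediction"].items()):
        ppv = "n/a" if d["ppv"] is None else f"{100 * d['ppv']:.1f}%"
        lines.append(f"- {thr}% threshold: PPV {ppv}, "
                     f"accuracy {100 * d['accuracy']:.1f}%")
    cov = report["coverage"]
    lines += ["", "## Combination coverage", "",
              f"- OS {cov['os']['pct']:.1f}%, RCT {cov['rct']['pct']:.1f}%, "
              f"combined {cov['combined']['pct']:.1f}% of "
              f"{cov['os']['n_possible']} combinations", ""]
    return "\n".join(lines)
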