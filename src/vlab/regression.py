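"""Per-cluster lagged regressions of weekly pain score.

Candidate predictors are lags of pain/PRSI/dose, baseline general-feeling
items, and fixed covariate dummies. Selection proceeds in two stages mirroring
the analysis design: forward/backward stepwise selection under a Gaussian
likelihood (likelihood-ratio p < 0.05 to enter, > 0.10 to remove), then
penalized re-estimation with LASSO, adaptive LASSO, or elastic net tuned by
K-fold cross-validation. Models carry no intercept: an all-zero predictor
vector predicts zero pain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV, Lasso, LassoCV
from sklearn.model_selection import KFold

from .equations import COLUMN_TO_SYMBOL

PAIN_LAGS = (1, 2, 3)
PRSI_LAGS = (0, 1, 2, 3)
DOSE_LAGS = (0, 1, 2, 3)

DEFAULT_CANDIDATES = (
    [f"pain_lag{l}" for l in PAIN_LAGS]
    + [f"prsi_lag{l}" for l in PRSI_LAGS]
    + [f"dose_lag{l}" for l in DOSE_LAGS]
    + ["feel_calm_t0", "feel_energy_t0", "feel_sad_t0",
       "age_75plus", "female", "insulin", "depression",
       "gabapentin", "monotherapy"]
)


def build_design(patients: pd.DataFrame, series: pd.DataFrame,
                 candidates=None, weeks=None) -> pd.DataFrame:
    """One row per (patient, week) with every candidate predictor evaluated.

    A week contributes a row only when all required lags exist within the
    series (weeks lacking a lag are dropped); rows with any missing value are
    dropped as well. ``y`` is pain at the row's week.
    """
    candidates = list(candidates or DEFAULT_CANDIDATES)
    max_lag = 0
    for name in candidates:
        if "_lag" in name:
            max_lag = max(max_lag, int(name.rsplit("_lag", 1)[1]))
    fixed = patients.set_index("patient_id")
    rows = []
    for pid, grp in series.groupby("patient_id", sort=False):
        grp = grp.set_index("week").sort_index()
        f = fixed.loc[pid]
        weeks_avail = grp.index
        t_candidates = weeks if weeks is not None else weeks_avail
        for t in t_candidates:
            if t - max_lag < 0 or t not in weeks_avail or t == 0:
                continue
            row = {"patient_id": pid, "week": int(t), "y": grp.loc[t, "pain"]}
            ok = True
            for name in candidates:
                if name.startswith("pain_lag"):
                    val = grp.loc[t - int(name[8:]), "pain"]
                elif name.startswith("prsi_lag"):
                    val = grp.loc[t - int(name[8:]), "prsi"]
                elif name.startswith("dose_lag"):
                    val = grp.loc[t - int(name[8:]), "dose_mg"]
                elif name == "feel_calm_t0":
                    val = f["feel_calm"]
                elif name == "feel_energy_t0":
                    val = f["feel_energy"]
                elif name == "feel_sad_t0":
                    val = f["feel_sad"]
                elif name == "age_75plus":
                    val = 1.0 if f["age_group"] == "75+" else 0.0
                elif name == "female":
                    val = 1.0 if f["gender"] == "F" else 0.0
                elif name in ("insulin", "depression", "gabapentin", "monotherapy"):
                    val = float(f[name])
                else:
                    raise ValueError(f"unknown candidate predictor {name!r}")
                row[name] = float(val)
                if np.isnan(row[name]):
                    ok = False
            if ok and not np.isnan(row["y"]):
                rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "week", "y", *candidates])


def cross_correlation_screen(design: pd.DataFrame,
                             candidates=None) -> pd.DataFrame:
    """Pearson correlation of pain(t) with each candidate, ranked by |r|."""
    if len(design) < 10:
        raise ValueError("need at least 10 design rows for screening")
    candidates = list(candidates or
                      [c for c in design.columns
                       if c not in ("patient_id", "week", "y")])
    y = design["y"].to_numpy()
    recs = []
    for name in candidates:
        x = design[name].to_numpy()
        if np.std(x) == 0:
            warnings.warn(f"candidate {name!r} is constant; correlation set to 0")
            r = 0.0
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        recs.append({"candidate": name, "r": r, "abs_r": abs(r)})
    return (pd.DataFrame(recs)
            .sort_values(["abs_r", "candidate"], ascending=[False, True],
                         kind="stable")
            .reset_index(drop=True))


@dataclass
class FittedClusterModel:
    """Sparse no-intercept coefficient map plus fit metrics for one cluster."""

    cluster_id: int
    method: str
    coefficients: dict[str, float]
    adjusted_r2: float
    rmse: float
    lr_pvalue: float | None = None
    lambda_: float | None = None
    l1_ratio: float | None = None
    n_obs: int = 0
    selection_trace: list = field(default_factory=list)

    def equation(self) -> str:
        parts = []
        for name, b in self.coefficients.items():
            sym = COLUMN_TO_SYMBOL.get(name, name)
            parts.append(f"{b:+.4f}*{sym}")
        return "y = " + " ".join(parts) if parts else "y = 0"

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "method": self.method,
            "predictors": list(self.coefficients),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "adjusted_r2": self.adjusted_r2,
            "rmse": self.rmse,
            "lr_pvalue": self.lr_pvalue,
            "lambda": self.lambda_,
            "l1_ratio": self.l1_ratio,
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedClusterModel":
        coeffs = {k: float(d["coefficients"][k]) for k in d["predictors"]}
        return cls(d["cluster_id"], d["method"], coeffs, d["adjusted_r2"],
                   d["rmse"], d.get("lr_pvalue"), d.get("lambda"),
                   d.get("l1_ratio"), d.get("n_obs", 0))


def _gauss_llf(resid: np.ndarray) -> float:
    n = len(resid)
    s2 = max(float(np.mean(resid ** 2)), 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _fit_metrics(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> tuple[float, float]:
    resid = y - X @ beta
    n, p = X.shape
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - p - 1, 1)
    return adj, float(np.sqrt(ss_res / n))


def fit_stepwise_ml(design: pd.DataFrame, candidates=None, cluster_id: int = 0,
                    p_enter: float = 0.05, p_remove: float = 0.10,
                    max_steps: int = 100) -> FittedClusterModel:
    """Forward/backward selection by Gaussian likelihood-ratio tests.

    Candidates whose inclusion would make the design rank-deficient are
    skipped with a warning (the later-ranked collinear one is dropped).
    """
    candidates = list(candidates or
                      [c for c in design.columns
                       if c not in ("patient_id", "week", "y")])
    if len(design) < len(candidates) + 5:
        raise ValueError("too few rows for the candidate set")
    y = design["y"].to_numpy(dtype=float)
    cols = {c: design[c].to_numpy(dtype=float) for c in candidates}
    selected: list[str] = []
    trace: list[tuple[str, str, float]] = []

    def llf_of(names: list[str]) -> float:
        if not names:
            return _gauss_llf(y)
        X = np.column_stack([cols[c] for c in names])
        return _gauss_llf(y - X @ _ols(X, y))

    current_llf = llf_of([])
    for _ in range(max_steps):
        changed = False
        # forward
        best_p, best_c, best_llf = 1.0, None, None
        for c in candidates:
            if c in selected:
                continue
            X_try = np.column_stack([cols[k] for k in selected + [c]])
            if np.linalg.matrix_rank(X_try) < X_try.shape[1]:
                warnings.warn(f"candidate {c!r} collinear with selected set; skipped")
                continue
            llf = llf_of(selected + [c])
            p = stats.chi2.sf(max(2.0 * (llf - current_llf), 0.0), df=1)
            if p < best_p - 1e-15:
                best_p, best_c, best_llf = p, c, llf
        if best_c is not None and best_p < p_enter:
            selected.append(best_c)
            current_llf = best_llf
            trace.append(("add", best_c, float(best_p)))
            changed = True
        # backward
        worst_p, worst_c, worst_llf = -1.0, None, None
        for c in selected:
            rest = [k for k in selected if k != c]
            llf = llf_of(rest)
            p = stats.chi2.sf(max(2.0 * (current_llf - llf), 0.0), df=1)
            if p > worst_p:
                worst_p, worst_c, worst_llf = p, c, llf
        if worst_c is not None and worst_p > p_remove:
            selected.remove(worst_c)
            current_llf = worst_llf
            trace.append(("drop", worst_c, float(worst_p)))
            changed = True
        if not changed:
            break

    if selected:
        X = np.column_stack([cols[c] for c in selected])
        beta = _ols(X, y)
        adj, rmse = _fit_metrics(X, y, beta)
        lr_p = float(stats.chi2.sf(2.0 * (current_llf - llf_of([])),
                                   df=len(selected)))
        coeffs = {c: float(b) for c, b in zip(selected, beta)}
    else:
        adj, rmse = 0.0, float(np.sqrt(np.mean(y ** 2)))
        lr_p, coeffs = 1.0, {}
    return FittedClusterModel(cluster_id, "stepwise_ml", coeffs, adj, rmse,
                              lr_pvalue=lr_p, n_obs=len(y),
                              selection_trace=trace)


def fit_penalized(design: pd.DataFrame, method: str = "lasso",
                  candidates=None, cluster_id: int = 0, cv: int = 10,
                  lambda_: float | None = None,
                  random_state: int = 0) -> FittedClusterModel:
    """Penalized no-intercept fit: LASSO, adaptive LASSO, or elastic net.

    Columns are scaled to unit SD for the penalty and coefficients mapped
    back; tuning is by K-fold CV at the CV-minimum. ``lambda_`` overrides the
    CV search (``lambda_ = 0`` reduces to ordinary least squares). Adaptive
    LASSO uses weights 1/|b_ML| from the unpenalized fit.
    """
    if method not in ("lasso", "adaptive_lasso", "elastic_net"):
        raise ValueError(f"unknown method {method!r}")
    candidates = list(candidates or
                      [c for c in design.columns
                       if c not in ("patient_id", "week", "y")])
    y = design["y"].to_numpy(dtype=float)
    X = design[candidates].to_numpy(dtype=float)
    sd_all = X.std(axis=0)
    if (sd_all == 0).any():
        dropped = [c for c, s in zip(candidates, sd_all) if s == 0]
        warnings.warn(f"constant candidates dropped: {dropped}")
    names = [c for c, s in zip(candidates, sd_all) if s > 0]
    sd = sd_all[sd_all > 0]
    Xs = X[:, sd_all > 0] / sd  # unit-SD columns

    adapt = np.ones(len(names))
    if method == "adaptive_lasso":
        beta_ml = _ols(Xs, y)
        if (beta_ml == 0).any():
            zeroed = [n for n, b in zip(names, beta_ml) if b == 0]
            warnings.warn(f"adaptive weights infinite for {zeroed}; excluded")
            mask = beta_ml != 0
            names = [n for n, k in zip(names, mask) if k]
            Xs, sd, beta_ml = Xs[:, mask], sd[mask], beta_ml[mask]
        adapt = np.abs(beta_ml)

    Xw = Xs * adapt  # identity except for adaptive LASSO
    if lambda_ is not None and lambda_ == 0:
        beta_w = _ols(Xw, y)
        lam, l1r = 0.0, None
    else:
        folds = KFold(n_splits=min(cv, max(2, len(y) // 2)), shuffle=True,
                      random_state=random_state)
        if method == "elastic_net":
            est = ElasticNetCV(l1_ratio=[0.2, 0.5, 0.8, 0.95], alphas=60,
                               fit_intercept=False, cv=folds, max_iter=50_000)
        elif lambda_ is not None:
            est = Lasso(alpha=lambda_, fit_intercept=False, max_iter=50_000)
        else:
            est = LassoCV(alphas=60, fit_intercept=False, cv=folds,
                          max_iter=50_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xw, y)
        beta_w = est.coef_.copy()
        lam = float(getattr(est, "alpha_", lambda_ if lambda_ is not None else 0.0))
        l1r = float(est.l1_ratio_) if method == "elastic_net" else None

    beta = beta_w * adapt / sd  # back to the raw predictor scale
    keep_all = lambda_ is not None and lambda_ == 0
    coeffs = {n: float(b) for n, b in zip(names, beta) if keep_all or b != 0.0}
    Xfull = design[list(coeffs)].to_numpy(dtype=float) if coeffs else \
        np.zeros((len(y), 0))
    bvec = np.array([coeffs[c] for c in coeffs])
    adj, rmse = _fit_metrics(Xfull, y, bvec) if coeffs else \
        (0.0, float(np.sqrt(np.mean(y ** 2))))
    return FittedClusterModel(cluster_id, method, coeffs, adj, rmse,
                              lambda_=lam, l1_ratio=l1r, n_obs=len(y))


def predict_pain(model: FittedClusterModel, values) -> float:
    """Inner product of the model's coefficients with supplied predictor values.

    No intercept and no clipping here; raises ``ValueError`` naming any
    missing predictor.
    """
    total = 0.0
    for name, b in model.coefficients.items():
        if name not in values:
            raise ValueError(f"missing predictor {name!r}")
        total += b * float(values[name])
    return total


def predict_frame(model: FittedClusterModel, design: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.coefficients if c not in design.columns]
    if missing:
        raise ValueError(f"missing predictors {missing}")
    if not model.coefficients:
        return np.zeros(len(design))
    X = design[list(model.coefficients)].to_numpy(dtype=float)
    return X @ np.array(list(model.coefficients.values()))


def validate_holdout(models: dict[int, FittedClusterModel],
                     patients: pd.DataFrame, series: pd.DataFrame,
                     labels: pd.Series) -> dict[int, dict]:
    """Observed-vs-predicted validation on holdout patients, per cluster.

    Reports the scatter R², a two-sample t-test p of observed vs predicted
    weekly scores, and residual summaries. Clusters absent from the holdout
    are skipped with a warning.
    """
    report: dict[int, dict] = {}
    lab = patients["patient_id"].map(labels)
    for c, model in sorted(models.items()):
        members = patients[lab == c]
        if members.empty:
            warnings.warn(f"cluster {c} absent from holdout; skipped")
            continue
        sub_series = series[series["patient_id"].isin(members["patient_id"])]
        design = build_design(members, sub_series,
                              candidates=list(model.coefficients) or None)
        if design.empty:
            warnings.warn(f"cluster {c}: no usable holdout rows; skipped")
            continue
        obs = design["y"].to_numpy()
        pred = predict_frame(model, design)
        resid = obs - pred
        ss_tot = float(((obs - obs.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        if np.allclose(obs, pred):
            t_p = 1.0
        else:
            t_p = float(stats.ttest_ind(obs, pred).pvalue)
        report[c] = {"n_rows": int(len(obs)), "r2": r2, "t_pvalue": t_p,
                     "resid_mean": float(resid.mean()),
                     "resid_sd": float(resid.std())}
    return report
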