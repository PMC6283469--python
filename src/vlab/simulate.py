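"""Patient-level Monte-Carlo microsimulation of a novel patient.

A novel patient (baseline covariates only, no trajectory) is first assigned to
a phenotype cluster by an ensemble of two instance-based learners: a k-nearest
-neighbor vote over Gower distance (k = round(sqrt(n_training))) and fuzzy
c-means memberships against the cluster centroids (fuzzifier m = 2). The
assigned cluster's lagged regression then drives ``n_instances`` virtual
trajectories over 6 weeks: each week, the k patients of the cluster nearest to
the evolving state supply empirical distributions for next-week PRSI (and any
other time-varying model inputs), dose is drawn from the cluster's 50%-
responder dose distribution for that week, and pain advances through the
regression, truncated to the 0-10 NRS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import CATEGORICAL_VARS, NUMERIC_VARS, ClusterModel, gower_to_frame
from .monotonicity import monotonicity
from .regression import FittedClusterModel, predict_pain

HORIZON_WEEKS = 6


def sqrt_k(n: int) -> int:
    """The square-root convention for the neighbor count k."""
    return max(int(round(np.sqrt(n))), 1)


def fuzzy_memberships(distances: np.ndarray, m: float = 2.0) -> np.ndarray:
    """Fuzzy c-means memberships from distances to centroids; sums to 1.

    Zero distance gives full membership to (the first of) the touching
    centroids.
    """
    d = np.asarray(distances, dtype=float)
    u = np.zeros(len(d))
    if (d == 0).any():
        u[int(np.argmax(d == 0))] = 1.0
        return u
    power = 2.0 / (m - 1.0)
    for c in range(len(d)):
        u[c] = 1.0 / np.sum((d[c] / d) ** power)
    return u


def assign_cluster(novel, model: ClusterModel, training: pd.DataFrame,
                   m: float = 2.0) -> tuple[int, float, dict]:
    """Ensemble cluster assignment: kNN vote + fuzzy membership.

    When the two methods agree the common cluster wins; otherwise the method
    with the higher normalized confidence (vote fraction vs max membership)
    decides. Raises if the novel patient carries a categorical level unseen in
    training.
    """
    unseen = [v for v in CATEGORICAL_VARS
              if novel[v] not in set(training[v].unique())]
    if unseen:
        raise ValueError(f"unseen categorical level(s) for: {unseen}")

    d_train = gower_to_frame(novel, training, CATEGORICAL_VARS, NUMERIC_VARS,
                             model.ranges)
    k = sqrt_k(len(training))
    order = np.argsort(d_train, kind="stable")[:k]
    votes = training["patient_id"].map(model.labels).to_numpy()[order]
    vote_counts = pd.Series(votes).value_counts()
    knn_cluster = int(vote_counts.index[0])
    knn_conf = float(vote_counts.iloc[0] / k)

    cents = model.centroids
    d_cent = np.array([
        np.mean([(0.0 if novel[v] == cents.loc[c, v] else 1.0)
                 for v in CATEGORICAL_VARS]
                + [abs(float(novel[v]) - float(cents.loc[c, v])) / model.ranges[v]
                   for v in NUMERIC_VARS if model.ranges[v] > 0])
        for c in cents.index])
    u = fuzzy_memberships(d_cent, m=m)
    fuzzy_cluster = int(cents.index[int(np.argmax(u))])
    fuzzy_conf = float(u.max())

    detail = {"knn": (knn_cluster, knn_conf), "fuzzy": (fuzzy_cluster, fuzzy_conf),
              "memberships": {int(c): float(x) for c, x in zip(cents.index, u)}}
    if knn_cluster == fuzzy_cluster:
        return knn_cluster, max(knn_conf, fuzzy_conf), detail
    if knn_conf >= fuzzy_conf:
        return knn_cluster, knn_conf, detail
    return fuzzy_cluster, fuzzy_conf, detail


def knn_neighbors(member_states: np.ndarray, member_ids, state: np.ndarray,
                  k: int) -> list:
    """Ids of the k members nearest (Euclidean) to ``state``; stable id ties."""
    if len(member_ids) == 0:
        raise ValueError("cluster is empty")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(member_ids):
        warnings.warn(f"k={k} exceeds cluster size {len(member_ids)}; clamped")
        k = len(member_ids)
    d = np.sqrt(((member_states - state[None, :]) ** 2).sum(axis=1))
    ids = np.asarray(member_ids)
    order = np.lexsort((ids, d))  # by distance, then id
    return ids[order[:k]].tolist()


def sample_next_covariates(neighbor_values: dict[str, np.ndarray],
                           rng: np.random.Generator) -> dict[str, float]:
    """One i.i.d. draw per variable from the neighbors' empirical values."""
    out = {}
    for var, vals in neighbor_values.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            warnings.warn(f"no neighbor values for {var!r}; carrying forward")
            out[var] = None
            continue
        out[var] = float(vals[rng.integers(len(vals))])
    return out


def assign_dose(dose_matrix: np.ndarray, week: int,
                rng: np.random.Generator) -> float:
    """Draw a week-``week`` dose from the responder dose pool."""
    col = dose_matrix[:, week]
    col = col[~np.isnan(col)]
    if len(col) == 0:
        raise ValueError("no dose history available")
    return float(col[rng.integers(len(col))])


@dataclass
class SimulationResult:
    patient_id: str
    assigned_cluster: int
    confidence: float | None
    n_instances: int
    trajectories: np.ndarray  # (n_instances, HORIZON_WEEKS+1)
    median_final_pain: float
    responder_fraction_50: float
    responder_fraction_30: float
    cloud_monotonicity: float

    def summary(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "assigned_cluster": self.assigned_cluster,
            "confidence": self.confidence,
            "n_instances": self.n_instances,
            "median_final_pain": self.median_final_pain,
            "responder_fraction_50": self.responder_fraction_50,
            "responder_fraction_30": self.responder_fraction_30,
            "cloud_monotonicity": self.cloud_monotonicity,
        }


@dataclass
class ClusterSimulationContext:
    """Precomputed per-cluster member arrays used by the weekly kNN search."""

    cluster_id: int
    member_ids: list
    pain: np.ndarray       # (n_members, 7)
    prsi: np.ndarray       # (n_members, 7)
    responder_dose: np.ndarray  # (n_responders, 7) weekly doses of 50%-responders
    col_mean: np.ndarray   # standardization stats per (variable, week)
    col_sd: np.ndarray

    @classmethod
    def build(cls, cluster_id: int, members: pd.DataFrame,
              series: pd.DataFrame,
              responder_threshold: float = 0.5) -> "ClusterSimulationContext":
        ids = list(members["patient_id"])
        sub = series[series["patient_id"].isin(ids) &
                     (series["week"] <= HORIZON_WEEKS)]
        pain = (sub.pivot(index="patient_id", columns="week", values="pain")
                .reindex(ids).to_numpy(dtype=float))
        prsi = (sub.pivot(index="patient_id", columns="week", values="prsi")
                .reindex(ids).to_numpy(dtype=float))
        dose = (sub.pivot(index="patient_id", columns="week", values="dose_mg")
                .reindex(ids).to_numpy(dtype=float))
        ok = ~np.isnan(pain).any(axis=1) & ~np.isnan(prsi).any(axis=1)
        ids = [i for i, keep in zip(ids, ok) if keep]
        pain, prsi, dose = pain[ok], prsi[ok], dose[ok]
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = (pain[:, 0] - pain[:, HORIZON_WEEKS]) / pain[:, 0]
        resp = pct >= responder_threshold
        responder_dose = dose[resp] if resp.any() else dose
        if not resp.any():
            warnings.warn(f"cluster {cluster_id}: no responders; "
                          "falling back to whole-cluster dose distribution")
        state = np.hstack([pain, prsi])
        mean = state.mean(axis=0)
        sd = state.std(axis=0)
        sd[sd == 0] = 1.0
        return cls(cluster_id, ids, pain, prsi, responder_dose, mean, sd)

    def state_columns(self, week: int) -> list[int]:
        # pain weeks 0..week-1 then prsi weeks 0..week-1 within the stacked state
        return list(range(week)) + [7 + w for w in range(week)]


def simulate(novel, model: FittedClusterModel, context: ClusterSimulationContext,
             n_instances: int = 1000, seed: int = 0) -> SimulationResult:
    """Run the weekly microsimulation for one assigned novel patient."""
    if model is None:
        raise ValueError("assigned cluster has no fitted model")
    n_members = len(context.member_ids)
    k = sqrt_k(n_members)
    member_state = np.hstack([context.pain, context.prsi])
    member_state_std = (member_state - context.col_mean) / context.col_sd

    age75 = 1.0 if novel["age_group"] == "75+" else 0.0
    fixed_values = {
        "age_75plus": age75,
        "feel_calm_t0": float(novel["feel_calm"]),
        "feel_energy_t0": float(novel["feel_energy"]),
        "feel_sad_t0": float(novel["feel_sad"]),
        "female": 1.0 if novel["gender"] == "F" else 0.0,
        "insulin": float(novel["insulin"]),
        "depression": float(novel["depression"]),
        "gabapentin": float(novel["gabapentin"]),
        "monotherapy": float(novel["monotherapy"]),
    }

    traj = np.empty((n_instances, HORIZON_WEEKS + 1))
    id_to_idx = {p: j for j, p in enumerate(context.member_ids)}
    baseline = float(novel["baseline_pain"])
    for i in range(n_instances):
        rng = np.random.default_rng([seed, i])
        pain = np.empty(HORIZON_WEEKS + 1)
        prsi = np.empty(HORIZON_WEEKS + 1)
        dose = np.empty(HORIZON_WEEKS + 1)
        pain[0] = baseline
        prsi[0] = float(novel["baseline_prsi"])
        dose[0] = assign_dose(context.responder_dose, 0, rng)
        for t in range(1, HORIZON_WEEKS + 1):
            cols = context.state_columns(t)
            state = np.concatenate([pain[:t], prsi[:t]])
            state_std = (state - context.col_mean[cols]) / context.col_sd[cols]
            nbr_ids = knn_neighbors(member_state_std[:, cols],
                                    context.member_ids, state_std, k)
            nbr_idx = [id_to_idx[p] for p in nbr_ids]
            draws = sample_next_covariates(
                {"prsi": context.prsi[nbr_idx, t]}, rng)
            prsi[t] = draws["prsi"] if draws["prsi"] is not None else prsi[t - 1]
            dose[t] = assign_dose(context.responder_dose, t, rng)
            lag3 = max(t - 3, 0)
            values = {"pain_lag1": pain[t - 1], "pain_lag2": pain[max(t - 2, 0)],
                      "pain_lag3": pain[lag3],
                      "prsi_lag0": prsi[t], "prsi_lag1": prsi[t - 1],
                      "prsi_lag2": prsi[max(t - 2, 0)], "prsi_lag3": prsi[lag3],
                      "dose_lag0": dose[t], "dose_lag1": dose[t - 1],
                      "dose_lag2": dose[max(t - 2, 0)], "dose_lag3": dose[lag3],
                      **fixed_values}
            pain[t] = float(np.clip(predict_pain(model, values), 0.0, 10.0))
        traj[i] = pain

    finals = traj[:, HORIZON_WEEKS]
    pct = (baseline - finals) / baseline
    monos = np.array([monotonicity(traj[i]) for i in range(n_instances)])
    return SimulationResult(
        patient_id=str(novel.get("patient_id", "novel")),
        assigned_cluster=context.cluster_id,
        confidence=None,
        n_instances=n_instances,
        trajectories=traj,
        median_final_pain=float(np.median(finals)),
        responder_fraction_50=float(np.mean(pct >= 0.5)),
        responder_fraction_30=float(np.mean(pct >= 0.3)),
        cloud_monotonicity=float(monos.mean()),
    )
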