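"""Hierarchical clustering of OS patients on mixed-type baseline covariates.

Nine clustering variables: gender, age, insulin use, BMI, depression history,
pregabalin monotherapy, prior gabapentin, baseline pain, baseline PRSI.
Dissimilarity is the Gower coefficient (range-normalized absolute difference
for numeric variables, mismatch indicator for categorical ones); agglomeration
is Ward linkage on that matrix, with a per-merge semipartial R² — the share of
total dispersion absorbed by each merge — reported as the homogeneity
diagnostic used to select the six-cluster cut.

Ward formally assumes Euclidean geometry; pairing it with Gower mirrors the
semipartial-R² / Gower combination this analysis is built around and is
documented as a deliberate caveat.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

CATEGORICAL_VARS = ("gender", "insulin", "depression", "gabapentin", "monotherapy")
NUMERIC_VARS = ("age_years", "bmi", "baseline_pain", "baseline_prsi")
CLUSTER_VARS = CATEGORICAL_VARS + NUMERIC_VARS


def numeric_ranges(patients: pd.DataFrame,
                   numeric=NUMERIC_VARS) -> dict[str, float]:
    """max - min per numeric clustering variable over the cohort."""
    return {v: float(patients[v].max() - patients[v].min()) for v in numeric}


def _usable_numeric(numeric, ranges) -> list[str]:
    keep = []
    for v in numeric:
        if ranges.get(v, 0.0) > 0.0:
            keep.append(v)
        else:
            warnings.warn(f"numeric variable {v!r} has zero range; excluded "
                          "from Gower distance")
    return keep


def gower_distance(a, b, categorical=CATEGORICAL_VARS, numeric=NUMERIC_VARS,
                   ranges=None) -> float:
    """Gower dissimilarity between two records; in [0, 1].

    ``ranges`` must give max-min per numeric variable; zero-range variables
    are excluded with a warning.
    """
    if ranges is None:
        raise ValueError("ranges for numeric variables are required")
    num = _usable_numeric(numeric, ranges)
    parts = [0.0 if a[v] == b[v] else 1.0 for v in categorical]
    parts += [abs(float(a[v]) - float(b[v])) / ranges[v] for v in num]
    return float(np.mean(parts))


def gower_matrix(patients: pd.DataFrame, categorical=CATEGORICAL_VARS,
                 numeric=NUMERIC_VARS, ranges=None) -> np.ndarray:
    """Square Gower dissimilarity matrix over the cohort (vectorized)."""
    if ranges is None:
        ranges = numeric_ranges(patients, numeric)
    num = _usable_numeric(numeric, ranges)
    n = len(patients)
    total = np.zeros((n, n))
    for v in categorical:
        codes = pd.factorize(patients[v])[0]
        total += (codes[:, None] != codes[None, :]).astype(float)
    for v in num:
        x = patients[v].to_numpy(dtype=float)
        total += np.abs(x[:, None] - x[None, :]) / ranges[v]
    return total / (len(categorical) + len(num))


def gower_to_frame(record, patients: pd.DataFrame, categorical=CATEGORICAL_VARS,
                   numeric=NUMERIC_VARS, ranges=None) -> np.ndarray:
    """Gower distance from one record to every row of ``patients``."""
    if ranges is None:
        ranges = numeric_ranges(patients, numeric)
    num = _usable_numeric(numeric, ranges)
    n = len(patients)
    total = np.zeros(n)
    for v in categorical:
        total += (patients[v].to_numpy() != record[v]).astype(float)
    for v in num:
        total += np.abs(patients[v].to_numpy(dtype=float) - float(record[v])) / ranges[v]
    return total / (len(categorical) + len(num))


@dataclass
class ClusterModel:
    variables: tuple[str, ...]
    linkage: np.ndarray          # scipy linkage matrix
    semipartial_r2: np.ndarray   # per-merge homogeneity loss, sums to ~1
    n_clusters: int
    labels: pd.Series            # cluster id (1..k) indexed by patient_id
    centroids: pd.DataFrame      # mixed-type prototype per cluster
    ranges: dict[str, float]
    distance_matrix_digest: str

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def hierarchical_cluster(patients: pd.DataFrame, n_clusters: int = 6,
                         categorical=CATEGORICAL_VARS,
                         numeric=NUMERIC_VARS) -> ClusterModel:
    """Ward agglomeration on the Gower matrix, cut at ``n_clusters``.

    Cluster ids 1..k are assigned deterministically by decreasing size (ties
    by first patient row). Semipartial R² of merge i is ``h_i²/2`` over the
    total dispersion ``Σ d²/n``.
    """
    if n_clusters < 2:
        raise ValueError(f"n_clusters must be >= 2, got {n_clusters}")
    if len(patients) < n_clusters:
        raise ValueError("fewer records than clusters")
    ranges = numeric_ranges(patients, numeric)
    dm = gower_matrix(patients, categorical, numeric, ranges)
    condensed = squareform(dm, checks=False)
    digest = hashlib.sha256(np.round(condensed, 12).tobytes()).hexdigest()
    Z = linkage(condensed, method="ward")
    total_ss = float((condensed ** 2).sum()) / len(patients)
    spr2 = (Z[:, 2] ** 2 / 2.0) / total_ss if total_ss > 0 else np.zeros(len(Z))

    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    order = sorted(np.unique(raw),
                   key=lambda c: (-(raw == c).sum(), int(np.argmax(raw == c))))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw],
                       index=patients["patient_id"].to_numpy(), name="cluster")

    centroids = assign_centroids(labels, patients, categorical, numeric)
    return ClusterModel(tuple(categorical) + tuple(numeric), Z, spr2,
                        n_clusters, labels, centroids, ranges, digest)


def assign_centroids(labels: pd.Series, patients: pd.DataFrame,
                     categorical=CATEGORICAL_VARS,
                     numeric=NUMERIC_VARS) -> pd.DataFrame:
    """Per-cluster prototype: mean for numeric, mode (lowest-sorted tie) for
    categorical. Raises on an empty cluster."""
    lab = patients["patient_id"].map(labels)
    rows = {}
    for c in sorted(labels.unique()):
        members = patients[lab == c]
        if members.empty:
            raise ValueError(f"cluster {c} is empty")
        row = {}
        for v in categorical:
            counts = members[v].value_counts()
            top = counts[counts == counts.max()].index
            row[v] = sorted(top)[0]
        for v in numeric:
            row[v] = float(members[v].mean())
        rows[c] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def to_newick(model: ClusterModel, leaf_names=None) -> str:
    """Newick export of the linkage tree (iterative; safe for large cohorts)."""
    Z = model.linkage
    n = Z.shape[0] + 1
    if leaf_names is None:
        leaf_names = list(model.labels.index)
    height = {i: 0.0 for i in range(n)}
    for i in range(Z.shape[0]):
        height[n + i] = Z[i, 2]
    # post-order assembly without recursion
    text: dict[int, str] = {i: str(leaf_names[i]) for i in range(n)}
    for i in range(Z.shape[0]):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        node = n + i
        la = max(height[node] - height[a], 0.0)
        lb = max(height[node] - height[b], 0.0)
        text[node] = f"({text.pop(a)}:{la:.6f},{text.pop(b)}:{lb:.6f})"
    return text[2 * n - 2] + ";"
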