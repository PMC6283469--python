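"""Trajectory-monotonicity statistic and responder-status extrapolation.

Monotonicity of a pain trajectory is the mean sign of its weekly steps —
``(1/T) Σ sign(p[t+1] − p[t])`` — ranging from −1 (strictly falling pain) to
+1 (strictly rising pain). Trajectories are classified with the ±0.2
thresholds (the middle band is inclusive: −0.2 ≤ x ≤ 0.2). To extrapolate a
simulated novel patient beyond week 6, the long-duration (12/13-week) RCT
patients nearest in (median week-6 pain, cloud monotonicity) vote on the
week-6 → end-of-study responder transition: responder→non-responder =
increased pain, non-responder→responder = decreased pain, otherwise
maintained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("decreased_pain", "maintained", "increased_pain")
THRESHOLD = 0.2


def monotonicity(trajectory) -> float:
    """Mean step sign of a trajectory; in [−1, 1]; sign(0) counts as 0."""
    p = np.asarray(trajectory, dtype=float)
    if len(p) < 2:
        raise ValueError("trajectory needs at least 2 points")
    return float(np.mean(np.sign(np.diff(p))))


def classify(value: float) -> str:
    """Three-way monotonicity category with the ±0.2 thresholds."""
    if value < -THRESHOLD:
        return "below_negative"
    if value > THRESHOLD:
        return "above_positive"
    return "between"


@dataclass
class MonotonicityReport:
    value: float
    category: str
    horizon_prediction: str
    neighbor_histogram: dict[str, int]
    vote_fractions: dict[str, float]
    tie: bool
    k: int


def transition_label(pct_change_6: float, pct_change_end: float,
                     threshold: float = 0.5) -> str:
    """Week-6 → end-of-study responder transition category."""
    resp6 = pct_change_6 >= threshold
    resp_end = pct_change_end >= threshold
    if resp6 and not resp_end:
        return "increased_pain"
    if not resp6 and resp_end:
        return "decreased_pain"
    return "maintained"


def build_long_pool(patients: pd.DataFrame, series: pd.DataFrame,
                    threshold: float = 0.5) -> pd.DataFrame:
    """Indicator table for 12/13-week RCT patients.

    Columns: patient_id, pain_week6, mono06 (weeks 0-6 monotonicity), and the
    observed transition label at ``threshold``.
    """
    long_ids = patients.loc[patients["duration_weeks"] >= 12, "patient_id"]
    rows = []
    for pid, grp in series[series["patient_id"].isin(long_ids)].groupby(
            "patient_id", sort=False):
        grp = grp.set_index("week").sort_index()
        end = int(grp.index.max())
        p0, p6, pe = grp.loc[0, "pain"], grp.loc[6, "pain"], grp.loc[end, "pain"]
        rows.append({
            "patient_id": pid,
            "pain_week6": float(p6),
            "mono06": monotonicity(grp.loc[0:6, "pain"].to_numpy()),
            "transition": transition_label((p0 - p6) / p0, (p0 - pe) / p0,
                                           threshold),
        })
    return pd.DataFrame(rows)


def extrapolate(median_week6_pain: float, cloud_monotonicity: float,
                long_pool: pd.DataFrame, k: int | None = None) -> MonotonicityReport:
    """kNN vote of long-duration RCT patients on the post-week-6 transition.

    Distances are Euclidean on (week-6 pain, monotonicity), each indicator
    standardized by the pool SD. ``k`` defaults to round(sqrt(pool size)).
    A majority tie predicts "maintained" and sets the tie flag.
    """
    if long_pool.empty:
        raise ValueError("long-duration pool is empty")
    if k is None:
        from .simulate import sqrt_k
        k = sqrt_k(len(long_pool))
    k = min(k, len(long_pool))
    X = long_pool[["pain_week6", "mono06"]].to_numpy(dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    q = np.array([median_week6_pain, cloud_monotonicity])
    d = np.sqrt((((X - q) / sd) ** 2).sum(axis=1))
    order = np.lexsort((long_pool["patient_id"].to_numpy(), d))[:k]
    votes = long_pool["transition"].to_numpy()[order]
    hist = {c: int((votes == c).sum()) for c in CATEGORIES}
    best = max(hist.values())
    winners = [c for c in CATEGORIES if hist[c] == best]
    tie = len(winners) > 1
    prediction = "maintained" if tie else winners[0]
    fractions = {c: hist[c] / k for c in CATEGORIES}
    return MonotonicityReport(float(cloud_monotonicity),
                              classify(cloud_monotonicity), prediction, hist,
                              fractions, tie, k)


def evaluate_extrapolation(predictions, truths,
                           scores: pd.DataFrame | None = None) -> dict:
    """Per-category accuracy and one-vs-rest ROC points.

    ``predictions``/``truths`` are parallel category sequences; ``scores``
    optionally holds per-category neighbor vote fractions (columns named by
    category) from which ROC curves are traced by threshold variation.
    A category absent from the truths is reported as missing (None).
    """
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if len(pred) != len(true):
        raise ValueError("predictions and truths must be paired")
    out: dict = {"per_category_accuracy": {}, "overall_accuracy":
                 float((pred == true).mean()) if len(true) else None}
    for c in CATEGORIES:
        mask = true == c
        if not mask.any():
            warnings.warn(f"category {c!r} absent from truths")
            out["per_category_accuracy"][c] = None
        else:
            out["per_category_accuracy"][c] = float((pred[mask] == c).mean())
    if scores is not None:
        from sklearn.metrics import auc, roc_curve
        roc: dict = {}
        for c in CATEGORIES:
            y = (true == c).astype(int)
            if y.sum() in (0, len(y)):
                roc[c] = None
                continue
            fpr, tpr, thr = roc_curve(y, scores[c].to_numpy())
            roc[c] = {"fpr": fpr.tolist(), "tpr": tpr.tolist(),
                      "auc": float(auc(fpr, tpr))}
        out["roc"] = roc
    return out
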