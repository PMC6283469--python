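"""Imputation of unobserved OS weeks and responder-status derivation.

The OS records scores only at weeks {0, 1, 3, 6}; weeks 2, 4, 5 are filled by
evaluating the Lagrange quadratic through the three observed points nearest to
the target week (ties in nearness broken toward earlier weeks, interpolation
only — never extrapolation). A pain responder at threshold ``q`` is a patient
whose pain fell by at least the fraction ``q`` of baseline at the horizon week.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd



def quadratic_interpolate(obs_weeks, obs_values, targets,
                          bounds: tuple[float, float] = (0.0, 10.0)) -> np.ndarray:
    """Fill ``targets`` via the 3-point Lagrange quadratic; exact on degree <= 2.

    For each target week the three observed weeks nearest to it are used;
    nearness ties prefer the earlier week. Results are clipped to ``bounds``.

    Raises ``ValueError`` with fewer than 3 observed points or when a target
    lies outside the observed span (extrapolation).
    """
    w = np.asarray(obs_weeks, dtype=float)
    v = np.asarray(obs_values, dtype=float)
    if len(w) < 3:
        raise ValueError(f"need at least 3 observed weeks, got {len(w)}")
    out = np.empty(len(targets), dtype=float)
    lo, hi = w.min(), w.max()
    for j, t in enumerate(targets):
        if t < lo or t > hi:
            raise ValueError(f"target week {t} outside observed span [{lo}, {hi}]")
        order = sorted(range(len(w)), key=lambda i: (abs(w[i] - t), w[i]))
        sel = sorted(order[:3])
        xw, xv = w[sel], v[sel]
        val = 0.0
        for a in range(3):
            basis = 1.0
            for b in range(3):
                if b != a:
                    basis *= (t - xw[b]) / (xw[a] - xw[b])
            val += xv[a] * basis
        out[j] = np.clip(val, bounds[0], bounds[1])
    return out


def interpolate_series(series: pd.DataFrame, target_weeks=(2, 4, 5),
                       variables=("pain", "prsi", "feel_calm",
                                  "feel_energy", "feel_sad")) -> pd.DataFrame:
    """Impute unobserved target weeks for every patient that needs them.

    Observed values are never altered; imputed feeling items are rounded back
    to the 1..6 ordinal grid. Returns a new series table with the imputed
    values in place (``observed`` stays False on imputed rows).
    """
    out = series.copy()
    bounds = {"pain": (0.0, 10.0), "prsi": (0.0, 10.0)}
    for pid, grp in out.groupby("patient_id", sort=False):
        missing = grp[~grp["observed"].astype(bool) &
                      grp["week"].isin(target_weeks)]
        if missing.empty:
            continue
        obs = grp[grp["observed"].astype(bool)]
        for var in variables:
            vals = obs[[var, "week"]].dropna()
            filled = quadratic_interpolate(
                vals["week"], vals[var], missing["week"].to_numpy(),
                bounds=bounds.get(var, (1.0, 6.0)))
            if var.startswith("feel"):
                filled = np.round(filled)
            out.loc[missing.index, var] = filled
    return out


@dataclass(frozen=True)
class ResponderStatus:
    patient_id: str
    threshold: float
    horizon_week: int
    is_responder: bool
    pct_change: float


def derive_responder(pain_baseline: float, pain_horizon: float,
                     threshold: float, patient_id: str = "",
                     horizon_week: int = 6) -> ResponderStatus:
    """Responder iff ``(pain0 - pain_t)/pain0 >= threshold`` (boundary inclusive)."""
    if not pain_baseline > 0:
        raise ValueError(f"baseline pain must be > 0, got {pain_baseline}")
    if np.isnan(pain_horizon):
        raise ValueError(f"pain at horizon week {horizon_week} is missing")
    pct = (pain_baseline - pain_horizon) / pain_baseline
    return ResponderStatus(patient_id, threshold, horizon_week,
                           bool(pct >= threshold), float(pct))


def responder_table(series: pd.DataFrame, thresholds=(0.3, 0.5),
                    horizon_week: int = 6) -> pd.DataFrame:
    """Per-patient responder flags at each threshold, from the weekly series."""
    rows = []
    for pid, grp in series.groupby("patient_id", sort=False):
        grp = grp.set_index("week")
        p0 = grp.loc[0, "pain"]
        if horizon_week not in grp.index:
            continue
        pt = grp.loc[horizon_week, "pain"]
        if np.isnan(pt):
            continue
        row = {"patient_id": pid, "pain_baseline": p0, "pain_horizon": pt,
               "pct_change": (p0 - pt) / p0}
        for q in thresholds:
            row[f"responder_{int(q * 100)}"] = row["pct_change"] >= q
        rows.append(row)
    return pd.DataFrame(rows)
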