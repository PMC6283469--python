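"""Canonical lagged-regression predictor dictionary and reference coefficient sets.

The weekly pain score ``y(t)`` of a patient in phenotype cluster ``c`` follows a
sparse lagged linear model without intercept::

    y(t) = b1*pain(t-1) + b2*PRSI(t) + b3*PRSI(t-3) + b4*dose(t-3)
         + b5*1[age 75+] + b6*calm(0) + b7*energy(0)

where PRSI is the 0-10 pain-related sleep-interference score, dose is the daily
pregabalin dose in mg, and calm/energy are the baseline "general feeling" items
on a 1 (always) .. 6 (never) ordinal scale.

``CLUSTER_COEFFS`` holds one empirically calibrated coefficient set per cluster;
they define the six synthetic response phenotypes that the cohort generator
emulates and serve as ground truth in parameter-recovery tests.
"""

from __future__ import annotations

# symbolic name -> design-matrix column
PREDICTORS: dict[str, str] = {
    "x1": "pain_lag1",
    "x2": "prsi_lag0",
    "x3": "prsi_lag3",
    "x4": "dose_lag3",
    "x5": "age_75plus",
    "x6": "feel_calm_t0",
    "x7": "feel_energy_t0",
}

COLUMN_TO_SYMBOL = {v: k for k, v in PREDICTORS.items()}

# per-cluster coefficient maps over the symbolic predictor names (no intercept)
CLUSTER_COEFFS: dict[int, dict[str, float]] = {
    1: {"x1": 0.6229, "x2": 0.2461, "x4": 0.0002, "x6": 0.0354},
    2: {"x1": 0.7590, "x2": 0.1417, "x3": -0.0455, "x4": 0.0002,
        "x5": 0.1039, "x6": 0.0557},
    3: {"x1": 0.7605, "x2": 0.2393, "x3": -0.0707, "x4": 0.0002, "x7": 0.0162},
    4: {"x1": 0.6294, "x2": 0.2146, "x4": 0.0003, "x6": 0.0671, "x7": 0.0043},
    5: {"x1": 0.6415, "x2": 0.2234, "x6": 0.0150, "x7": 0.0133},
    6: {"x1": 0.6652, "x2": 0.1945, "x6": 0.0107, "x7": 0.0449},
}


def coeffs_by_column(cluster: int) -> dict[str, float]:
    """Cluster coefficient map keyed by design-matrix column name."""
    return {PREDICTORS[sym]: b for sym, b in CLUSTER_COEFFS[cluster].items()}
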