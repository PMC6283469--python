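"""Coarsened exact matching (CEM) of RCT patients to OS clusters.

Covariates are coarsened to clinically conventional bins (the four age groups,
the three WHO BMI groups, moderate 4-6 / severe 7-10 baseline pain, mild 0-3 /
moderate 4-6 / severe 7-10 baseline PRSI; dichotomous variables unchanged);
patients sharing a bin signature form a stratum, and only strata containing
both OS and RCT members are retained. Imbalance is the multivariate L1
statistic: half the summed absolute difference between the two groups'
relative stratum frequencies (0 identical, 1 disjoint). An RCT patient is
evaluated against every cluster independently, so it may match several.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import age_group_of, bmi_group_of


def pain_category(pain: float) -> str:
    if 4.0 <= pain < 7.0:
        return "moderate"
    if 7.0 <= pain <= 10.0:
        return "severe"
    raise ValueError(f"baseline_pain {pain} outside all bins [4,10]")


def prsi_category(prsi: float) -> str:
    if 0.0 <= prsi < 4.0:
        return "mild"
    if prsi < 7.0:
        return "moderate"
    if prsi <= 10.0:
        return "severe"
    raise ValueError(f"baseline_prsi {prsi} outside all bins [0,10]")


def _checked(fn: Callable[[float], str], name: str) -> Callable[[float], str]:
    def wrapped(x):
        try:
            return fn(float(x))
        except ValueError as err:
            raise ValueError(f"variable {name!r}: {err}") from None
    return wrapped


@dataclass
class CoarseningScheme:
    """Per-variable coarsening: identity for categorical, bins for numeric."""

    categorical: tuple[str, ...] = ("gender", "insulin", "depression",
                                    "gabapentin", "monotherapy")
    numeric_bins: dict[str, Callable] = field(default_factory=lambda: {
        "age_years": _checked(age_group_of, "age_years"),
        "bmi": _checked(bmi_group_of, "bmi"),
        "baseline_pain": _checked(pain_category, "baseline_pain"),
        "baseline_prsi": _checked(prsi_category, "baseline_prsi"),
    })

    @property
    def variables(self) -> tuple[str, ...]:
        return self.categorical + tuple(self.numeric_bins)


def coarsen(record, scheme: CoarseningScheme | None = None) -> tuple:
    """Deterministic stratum signature of one record."""
    scheme = scheme or CoarseningScheme()
    sig = [record[v] for v in scheme.categorical]
    sig += [fn(record[v]) for v, fn in scheme.numeric_bins.items()]
    return tuple(sig)


def coarsen_frame(patients: pd.DataFrame,
                  scheme: CoarseningScheme | None = None) -> pd.Series:
    scheme = scheme or CoarseningScheme()
    return pd.Series([coarsen(row, scheme) for _, row in patients.iterrows()],
                     index=patients.index)


def l1_imbalance(sig_a, sig_b, weights_a=None, weights_b=None) -> float:
    """½ Σ_s |f_s − g_s| over stratum relative frequencies (optionally weighted)."""
    sig_a, sig_b = list(sig_a), list(sig_b)
    if not sig_a or not sig_b:
        raise ValueError("both groups must be nonempty")
    wa = np.ones(len(sig_a)) if weights_a is None else np.asarray(weights_a, float)
    wb = np.ones(len(sig_b)) if weights_b is None else np.asarray(weights_b, float)
    fa = pd.Series(wa).groupby(pd.Series(sig_a)).sum() / wa.sum()
    fb = pd.Series(wb).groupby(pd.Series(sig_b)).sum() / wb.sum()
    strata = fa.index.union(fb.index)
    return float(0.5 * (fa.reindex(strata, fill_value=0.0)
                        - fb.reindex(strata, fill_value=0.0)).abs().sum())


@dataclass
class MatchResult:
    cluster_id: int
    strata: dict                  # signature -> (list of OS ids, list of RCT ids)
    matched_os: list
    matched_rct: list
    rct_weights: dict             # RCT patient id -> CEM weight
    l1_before: float
    l1_after: float | None        # CEM-weighted L1 on matched sample
    l1_after_unweighted: float | None
    imbalance_reduction_pct: float | None


def match_cluster(os_members: pd.DataFrame, rct_pool: pd.DataFrame,
                  scheme: CoarseningScheme | None = None,
                  cluster_id: int = 0) -> MatchResult:
    """Match an RCT pool to one OS cluster on exact coarsened strata.

    ``l1_before`` compares the OS cluster with the full RCT pool;
    ``l1_after`` is the CEM-weighted L1 on the matched sample (zero by
    construction of exact strata and the equalizing weights — it is computed,
    not assumed). The unweighted matched-sample L1 is reported alongside.
    """
    scheme = scheme or CoarseningScheme()
    if len(os_members) == 0:
        raise ValueError("cluster must have at least one OS member")
    os_sig = coarsen_frame(os_members, scheme)
    rct_sig = coarsen_frame(rct_pool, scheme)
    l1_before = l1_imbalance(os_sig, rct_sig)

    strata: dict = {}
    for sig in sorted(set(os_sig) | set(rct_sig)):
        os_ids = list(os_members.loc[os_sig == sig, "patient_id"])
        rct_ids = list(rct_pool.loc[rct_sig == sig, "patient_id"])
        strata[sig] = (os_ids, rct_ids)

    common = {s: v for s, v in strata.items() if v[0] and v[1]}
    matched_os = [pid for v in common.values() for pid in v[0]]
    matched_rct = [pid for v in common.values() for pid in v[1]]
    if not common:
        warnings.warn(f"cluster {cluster_id}: no common strata; empty match")
        return MatchResult(cluster_id, strata, [], [], {}, l1_before,
                           None, None, None)

    n_os_m, n_rct_m = len(matched_os), len(matched_rct)
    rct_weights, m_sig_os, m_sig_rct, w_rct = {}, [], [], []
    for sig, (os_ids, rct_ids) in common.items():
        w = (len(os_ids) / n_os_m) / (len(rct_ids) / n_rct_m)
        for pid in rct_ids:
            rct_weights[pid] = w
        m_sig_os += [sig] * len(os_ids)
        m_sig_rct += [sig] * len(rct_ids)
        w_rct += [w] * len(rct_ids)
    l1_after = l1_imbalance(m_sig_os, m_sig_rct, weights_b=w_rct)
    l1_after_unw = l1_imbalance(m_sig_os, m_sig_rct)
    reduction = (100.0 * (l1_before - l1_after) / l1_before
                 if l1_before > 0 else None)
    return MatchResult(cluster_id, strata, matched_os, matched_rct, rct_weights,
                       l1_before, l1_after, l1_after_unw, reduction)


def match_all(patients: pd.DataFrame, labels: pd.Series,
              scheme: CoarseningScheme | None = None) -> dict[int, MatchResult]:
    """Run CEM per cluster; RCT patients may appear in several clusters."""
    scheme = scheme or CoarseningScheme()
    os_df = patients[patients["source"] == "OS"]
    rct_df = patients[patients["source"] == "RCT"]
    results = {}
    for c in sorted(labels.unique()):
        members = os_df[os_df["patient_id"].map(labels) == c]
        results[int(c)] = match_cluster(members, rct_df, scheme, cluster_id=int(c))
    return results
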