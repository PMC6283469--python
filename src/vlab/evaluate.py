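"""Study-level metrics: responder-prediction PPV/accuracy, pairwise Fisher
cluster comparisons, covariate-combination coverage, cohort accounting.

The responder "prediction" for a simulated patient follows the majority rule:
a patient is predicted to respond iff more than half of the simulated
instances respond. Fisher pair counts are tallied at p < 0.05 with no
multiplicity correction (a deliberate, documented convention). 2x2 tables use
the exact two-sided (point-probability) test; larger r x c tables use a
seeded Monte-Carlo Freeman-Halton p-value over tables drawn with fixed
margins.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AGE_GROUPS, BMI_GROUPS


@dataclass
class ConfusionSummary:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def ppv(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "tp": self.tp, "fp": self.fp,
                "tn": self.tn, "fn": self.fn, "ppv": self.ppv,
                "accuracy": self.accuracy}


def confusion(predicted, truth, threshold: float) -> ConfusionSummary:
    """Confusion summary of paired boolean responder labels."""
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if len(pred) != len(true):
        raise ValueError("predicted and true labels must be paired")
    return ConfusionSummary(
        threshold,
        tp=int((pred & true).sum()), fp=int((pred & ~true).sum()),
        tn=int((~pred & ~true).sum()), fn=int((~pred & true).sum()))


def fisher_exact_table(table: np.ndarray, rng=None, n_mc: int = 2000) -> float:
    """Two-sided Fisher's exact p for an r x c contingency table.

    2x2 tables are exact (point-probability method); larger tables use a
    Monte-Carlo Freeman-Halton estimate: tables are drawn with the observed
    margins (Patefield sampler) and the p-value is the fraction whose point
    probability does not exceed the observed one (with the +1 correction).
    """
    t = np.asarray(table, dtype=int)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    if t.shape == (2, 2):
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    rng = np.random.default_rng(0) if rng is None else rng

    def log_point_prob(x):
        # multivariate hypergeometric point log-probability given margins
        from scipy.special import gammaln
        r, c, n = x.sum(axis=1), x.sum(axis=0), x.sum()
        return (gammaln(r + 1).sum() + gammaln(c + 1).sum()
                - gammaln(n + 1) - gammaln(x + 1).sum())

    obs = log_point_prob(t)
    sampler = stats.random_table(t.sum(axis=1), t.sum(axis=0))
    draws = sampler.rvs(n_mc, random_state=rng)
    lp = np.array([log_point_prob(d) for d in draws])
    hits = int((lp <= obs + 1e-9).sum())
    return float((hits + 1) / (n_mc + 1))


def pairwise_fisher(groups: dict, variable_values: pd.Series,
                    alpha: float = 0.05, rng=None) -> dict:
    """Count significant pairwise cluster differences for one variable.

    ``groups`` maps cluster id -> patient index; ``variable_values`` holds the
    categorical value per patient index. For every unordered cluster pair the
    2 x L table of level counts is tested; the number of pairs with p < alpha
    is tallied (15 pairs for six clusters).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if variable_values.nunique() < 2:
        warnings.warn("variable constant overall; no significant pairs")
    levels = sorted(variable_values.dropna().unique())
    pvals = {}
    for a, b in itertools.combinations(sorted(groups), 2):
        ca = variable_values.loc[groups[a]].value_counts()
        cb = variable_values.loc[groups[b]].value_counts()
        tab = np.array([[int(ca.get(l, 0)) for l in levels],
                        [int(cb.get(l, 0)) for l in levels]])
        pvals[(a, b)] = fisher_exact_table(tab, rng=rng)
    n_sig = sum(1 for p in pvals.values() if p < alpha)
    return {"n_pairs": len(pvals), "n_significant": n_sig, "pvalues": pvals}


def cross_dataset_fisher(groups_a: dict, values_a: pd.Series,
                         groups_b: dict, values_b: pd.Series,
                         alpha: float = 0.05, rng=None) -> dict:
    """All cross-dataset cluster pairs (6 x 6 = 36) for one variable."""
    rng = np.random.default_rng(0) if rng is None else rng
    levels = sorted(set(values_a.dropna().unique())
                    | set(values_b.dropna().unique()))
    pvals = {}
    for a in sorted(groups_a):
        ca = values_a.loc[groups_a[a]].value_counts()
        for b in sorted(groups_b):
            cb = values_b.loc[groups_b[b]].value_counts()
            tab = np.array([[int(ca.get(l, 0)) for l in levels],
                            [int(cb.get(l, 0)) for l in levels]])
            pvals[(a, b)] = fisher_exact_table(tab, rng=rng)
    n_sig = sum(1 for p in pvals.values() if p < alpha)
    return {"n_pairs": len(pvals), "n_significant": n_sig, "pvalues": pvals}


COVERAGE_LEVELS = {
    "gender": ("F", "M"),
    "age_group": AGE_GROUPS,
    "bmi_group": BMI_GROUPS,
    "insulin": (0, 1),
    "gabapentin": (0, 1),
    "pain_category": ("moderate", "severe"),
}


@dataclass
class CombinationCoverage:
    n_possible: int
    n_observed: int

    @property
    def pct(self) -> float:
        return 100.0 * self.n_observed / self.n_possible

    def to_dict(self) -> dict:
        return {"n_possible": self.n_possible, "n_observed": self.n_observed,
                "pct": self.pct}


def combination_coverage(patients: pd.DataFrame,
                         levels: dict | None = None) -> CombinationCoverage:
    """Fraction of the characteristic-combination grid present in a cohort.

    Default grid: gender(2) x age group(4) x BMI group(3) x insulin(2) x
    prior gabapentin(2) x baseline pain category(2) = 192 combinations.
    """
    from .matching import pain_category
    levels = levels or COVERAGE_LEVELS
    n_possible = int(np.prod([len(v) for v in levels.values()]))
    frame = patients.copy()
    if "pain_category" in levels and "pain_category" not in frame.columns:
        frame["pain_category"] = frame["baseline_pain"].map(pain_category)
    for var, lv in levels.items():
        bad = set(frame[var].unique()) - set(lv)
        if bad:
            raise ValueError(f"unknown level(s) {sorted(map(str, bad))} "
                             f"for {var!r}")
    observed = frame[list(levels)].drop_duplicates()
    return CombinationCoverage(n_possible, int(len(observed)))


def cohort_accounting(n_os: int, n_matched_os: int, n_rct: int,
                      n_matched_rct: int) -> dict:
    """Bookkeeping of the matching stage, with derived percentages."""
    return {
        "n_os": n_os,
        "n_rct": n_rct,
        "n_matched_os": n_matched_os,
        "n_matched_rct": n_matched_rct,
        "os_match_pct": 100.0 * n_matched_os / n_os if n_os else None,
        "rct_match_pct": 100.0 * n_matched_rct / n_rct if n_rct else None,
        "n_matched_total": n_matched_os + n_matched_rct,
        "n_validation_os": n_os - n_matched_os,
    }
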