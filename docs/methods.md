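# Methods

This note documents the models, numerical conventions, and design choices
behind `vlab`, and what the synthetic-data experiments do and do not show.

## Synthetic cohort generator

The pipeline was designed against proprietary clinical cohorts (a German
open-label observational study and nine placebo-controlled pregabalin trials),
so all testing runs on a generator that emulates their structure.

**Mixture.** Each patient belongs to one of six latent phenotype clusters,
drawn from weights defaulting to the reference cohort cluster-size mix
(431, 189, 437, 266, 127, 316)/1766. Each cluster carries marginals for the
nine baseline variables plus pDPN-duration bins, three "general feeling"
items (6-level always-to-never scale, coded 1 = Always … 6 = Never and
treated as numeric), and maintenance-dose frequencies over
{75, 150, 300, 600} mg/day. Numeric covariates are Gaussian draws truncated
to their scales (baseline pain to [4, 10], reflecting the ≥ 4 trial-inclusion
rule; truncation rather than resampling is the bounded-NRS convention used
throughout).

**Trajectories.** Weekly pain follows the cluster's lagged equation (see
`vlab/equations.py`) plus Gaussian noise with SD `noise_sd` (default 0.5 NRS
points, consistent with per-cluster regression RMSEs of ≈ 0.5). PRSI is
generated as `0.6·pain(t−1) + offset·ρ^(t−1) + AR(1) noise` with
`offset = PRSI(0) − 0.6·pain(0)`, AR coefficient 0.5 and innovation SD 0.8.
The geometric offset decay (ρ = 0.3) encodes the reciprocal pain–sleep
improvement under treatment and was calibrated once so that the cohort-level
50%-responder rate sits near the ≈ 0.80 marginal the phenotype profiles
carry; it was fixed before any downstream evaluation. Lag-3 terms are clamped
to week 0 for weeks 1–2; the regression design drops those weeks, so fitting
only ever sees unclamped lags. Dose starts at 150 mg/day (75 if the drawn
maintenance dose is 75) and jumps to the maintenance dose at week 1. Feelings
follow a ±1 ordinal random walk (p = 0.15 each direction) from baseline.

**Observation schedule.** OS patients are observed at weeks {0, 1, 3, 6}
only; other weeks are masked (dose, a prescription, stays known). RCT
patients are fully observed for 6 weeks (28.9%) or 12/13 weeks (71.1%).

**Selection bias.** `inject_selection_bias(strength)` perturbs OS covariates
toward insulin use, depression history, combination therapy, and higher age
with probabilities proportional to `1 − exp(−strength)`; strength 0 is a
no-op. This is our construct — the true OS covariate-generating process is
unknown — and exists so CEM has realistic imbalance to remove.

**What passing tests show.** The generator matches the marginal and dynamic
structure the pipeline assumes, not any real joint distribution: real cohorts
have missingness beyond the visit schedule, dose titration paths, dropouts,
and covariate dependence the mixture does not encode. Green tests certify the
pipeline's internal correctness and self-consistency, not clinical
performance.

## Clustering

Gower dissimilarity averages per-variable terms: |Δ|/range for the four
numeric variables (age, BMI, baseline pain, baseline PRSI — Gower's range
normalization makes prior standardization moot), 0/1 mismatch for the five
dichotomous ones. Zero-range variables are excluded with a warning.
Agglomeration is scipy's Ward linkage on that matrix; Ward formally assumes
Euclidean geometry and Gower matrices are only approximately Euclidean-
embeddable — we accept the mismatch because the semipartial-R² homogeneity
diagnostic belongs to the Ward family. Semipartial R² of merge i is
h²ᵢ/2 divided by the total dispersion Σd²/n (the Lance–Williams identity for
Ward heights); the cut is fixed at k = 6 by configuration, with the R² trace
reported for transparency. Cluster ids are deterministic (decreasing size,
ties by first row); scipy's merge order resolves ties by lowest pair index.

## Coarsened exact matching

Matching variables are the coarsened nine clustering variables: age → four
groups (0–44, 45–64, 65–74, 75+), BMI → WHO bins (< 25, 25–< 30, ≥ 30),
baseline pain → moderate [4, 7) / severe [7, 10], baseline PRSI → mild
[0, 4) / moderate [4, 7) / severe [7, 10], dichotomous variables unchanged.
RCT patients are evaluated against every cluster independently and may match
several. Per cluster we report L1 on the full pool (before), the unweighted
matched-set L1, and the CEM-weighted L1 (weights equalize stratum
frequencies), defaulting to the weighted variant for the percent imbalance
reduction, 100·(L1_before − L1_after)/L1_before. On the matching strata the
weighted L1 is zero by construction — we compute it anyway (and verify it
against a brute-force stratum oracle) rather than assert it; the unweighted
value is the informative residual-imbalance diagnostic.

## Lagged regressions

The candidate set spans pain lags 1–3, PRSI lags 0–3, dose lags 0–3 (raw
mg/day — the ≈ 2·10⁻⁴ dose coefficients imply mg units), the three baseline
feeling items, and 0/1 dummies for age 75+, gender, insulin, depression,
prior gabapentin, and monotherapy. Rows exist for weeks where every lag is
available (weeks 3–6 of a 6-week series). Models carry no intercept: the
selected equations pass through the origin, and an all-zero predictor vector
predicts zero pain.

Stepwise selection uses Gaussian likelihood-ratio tests with conventional
thresholds (p < 0.05 to enter, > 0.10 to remove); collinear candidates are
skipped. Penalized re-estimation standardizes columns to unit SD, tunes λ by
10-fold CV at the CV minimum (not 1-SE), and maps coefficients back to the
raw scale; adaptive LASSO weights are 1/|b_ML|; elastic net searches
l1_ratio ∈ {0.2, 0.5, 0.8, 0.95}. `lambda_ = 0` reduces exactly to OLS. When
a matched cluster is too small for the full candidate set, candidates are
first screened by cross-correlation rank (the screened-subset variant of the
two-stage design); below 10 design rows no model is fitted and the cluster is
excluded with a warning. Adjusted R² uses the final design's n and p with a
centered total sum of squares; RMSE is √(SSR/n).

## Microsimulation

Cluster assignment is an ensemble: a kNN vote over Gower distance to the
training cohort (k = round(√n), the square-root convention used throughout)
and fuzzy c-means memberships u_c = 1/Σ_j (d_c/d_j)² against the centroids
(fuzzifier m = 2; zero distance ⇒ full membership). Agreement decides;
otherwise the method with the higher normalized confidence (vote fraction vs
maximum membership) wins — the combination rule was an open design point and
this is our choice.

Each weekly step finds the k cluster members nearest (Euclidean) to the
instance's evolving pain/PRSI history, standardized per (variable, week) by
the within-cluster SD; next-week PRSI is an i.i.d. draw from the neighbors'
empirical week-(t+1) values (no kernel smoothing — reproducible and
assumption-free), dose is drawn from the cluster's 50%-responders' week-t
doses (whole-cluster fallback with a warning when a cluster has no
responders), and pain advances through the cluster regression, truncated to
[0, 10] after each update. The neighbor set is re-selected every week on the
evolving state. Instance i uses RNG stream (seed, i), so results are
reproducible and order-independent. Responder fractions compare each
instance's week-6 pain with the novel patient's baseline at the inclusive
≥ 30%/≥ 50% reduction thresholds.

## Monotonicity and extrapolation

Monotonicity is the mean step sign (1/T)·Σ sign(p_{t+1} − p_t) ∈ [−1, 1]
(positive = rising pain); a Spearman-vs-time statistic is the documented
alternative but mean step sign matches the ±0.2 working thresholds and the
"extent of monotone movement" reading. Categories: < −0.2, [−0.2, 0.2]
(inclusive), > 0.2. Cloud monotonicity is the mean of per-instance values.
Extrapolation finds the round(√pool) long-duration RCT patients nearest in
(week-6 pain, monotonicity) — each indicator standardized by the pool SD,
since the raw scales differ by ~5× — and takes the majority of their observed
week-6 → week-12/13 responder transitions; ties predict "maintained" (the
modal transition). Per-category accuracy is evaluated on a held-out half of
the pool; ROC curves vary the neighbor-vote fraction threshold one-vs-rest.
The ±0.2 thresholds are fixed constants here; an optional threshold search is
deliberately not run inside the evaluation to avoid tuning on the data being
scored.

## Evaluation

Responder prediction for a simulated patient uses the majority rule (> 50% of
instances respond). PPV = TP/(TP+FP) (reported missing when no positive
predictions exist), accuracy = (TP+TN)/total. Pairwise cluster comparisons
use two-sided Fisher's exact tests per variable — exact for 2×2 tables; for
r×c tables a seeded Monte-Carlo Freeman–Halton estimate (2000 tables with
fixed margins via the Patefield sampler; the p-value is the fraction of
tables whose point probability does not exceed the observed one, with the
+1 correction) — tallied at p < 0.05 with no multiplicity correction, a
deliberate convention that inflates per-family error and is kept for
comparability. Combination coverage enumerates the
gender × age-group × BMI-group × insulin × prior-gabapentin × pain-category
grid (2·4·3·2·2·2 = 192 cells).

## Problem sizes

Unit tests run cohorts of 200–300 OS patients; the acceptance suite and
`scripts/acceptance.py` use the demo configuration — 600 OS, 300 RCT,
100 virtual instances per patient, 40 simulated validation patients,
2000 Monte-Carlo Fisher draws — which exercises every stage in about half a
minute on one CPU. Full-scale runs (2642 OS / 1320 RCT, 1000 instances) use
the same code paths via `CohortSpec` defaults and `--n` options.

## Known limitations

- Ward-on-Gower is a pragmatic pairing, not a theoretically clean one; merge
  heights are only approximately ESS increments.
- The stepwise stage's likelihood-ratio p-values ignore the weekly repeated
  measures within patient (no mixed effects or robust covariance), matching
  the plain lagged-regression design.
- The Monte-Carlo Fisher p-values carry ~1% standard error at 2000 draws;
  tallies at p < 0.05 are insensitive to this except for borderline pairs.
- Simulated responder fractions at the demo scale are often extreme (0 or 1)
  because the synthetic phenotypes are strongly responder-skewed; PPV/accuracy
  on synthetic data therefore read higher than any real-data analogue would.
- The extrapolation's "increased pain" category is rare in synthetic pools,
  so its accuracy estimate is unstable at small n.
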