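# vlab — virtual-laboratory prediction of pregabalin pain response in pDPN

Painful diabetic peripheral neuropathy (pDPN) patients respond very unevenly
to pregabalin, and the observational cohorts that best reflect routine care
carry heavy covariate bias. `vlab` implements an end-to-end "virtual
laboratory" that integrates observational-study (OS) and randomized
controlled-trial (RCT) data to predict an individual patient's weekly pain
trajectory and responder status:

1. **Phenotype clustering** — hierarchical (Ward) clustering of OS patients on
   nine mixed-type baseline variables (gender, age, BMI, insulin use,
   depression history, pregabalin monotherapy, prior gabapentin, baseline pain,
   baseline pain-related sleep interference) using the Gower distance, with
   per-merge semipartial R² diagnostics and a six-cluster cut.
2. **Coarsened exact matching (CEM)** — RCT patients are matched to each OS
   cluster on coarsened covariate strata; multivariate L1 imbalance
   (½ Σₛ |fₛ − gₛ|) is reported before and after matching.
3. **Lagged pain regressions** — per cluster, weekly pain y(t) is modeled
   without intercept as

   y(t) = b₁·pain(t−1) + b₂·PRSI(t) + b₃·PRSI(t−3) + b₄·dose(t−3)
        + b₅·1[age 75+] + b₆·calm(0) + b₇·energy(0)

   selected from a larger lag/covariate candidate set by forward/backward
   maximum-likelihood stepwise selection and re-estimated with LASSO
   (adaptive LASSO and elastic net are available and give near-identical
   fits). Models are validated on the OS patients that did not match.
4. **Microsimulation** — a novel patient is assigned to a cluster by a
   kNN + supervised fuzzy c-means ensemble; 1000 virtual instances are then
   advanced week by week, sampling time-varying covariates from the empirical
   distributions of the k = √(cluster size) nearest neighbors and dose from
   the cluster's 50%-responders, yielding a trajectory cloud, the median
   week-6 pain, and responder fractions at the 30% and 50% pain-reduction
   thresholds.
5. **Monotonicity extrapolation** — the trajectory cloud's monotonicity
   (mean weekly step sign, in [−1, 1], classified with ±0.2 thresholds)
   and median week-6 pain place the simulated patient among 12/13-week RCT
   patients, whose observed week-6 → end-of-study responder transitions vote
   on whether the response will be maintained, improve, or fade.

Because the underlying clinical cohorts are proprietary, the package ships a
fully specified synthetic-cohort generator (`vlab.cohort`) that reproduces the
structural features the pipeline consumes: a six-phenotype mixture with
reference-cohort-style marginals, trajectories generated from the cluster equations
plus noise, the sparse OS visit schedule {0, 1, 3, 6} (filled by second-order
Lagrange interpolation), and 6- vs 12/13-week RCT follow-up.

## Worked example

```python
import pandas as pd
from vlab import (CohortSpec, generate_cohort, interpolate_series,
                  hierarchical_cluster, assign_cluster, simulate,
                  ClusterSimulationContext, extrapolate)
from vlab.regression import FittedClusterModel
from vlab.equations import coeffs_by_column
from vlab.monotonicity import build_long_pool

spec = CohortSpec(n_os=600, n_rct=300, seed=1)
patients, series = generate_cohort(spec)
series = interpolate_series(series)                      # fill weeks 2, 4, 5
os_patients = patients[patients["source"] == "OS"].reset_index(drop=True)
model = hierarchical_cluster(os_patients, n_clusters=6)

novel = pd.Series(dict(patient_id="novel-1", gender="F", age_years=62,
                       age_group="45-64", bmi=31.0, insulin=0, depression=0,
                       gabapentin=0, monotherapy=1, baseline_pain=7.5,
                       baseline_prsi=6.0, feel_calm=4, feel_energy=5, feel_sad=4))
c, conf, _ = assign_cluster(novel, model, os_patients)

members = os_patients[os_patients["patient_id"].map(model.labels) == c]
context = ClusterSimulationContext.build(c, members, series)
reg = FittedClusterModel(c, "reference", coeffs_by_column(c), 1.0, 0.0)
res = simulate(novel, reg, context, n_instances=1000, seed=7)
pool = build_long_pool(patients, series)
rep = extrapolate(res.median_final_pain, res.cloud_monotonicity, pool)
```

This prints (via the obvious `print` calls):

```
cluster sizes: {1: 144, 2: 139, 3: 106, 4: 100, 5: 56, 6: 55}
assigned cluster: 4 (confidence 1.00)
median week-6 pain: 2.61
responder fraction (50%/30%): 1.000 / 1.000
cloud monotonicity: -0.995
beyond week 6: maintained (votes {'decreased_pain': 0, 'maintained': 15, 'increased_pain': 0})
```

Read: the patient lands in the all-female monotherapy phenotype; every one of
the 1000 virtual instances reaches at least a 50% pain reduction by week 6
(median final pain 2.61 on the 0–10 scale, down from 7.5); the trajectory
cloud falls almost strictly (monotonicity −0.995, "below-negative" category);
and all 15 nearest long-duration RCT neighbors kept their week-6 responder
status through weeks 12–13, so the predicted response is durable.

The same pipeline runs end to end from the shell:

```bash
vlab run --out results/demo --seed 1        # synth → … → report.md
vlab report --in results/demo
```

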