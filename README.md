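# readmit-rsf

Random-survival-forest risk scoring for 30-day hospital readmission, built as
a tested, reusable pipeline: a from-scratch survival forest with log-rank node
splitting and Nelson–Aalen terminal hazards, PPV-calibrated 0–100 risk
scoring with Low/Intermediate/High tiers, stratified evaluation (risk-bin
readmission rates, tiered readmission-free curves, binary c-statistic), and
unsupervised high-risk phenotype discovery by PCA + K-means with an
elbow-rule cluster count.

The package is aimed at biostatisticians and clinical-informatics engineers
who want to study or reproduce this class of population risk model.  Real
health-information-exchange data cannot be redistributed, so a first-class
synthetic EHR generator emulates the statistical structure the method relies
on — encounter-level look-back histories, a discrete-time readmission hazard
driven by chronic-disease burden, prior inpatient utilization and age, and
planted high-risk patient archetypes — with the generating truth recorded so
every stage can be validated against known ground truth.

## The model

Each index inpatient discharge *l* carries predictors `x_l`, an observed time
`T_l` (days to readmission, censored at 30) and an event indicator.  Survival
trees choose, at every node, the predictor/cut pair `(x, c)` maximizing the
absolute standardized log-rank statistic over the node's distinct event times
`t_i`:

    F(x, c) = Σ_i (d_i1 − Y_i1 d_i / Y_i)
              / sqrt( Σ_i (Y_i1/Y_i)(1 − Y_i1/Y_i)((Y_i − d_i)/(Y_i − 1)) d_i )

with `Y_i1 = #{T_l ≥ t_i and x_l ≤ c}`.  Terminal nodes carry the
Nelson–Aalen cumulative hazard `H(t) = Σ_{t_i ≤ t} d_i / Y_i`, and the forest
prediction is the ensemble average `H^e(t|x) = (1/ntree) Σ_b H^b(t|x)` over
`ntree` bootstrap-grown trees.

Because the four chronic-disease × inpatient-history sub-cohorts are modelled
separately, their hazards live on different scales.  A calibration set maps
each hazard `h` to `score(h) = 100 × PPV(h)` where `PPV(h)` is the fraction of
calibration patients with `H^e ≥ h` who readmitted within 30 days,
regularized to be monotone; scores are tiered as Low (< 30), Intermediate
(30–< 70) and High (≥ 70).  High-risk encounters are finally projected onto
two principal components and clustered with K-means, choosing
`K = max{k : R_k > 0.2}` from the reduction rate
`R_k = (TWSS_{k−1} − TWSS_k)/TWSS_{k−1}` of the total within-cluster sum of
squares.

## Worked example

```python
import numpy as np
from readmit_rsf import (GeneratorConfig, generate_cohort, aggregate_features,
                         variance_filter, SurvivalForest, ForestConfig,
                         fit_calibration, c_statistic, bin_rates)

patients, encounters, index = generate_cohort(
    GeneratorConfig(n_patients=4000, seed=42))
feats = aggregate_features(patients, encounters, index)
idx = index.set_index("index_id")

ids = np.random.default_rng(42).permutation(feats.index.to_numpy())
train, cal, test = np.split(ids, [2000, 3000])
kept = variance_filter(feats.loc[train], 50)

model = SurvivalForest(idx.loc[train, "observed_time"],
                       idx.loc[train, "event_observed"].astype(int),
                       feats.loc[train, kept],
                       config=ForestConfig(ntree=100, seed=42))
res = model.fit()
print(res.summary())

cal_map = fit_calibration(res.predict_risk(feats.loc[cal, kept]),
                          idx.loc[cal, "event_within_30d"].astype(int))
h_test = res.predict_risk(feats.loc[test, kept])
score = cal_map.score(h_test)
y_test = idx.loc[test, "event_within_30d"].astype(int).to_numpy()
print("held-out 30-day c-statistic:",
      round(c_statistic(h_test, y_test).auc, 3))
_, tiers = bin_rates(score, y_test)
for name, t in tiers.items():
    print(f"{name:>12}: n={t['n']:4d}  30-day readmission rate={t['rate']:.3f}")
```

prints

```
Random Survival Forest Results
==============================================
No. samples:                2000
No. events:                 401
No. features:               50
Trees:                      100
mtry:                       8
Min node size to split:     3
Scoring horizon (days):     30
Leaf CHF estimator:         nelson-aalen
Avg. leaves per tree:       329.0
==============================================
held-out 30-day c-statistic: 0.761
         Low: n= 598  30-day readmission rate=0.097
Intermediate: n= 285  30-day readmission rate=0.151
        High: n= 117  30-day readmission rate=0.769
```

The c-statistic says a randomly chosen readmitted patient outranks a
non-readmitted one 76% of the time on the ensemble hazard; the tier rates
show the PPV semantics of the score — patients tiered High (score ≥ 70, i.e.
calibration-set PPV ≥ 0.70) readmitted at 77% on held-out data, against a
~13% cohort average.

The same experiment, end to end and with the facility-balanced
blind-test split, four sub-cohort models and the clustering stage, runs from
a shell:

```bash
readmit-rsf run-all --seed 1 --out runs/demo
```

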