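# Methods

This note records the statistical model, the synthetic-data design and the
numerical choices behind `readmit-rsf`, at the level of detail a maintainer
needs to judge what a passing test suite does and does not establish.

## Outcome and cohort construction

The unit of analysis is an index inpatient discharge: the patient is alive
and not transferred at discharge, and the outcome is an inpatient
readmission to any facility within 30 days.  Predictors are aggregated
strictly from encounters whose *discharge* date lies in the half-open
look-back window `(index_date − 365 d, index_date]`, excluding the index
stay itself (otherwise every patient would trivially have inpatient
history).  Feature groups: visit counts by encounter type (E/O/I/P/R),
accumulated inpatient length of stay, chronic-disease count plus 19
per-condition indicators, total and non-redundant (distinct-code) lab /
prescription / radiology counts plus per-code counts, distinct
primary/secondary diagnosis codes, demographics (age bin, gender, income and
education bands, payer one-hots) and, on synthetic data, the generator's
planted continuous covariates.  "Non-redundant" is read as the number of
distinct codes, the only reading that makes it informative alongside the
total.

Four sub-cohorts partition every cohort by (≥ 1 chronic-disease diagnosis in
look-back) × (≥ 1 prior inpatient admission in look-back); the ≥ 1 threshold
reflects risk rising from the first unit of either exposure.  The
retrospective phase is split at the *facility* level into two subgroups by
exhaustive search (≤ 12 facilities; greedy beyond) minimizing,
lexicographically, the worst monthly absolute inpatient-volume difference
then the worst monthly readmission-rate difference.  Subgroup 1 is divided
70/30 into training and calibration sets by a patient-level seeded draw;
subgroup 2 is the blind test set; rows discharged after the retrospective
period form the prospective phase regardless of facility.  One patient
contributes one index discharge, so patient-level and encounter-level
exclusivity coincide here.

Feature filtering drops zero-variance columns, then ranks the remainder by
sample variance after per-feature min-max scaling and keeps the top `n_keep`
(default 50 at desk scale), ties broken by feature name.  Min-max scaling
makes the ranking scale-free across count, indicator and continuous columns
while preserving each feature's relative dispersion.

## Random survival forest

Trees are grown on with-replacement bootstrap resamples of the training set
(default `ntree = 100` at desk scale; 300 is the classical choice and is the
`ForestConfig` default).  At each node a fresh draw of `mtry = ⌈√p⌉`
candidate predictors is searched over all midpoints between consecutive
distinct values; the split maximizes |F|, the standardized log-rank
statistic, with these conventions:

- variance terms with a single subject at risk (`Y_i = 1`) contribute zero
  (the `(Y_i − 1)` factor is degenerate there and the `p(1−p)` factor
  vanishes simultaneously);
- candidates whose variance sum is non-positive are invalid;
- ties in |F| keep the candidate with the lexicographically smallest feature
  name, then the smallest cut, making tree growth deterministic given the
  seed.

Splitting stops when a node has fewer than `nodesize_min` samples (default
3; 1 grows trees to single-sample purity and is available for the classical
"maximum terminal node size 1" reading), no remaining events, or no valid
candidate.  Leaves store the Nelson–Aalen cumulative hazard of their
samples.  The identity `H = −log S` motivates the cumulative-hazard scale,
but the Nelson–Aalen estimator is used rather than `−log(KM)` because fully
eventful leaves drive the Kaplan–Meier survival to zero and `−log 0`
diverges; a `neg-log-km` estimator (with S floored at `0.5/n`) is available
behind a config switch for comparison.  Predictions average the leaf hazards
over trees; scoring uses `t* = 30` days while training uses the full
observed times.  All randomness flows from one seed through named
substreams (per-tree bootstrap + mtry draws, permutation importance,
calibration split), so identical configs give byte-identical artifacts.

Permutation importance permutes one evaluation-set column at a time and
reports the increase in mean-square error of the monotonely rescaled
ensemble score against the binary 30-day label (the pipeline passes the
calibrated score / 100; standalone use min-max rescales the raw hazard).  A
feature no tree uses has exactly zero importance.  Forward selection starts
from the top-10 features of that ranking, adds batches of 5 in descending
importance, scores each candidate set by sensitivity + specificity − 1 at
the score-70 threshold on the calibration set (sensitivity, specificity and
PPV all being of interest, a single scalar is needed for a stopping rule and
Youden's index is the standard choice), stops after 2 consecutive
non-improvements beyond `tol = 1e-3`, and returns the best set seen.

## PPV calibration and tiers

For a calibration set of (hazard, label) pairs, the raw curve
`PPV(h) = #{label = 1, H ≥ h} / #{H ≥ h}` is evaluated at every distinct
observed hazard ("at or above", so the largest hazard keeps a defined
value).  Finite-sample PPV curves wiggle, so the stored map is the running
maximum of the raw curve over knots ≤ h — the smallest monotone
non-decreasing majorant.  This pins the lowest knot to the full-set PPV
(the cohort prevalence) and leaves well-populated upper knots essentially
untouched.  Scoring uses left-step interpolation (the largest knot not
exceeding h) and clamps outside the knot range; scores are invariant to any
strictly increasing transform of the hazards, which is what makes the four
sub-cohort models comparable on one 0–100 scale.  Tiers: Low < 30 ≤
Intermediate < 70 ≤ High; the cuts are conventional, not optimized, and are
exposed in config.

## Evaluation

Risk-bin analysis reports the 30-day readmission fraction in ten score bins
([0,10), …, [90,100]; the top bin closed so a score of 100 is counted), with
empty bins reported as null rather than a fabricated zero, plus tier-level
aggregates.  Readmission-free curves are Kaplan–Meier product-limit
estimates (via lifelines) at integer days 0–30 per tier.  The c-statistic is
the binary 30-day AUC in its Mann–Whitney midrank form — the tiered
evaluation is a binary-classification surface, not a time-dependent
concordance — and the median time to event is the first day at which the
conditional CDF of event times among 30-day readmitters reaches one half.

## High-risk clustering

Encounters tiered High in the prospective phase are z-scored per feature
(count features differ by orders of magnitude; constant columns dropped),
projected onto the top two principal components (full SVD, component signs
fixed by the largest-magnitude loading), and clustered by Lloyd K-means with
k-means++ seeding, 10 restarts, `max_iter = 300`, `tol = 1e-6`.  For the
TWSS trace each `k ≥ 3` additionally warm-starts one run from the previous
best centers plus the point farthest from its centroid, which guarantees a
non-increasing trace.  `TWSS_1` is computed in closed form (total sum of
squares about the grand mean).  The selected count is the literal rule
`K = max{k : R_k > 0.2}`; the argmax of `R_k` is reported alongside because
the two can disagree, and `K = 1` with a warning when no k qualifies.
`R_k` with a zero denominator is defined as 0.  The default clustering input
is the model's selected feature set (configurable).

## Synthetic cohort design

The generator emulates what the analysis assumes, with the generating model
deliberately different from the fitted one (a discrete-time logistic hazard,
so recovery tests are not circular).  Patient `l` has a constant daily
readmission probability

    h_l = logistic( logit(h0) + β·z_l ),   T_l ~ Geometric(h_l),

with `h0 = 0.001/day` and default log hazard ratios 0.22 per chronic
condition, 0.35 per prior inpatient admission, 0.07 per age bin, 0.28 per
planted signal feature (10 signal + 40 pure-noise standard-normal patient
covariates), and 2.4 for membership in a planted high-risk archetype (10% of
patients).  Background (non-archetype) daily hazard is capped at 0.03 so the
extreme background tail cannot cross the 0.7 30-day-risk line — the planted
archetypes are then exactly the true high-risk stratum, which keeps the
planted cluster count well defined.  These defaults give an overall 30-day
readmission rate near 19%, a background rate near 11%, archetype rates near
80%, and a true-risk AUC of ~0.86 — a realistic regional-cohort regime with
a genuine risk continuum (early designs with a homogeneous background made
the Intermediate tier indistinguishable from Low, which no tiered analysis
would survive).

Archetypes are laid out on a ring: archetype k at angle `θ_k = 2πk/K`
prefers chronic conditions and lab / prescription / radiology codes in a
von-Mises window around its angle (κ = 3.0 for conditions and lab/rx codes,
2.0 for radiology), while member utilization *volumes* are tightly regulated
(fixed encounter counts, fixed per-encounter code counts, random
composition; fixed chronic burden of 5 and 2 prior admissions).  Ring
layouts make the between-archetype variation essentially two-dimensional —
exactly what a rank-2 PCA can retain — and the volume regulation keeps
within-cluster clouds compact and near-isotropic, which the
`R_k > 0.2` elbow rule needs: post-elbow `R_k` depends only on
within-cluster cloud shape, and a noisy radial (volume) axis keeps it above
threshold indefinitely.  Members are otherwise realistic: elevated
emergency/outpatient/recurring utilization, longer stays, older ages.

The calendar spans 24 months with index discharges drawn from month 13
onward, so every index has a full one-year look-back; months 13–18 are the
retrospective phase and months 19–24 the prospective phase.  Post-index
encounters (the readmission itself, occasional follow-ups) are emitted so
leakage tests bite.  No deaths, transfers or loss to follow-up occur within
the horizon by default (the qualification rule removes them);
`censoring_fraction` injects administrative censoring to exercise
censoring-aware code paths.  Identical config + seed reproduces tables byte
for byte.

What the generator does *not* emulate: ICD-coded vocabularies (conditions
and codes are opaque ids), lab values (counts only), missing data (complete
cases), within-patient temporal dynamics of risk, or temporal drift between
the retrospective and prospective phases — so a prospective c-statistic
close to the retrospective one is expected here, and passing tests say
nothing about robustness to real-world drift, coding practice variation or
missingness.

## Study conditions used by the tests

Simulation sizes were chosen so the full suite runs comfortably on one CPU:
discrimination and stratification checks use 10 seeds × 10,000 discharges
(≈5,000 retrospective / 5,000 prospective) with 50 variance-filtered
features and 100-tree forests, and require held-out AUC > 0.70 in ≥ 8/10
seeds plus strictly increasing tier rates; cluster-count recovery uses 10
seeds × 5,000 discharges at planted K ∈ {3, 6}; the feature-selection
recovery experiment uses 3,000 patients with 5 signal features at log-HR 0.6
among 45 noise features and *no* planted archetypes — with archetypes
present, their unobserved 2.4 log-HR dominates the hazard and no method
could rank five weak signals reliably; reproducibility runs the full
pipeline twice at 2,000 discharges and compares artifacts byte for byte.
The desk-scale feature path is ~190 aggregated features → 50 filtered →
forest; the reference protocol's much larger counts are a property of the
private source data, not of the method.

## Known limitations

- The PPV score is a tail functional: the Intermediate *band* rate is
  necessarily below the PPV at its lower edge, so band rates and scores are
  not directly comparable numbers.
- Sub-cohort models require events in every stratum; very small cohorts can
  leave the IP-only stratum empty of events, which is an error by design
  rather than a silent fallback.
- The end-to-end clustering input (tier-High rows under the fitted score)
  contains genuinely high-scoring background patients, so the selected K on
  pipeline output can differ from the planted archetype count even when
  direct recovery on the true high-risk stratum is exact; both numbers are
  reported.
- Tree growth is exact (no histogram binning); complexity is O(n·m) per
  feature per node with m distinct event times, fine at 30-day horizons but
  not tuned for long-horizon data with thousands of distinct times.
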