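# Methods

`bladderpheno` re-implements, as a tested pipeline, an unsupervised
phenotyping analysis of perceived bladder pain in premenopausal women:
symptom questionnaires are scored, symptomatic subjects are partitioned by
two-step clustering, the partition's bootstrap stability is quantified,
the items that drive it are profiled, symptom co-expression is mapped with
a self-organizing map (SOM), and treatment responder rates are compared by
phenotype.  Because the underlying patient-level data are not publicly
deposited, the package ships a synthetic cohort generator calibrated to
the published per-phenotype item summary statistics; every stage is
exercised and tested against that generator.

## Instruments and scoring

Four patient-reported instruments form the battery (52 items):

* **ICSI/ICPI** (O'Leary-Sant): four 0–5 symptom items and four 0–4
  problem items; totals 0–20 and 0–16, their sum (OLS) 0–36.
* **OAB-q SF** symptom scale: items 2–6 and 8, each 1–6.  Scored as the
  raw item sum (range 6–36), keeping totals on the same scale as the
  per-item summary statistics used for calibration, rather than the
  instrument's official 0–100 transform.
* **fGUPI**: eight yes/no pain location/activity items, pain frequency
  (0–5) and severity (0–10), two urinary items (0–5), three bother/QOL
  items (0–3, 0–3, 0–6).  Subscales: pain = binaries + frequency +
  severity (0–23), urinary (0–10), bother (0–12).
* **PFDI-20**: twenty 0–4 items; subscales POPDI-6, CRADI-8 and UDI-6 each
  scored 25 × (mean item), i.e. 0–100, summing to a 0–300 total.

Missing answers raise a scoring error naming the item; scoring functions
accept real-valued answers so per-group mean profiles can be scored
directly (the worked examples and calibration checks rely on this).

Two screening composites are config-driven weighted sums because their
exact constituent items were defined in earlier work and are not fixed by
the analysis itself: the bladder pain composite index (BPCI; case if > 4,
control if < 3, otherwise indeterminate) defaults to unit weights over
ICSI4, ICPI4 and the two voiding-cycle pain binaries — a documented
stand-in — and the urge incontinence composite index (UICI) defaults to
unit weights over OABq4, OABq8 and PFDI-20 q16.

Three per-subject symptom-domain measures summarise the phenotypes:

* bladder pain (BPS): equal-weighted mean of z-scored ICSI4,
  pain-with-filling (fGUPI2c) and urinary frequency (fGUPI6); weights are
  configurable because only "weighted composite" is specified;
* non-urologic pelvic pain (NUPP): count of endorsed pain
  locations/activities (fGUPI 1a, 1b, 1c, 2a, 2b), range 0–5;
* myofascial pain (MFP): mean of unit-scaled fGUPI5, PFDI-20 q5, q1 and
  q7.  Unit scaling uses each item's theoretical scale bounds so the
  measure always lives in [0, 1] regardless of the cohort at hand.

## Synthetic cohort generator

The generator defines the study conditions: 56 BPS, 31 NUPP and 58 MFP
cases plus 69 asymptomatic controls (214 subjects).  Each ordinal item is
drawn from a **discretised, range-truncated normal**: integer bin masses
are normal CDF differences renormalised over the item's support, the
location is solved by bisection so the achieved mean matches the published
target (to ~1e-9; the contract requires 0.01), and the scale is solved by
Brent's method so the achieved SD matches as closely as the family allows.
Two numerical points matter: bin masses are computed in log space
(`log_ndtr` differences) because far-tail CDF differences underflow, and
the location bracket must grow like σ² because pushing a truncated mean
toward a scale endpoint requires an exponential tilt of that order.  A few
published SDs (e.g. 0.12 ± 0.59 on a 0–4 item) exceed the maximum spread a
unimodal tilted discrete normal can have at that mean; these are matched
as closely as the family permits, which slightly under-disperses those
items.  Binary items are Bernoulli at the published endorsement
proportion.

Control-group item statistics were never published (controls were screened
to be asymptomatic); the package uses a constructed asymptomatic profile —
ordinal means 0.4 above the scale floor with SD 0.7, 4 % binary
endorsement, age 34.1 ± 6.4 y — and flags it as such.

Items are independent within subject by default.  An optional Gaussian
copula with a single shared severity factor (`correlation` ∈ [0, 1))
induces realistic positive inter-item dependence while preserving every
marginal exactly.  Mixed-phenotype subjects (`mixed_fraction` of each case
group) are drawn from convex blends (default weight 0.5) of two groups'
parameter vectors, mirroring the intermediate SOM bins seen in practice.
Treatment records are Bernoulli draws: attempt probability =
attempted/group size and response probability = responders/attempted from
the published responder table.

What the generator does **not** emulate: item-level covariance structure
beyond the single factor, longitudinal dynamics, comorbidities, floor/
ceiling response styles, or the selection process that produced the
clinical cohort.  Passing tests therefore demonstrate that the pipeline
recovers structure *of the kind the study describes*, not that it would
reproduce the study's real-data coefficients.

## Clustering

Continuous items are z-standardised (optionally log(1+x) first — no
columns by default, since which variables were log-transformed is not
enumerated in the source analysis); binary items pass through as 0/1.
Controls are excluded from cluster derivation.

* **Ward dendrogram**: agglomeration minimising the increase in total
  within-cluster sum of squares; merge height is that increase (a
  singleton pair merges at ‖a−b‖²/2).  Implemented on
  `scipy.cluster.hierarchy` with heights converted h²/2.
* **Elbow**: WSS(k) for k = 1..k_max, each the best of seeded k-means
  restarts.  The automated selector scores interior k by the ratio of the
  WSS drop achieved reaching k to the drop achieved by one further step.
  The raw second forward difference of WSS was evaluated first and
  rejected: it is dominated by the always-large k=1→2 drop and selects
  k=2 on study-calibrated cohorts whose visible knee (and generating
  structure) is at k=3.  The relative form selects k=3 stably across
  cohort and restart seeds.
* **K-means**: k-means++ starts, Lloyd iterations (tol 1e-6, ≤300
  iterations), best of 50 restarts, deterministic given the seed.  Labels
  are renumbered 1..k by first appearance; centroids and WSS are
  recomputed from final members so the stored model is exactly
  self-consistent.
* **Ordination**: principal coordinates of Bray–Curtis dissimilarities,
  computed on unit-scaled raw scores (z-scores would violate
  non-negativity); a double-zero pair is assigned d = 0.

## Bootstrap stability

Each of B replicates (default 10,000; the reduced profile uses 1,000)
resamples n subjects with replacement, refits k-means with the same k and
a fresh seeded initialisation, and aligns the replicate's arbitrary labels
to the reference partition by maximising unweighted Cohen's kappa over all
k! permutations.  Per reference cluster, on the unique resampled subjects:

* **Rand (per-cluster)**: fraction of subjects whose binary in/out
  membership agrees; joint absence counts as agreement, so sparsely
  assigned clusters can score high on Rand alone;
* **Jaccard**: |intersection| / |union| (1 if both empty); values above
  0.7 are conventionally "very good" stability.

Out-of-resample subjects are excluded by default because their bootstrap
assignment is undefined without an extra rule; a nearest-centroid
assignment mode exists for sensitivity analysis.  Point estimates are
replicate means with 2.5/97.5 percentile intervals; replicates whose refit
returns fewer than k non-empty clusters are skipped and counted.

## Variable importance

A random forest (default 500 trees, ⌊√p⌋ features per split, unlimited
depth, Gini impurity) classifies subjects into their cluster labels.  It
is a bagging loop over scikit-learn decision trees because the
mean-decrease-accuracy definition used here — the out-of-bag accuracy drop
when one feature is permuted within each tree's out-of-bag rows — is not
exposed by the stock ensemble.  Gini importance is the mean of the trees'
normalised impurity decreases.  The phenotype z-matrix reports each
cluster's raw item mean as a z-score against the overall cohort
(affine-invariant per item; zero-variance items are flagged, not scored).
The top-20 accuracy-ranked items are assigned each to the cluster with the
largest z-entry (ties go to the earlier column and are flagged) to form
the per-phenotype discriminatory item sets.

## Self-organizing map

Subjects — cases and controls — enter as their three unit-scaled symptom
measures (the bladder-pain measure is min-max scaled over the cohort; the
NUPP count is divided by 5; the MFP measure is already in [0, 1]).  The
map is a 6 × 4 rectangular grid (24 nodes) trained online for 1,000,000
iterations (100,000 in the reduced profile) at initial learning rate 0.1:
each iteration draws a random subject, finds its best-matching unit (BMU)
and pulls every node toward the subject with a Gaussian neighborhood
weight.  Decay schedules are not specified by the source analysis; linear
decay was chosen for both (α from α₀ to 0; radius from max(rows, cols)/2
to 0.5), and the codebook is initialised uniformly at random within each
feature's data range so that training measurably improves quantization
error over initialisation.  The **convergence index** follows the popsom
composite: ½ × (fraction of features whose codebook weights are
indistinguishable from the data by Welch's t-test and a variance F-test at
α = 0.05) + ½ × (fraction of subjects whose best and second-best units are
rook-adjacent).  Nodes are metaclustered by Ward clustering of codebooks;
the neighbor-distance map averages each node's Euclidean codebook distance
to its 2–4 rook neighbors.

Bin purity rules are a package invention (the source figures show rings,
not rules) and are config-exposed and echoed in output metadata: a bin is
**control** if all three mean measures are below 0.25, **global pain** if
all exceed 0.60, **pure-X** if measure X is at least twice each other
measure and at least 0.25, otherwise **mixed**; empty bins are labelled
`empty`.

## Treatment analysis

Responder counts aggregate per (phenotype, therapy) over four therapies
(oral bladder analgesics, intravesical instillations, pelvic floor
physical therapy, amitriptyline).  Within-group proportions are
responders/attempted (undefined, not zero, where nothing was attempted);
within-cohort proportions are each phenotype's share of all responders to
a therapy.  Proportions are compared with the pooled two-sample z-test
without continuity correction (switchable); Mann-Whitney (asymptotic with
tie correction), Pearson chi-square (no Yates correction) and Fisher's
exact test are provided as thin utilities for baseline comparisons.  No
multiple-testing correction is applied by default, with Holm available.

## Reproducibility and problem sizes

Every stochastic operation is a pure function of its inputs and a seed.
The pipeline derives per-stage seeds from one global seed by a stable hash
(blake2b of "seed:stage", mod 2³¹) and records them in the run summary, so
any stage can be replayed in isolation.  The default configuration uses
the full study sizes (B = 10,000 bootstrap replicates, 10⁶ SOM
iterations); the reduced profile (`PipelineConfig.ci_profile`, B = 1,000
and 10⁵ iterations) is the package's standard quick-verification setting
and is what the test suite runs.  Generator calibration checks use 2,000
subjects per phenotype with a 3-standard-error acceptance band.

## Known limitations

* BPCI/UICI item sets are stand-ins; conclusions about those composites
  concern the configured defaults, not the original instruments.
* The generator's independence default understates real item correlations;
  cluster recovery on synthetic cohorts is correspondingly easier than on
  clinical data (the real-data stability coefficients are materially lower
  than the near-1.0 values synthetic cohorts produce).
* The SOM convergence index depends on the chosen two-sample tests and
  neighborhood definition; alternative conventions shift its value.
* Per-cluster Rand/Jaccard are computed over subjects (not subject pairs),
  matching the per-subject agreement reading of those indices.
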