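# Methods

`edrisk` implements an *active case-finding* pipeline for population health
management: every patient in a population is scored for the risk of **any
emergency-department (ED) visit in the next 6 months**, using only the
12 months of encounter history before an index date. This note documents
the models, their assumptions, the tunable parameters, and what the
synthetic-data generator does and does not establish.

## The prediction problem

For patient *i* with encounter history H_i over the observation window
(365 days ending the day before the index date), the target is the binary
outcome Y_i = 1{any ED visit in the 180-day outcome window}, together with
T_i = days from the index date to the first such visit (right-censored at
180 when no visit occurs). Exclusions applied before modeling:

* patients with an `expired` encounter disposition anywhere in the study
  frame are removed (deaths cannot be cases or controls);
* same-day paired ED records flagged `transfer_from_ed` are merged into a
  single ED visit, so an inter-facility transfer is never double-counted.

## Feature engineering

Encounter records pivot to one numeric row per patient: counts of
encounter types, primary/secondary diagnosis codes, laboratory tests (plus
a total abnormal-result count), radiology modalities and medication
classes; exclusive indicators for the four age groups (0–18, 19–34, 35–49,
50+; lower edges inclusive) and gender; chronic-condition indicators per
ICD-9 chapter family plus the overall `chronic_flag`; zip-level income and
education proxies. Absence encodes as 0; no imputation. Counts are used
where a category can recur (they preserve utilization intensity);
indicators where categories are exclusive.

The chronic/non-chronic dichotomy comes from a bundled diagnosis lookup
keyed to six ICD-9 chapter families. Codes missing from the lookup default
to *non-chronic* with a warning — the conservative direction, since it
never inflates the chronic stratum.

Dimensionality is controlled by the **variance criterion**: features are
min-max scaled to [0, 1] (so counts and indicators compete on one scale —
the scale is a package choice, as variance filtering is otherwise
scale-dominated), ranked by variance, and the top `keep_n` (default 40)
kept; ties break lexicographically and the two empirical routing features
(`prior_ed_count`, `chronic_flag`) are always retained. The filter is
idempotent. Prospective scoring skips the filter entirely: a frozen model
defines its own feature schema, and re-filtering a new cohort could drop a
borderline feature the model needs.

## Cohort construction

The analyzable population is stratified into **six subgroups**:
chronic-condition status {no, yes} x prior-ED band {0, 1, >=2}. Within each
stratum, cases and controls are separately shuffled (seeded) and dealt
round-robin to Cohort I (training), II (calibrating) and III (blind
testing). The dealing scheme guarantees — not just in expectation — that
per-stratum per-cohort case and control counts differ pairwise by at most
one.

## The risk model

1. **Deterministic partition.** A fixed 2x2 tree on the two empirical
   features — any prior ED visit, any chronic diagnosis — routes every
   patient to one of four subgroups. This encodes the strongest known
   risk factors as prior knowledge rather than leaving them to be
   rediscovered.
2. **Greedy PPV-constrained feature selection** (per subgroup). Features
   are added one at a time to maximize out-of-fold case-finding
   *sensitivity within the top `review_fraction` (default 0.15) of scored
   patients* — the fraction of a population a care team could plausibly
   review — subject to positive predictive value >= `ppv_target` (default
   0.70) in that slice once any candidate attains it. Out-of-fold scores
   come from 5-fold logistic regression: a deliberately cheap surrogate
   whose ranking is monotone in planted signal, so selection cost stays
   linear in candidates rather than requiring a forest refit per
   candidate. Slice sensitivity has granularity 1/n_cases, so ties are
   common; among equal-sensitivity candidates the higher out-of-fold AUC
   wins (then the lexicographically smaller name, for determinism), and a
   candidate that leaves sensitivity unchanged but strictly improves
   out-of-fold AUC still extends the selection — it refines the ranking
   inside the review slice, which matters downstream because the
   calibration's resolution is bounded by the number of distinct scores.
   Selection stops when neither the sensitivity gain exceeds
   `selection_tol` (default 0) nor the AUC improves, or at `max_features`
   (10); a feature identical to the outcome therefore stops selection at
   one feature.
3. **Per-subgroup survival forest.** `n_trees` (100) trees are fit on
   seeded bootstrap resamples (fraction 0.8), each tree seeing a random
   `feature_fraction` (0.7) of the selected features. Feature subsampling
   is essential here, not cosmetic: with predominantly small-integer count
   features, every bootstrap otherwise finds the same greedy splits and
   the ensemble collapses onto a handful of distinct scores, which
   coarsens the risk-index calibration downstream. Splits maximize the
   two-sample log-rank chi-square on (T, event) restricted to the 180-day
   horizon; leaves predict the empirical within-horizon event fraction
   (with censoring only at the horizon this is the plain event-flag mean);
   the forest score is the mean over trees — an estimate of
   P(ED visit within 180 days). A plain Gini classification forest
   (`mode="classification"`) is available for comparison; it is not the
   default and is not JSON-persistable.

Numerical choices in split search: candidate thresholds are at most 8
quantile midpoints per feature per node, and the log-rank statistic is
evaluated on the node's distinct event days, quantile-coarsened to at most
24 time points. Both keep split search to two matrix products per node and
cost little accuracy under administrative censoring. Degenerate subgroups
(one outcome class, or empty) fall back to a constant model emitting the
subgroup event fraction.

## Risk-index calibration (PPV semantics)

Raw scores carry no clinical meaning on their own. On Cohort II, for each
distinct score s the package computes 100 x PPV among patients scored >= s,
applies a running maximum from the lowest score upward (monotone
correction), and linearly interpolates between the resulting knots. The
mapped value is the **risk index L in [0, 100]**, defined so patients with
index >= L have about an L% probability of an ED visit in the next
6 months. Knots with fewer than `min_cell` (50) patients above them
inherit the highest valid knot's value — a variance control for sparse
high-score tails. The construction guarantees exact L%-PPV semantics on
the calibration cohort at uncorrected knots; on held-out data the
semantics are approximate (the acceptance band is +/-5 points at L in
{30, 50, 70}). Thresholds T_m = 30 and T_h = 70 on the index scale divide
the population into low (< 30), medium (30–69.99) and high (>= 70) risk
groups; both boundaries are inclusive on the upper group.

## Evaluation

* **c-statistic / ROC AUC** via the trapezoid rule (equals concordance
  pair-counting with ties at one half; the test suite checks the
  equivalence to 1e-12).
* **PPV-by-threshold tables** at index cutoffs {30, 50, 70, 80}, with
  explicit flag counts and false-flag rates; a threshold flagging nobody
  reports an undefined marker, never 0.
* **Kaplan–Meier curves** per risk group and the k-group **log-rank
  test** (chi-square, k−1 df), both via lifelines.
* **Mean outcome-window ED counts** per risk group.
* **Shrunken differences**: per feature j and risk class k,
  d_jk = (mean_jk − mean_j) / (m_k (s_j + s0)) with s_j the pooled
  within-class SD, s0 the median of the s_j, and m_k = sqrt(1/n_k + 1/n);
  |d| is soft-thresholded by a configurable shrinkage (default 0, i.e. a
  pure diagnostic display). Note the m_k here uses a plus sign under the
  root — a deliberate package convention; the classical nearest-shrunken-
  centroid construction uses sqrt(1/n_k − 1/n).

## High-risk clustering

Patients with risk index >= 70 are standardized, projected onto the fewest
principal components reaching 80% cumulative explained variance
(`variance_target`), and clustered by K-means with K = 6. Initialization
is greedy farthest-point (first center a seeded random pick per restart,
the rest maximin), 25 restarts, lowest within-cluster sum of squares wins
— deterministic given the seed. Profiles report age/gender composition,
chronic chapter-family prevalences as explicit n/N fractions, and mean
lab/radiology/medication counts, with clusters renumbered by size.

## The synthetic generator: what it emulates, and what a green test means

No statewide HIE extract can ship with a package, so `edrisk.synth` draws
a population with the aggregate structure the pipeline needs to be
testable end to end:

* **Marginal 6-month ED incidence ~11.5%** — the logistic intercept of the
  latent hazard is solved by bisection so the population mean equals
  `target_incidence` exactly in expectation.
* **Strong ED recurrence**: the per-visit log-hazard weight (2.6, capped
  at 3 visits) is set so that more than 80% of patients with >=2 prior ED
  visits revisit within 180 days — a structural property of the stated
  world, checked by Monte Carlo at n = 50,000.
* **Chronic burden drives risk** through a chronic flag (0.9), count of
  chronic chapter families (0.3), medication count (0.08) and age band
  (0.9 across the range), all configurable log-hazard weights.
* **Risk-ordered event times**: event days are drawn as
  ceil(180·U^(1+2.5·hazard)), so higher-risk patients tend to earlier
  events and risk groups separate on Kaplan–Meier curves.
* Encounters, labs, radiology, prescriptions, deaths (0.5%, via expired
  dispositions) and same-day ED transfer pairs (2% of ED visits) are
  generated per patient; chronic patients receive one anchoring
  outpatient visit per chronic chapter family, so the chronic stratum is
  recoverable from records alone.

All randomness flows through one seeded `numpy` generator; identical
configs give byte-identical output. The latent hazard is persisted only in
a separate ground-truth table that models never read.

What the generator does **not** emulate: real ICD-9 code frequencies,
region-specific demographics or payer mix, coding errors and missingness,
seasonal utilization patterns, and correlation structures beyond the
drivers above. A green statistical test therefore establishes that the
pipeline *recovers known structure from data shaped like an HIE extract* —
not that it reproduces any published headline number, which would require
the original statewide data.

## Reproducibility

One global seed fans out to per-stage seeds by fixed offsets (generator
+1, cohort split +2, model +3, clustering +4). Every JSON artifact embeds
a SHA-256 hash of the scientific configuration (artifact paths excluded),
and two runs with equal manifests produce byte-identical artifacts.
Prospective runs score with a frozen model document and never refit or
mutate it; a cohort missing a required feature column fails with a schema
error naming the columns.

## Known limitations

* New patients with empty observation windows receive all-zero features
  and are systematically scored low — the model cannot see risk it has no
  history for.
* The PPV semantics of the risk index are exact only on the calibration
  cohort; drift between calibration and scoring populations shifts the
  realized PPV.
* The survival forest restricts attention to the 180-day horizon; it is
  not a general survival model and does not handle competing risks.
* Selection uses a logistic surrogate; features whose signal is purely
  non-monotone interaction could be missed even when the forest could
  exploit them.
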