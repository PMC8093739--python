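# Methods

`tidaltag` implements an analysis chain for passive acoustic telemetry of
reef manta rays (*Mobula alfredi*) at a tidally forced feeding aggregation:
detection quality control, resident-event segmentation and residency
statistics; conversion of moored-instrument records into environmental
predictors on a 5-minute grid; and a from-scratch boosted-regression-tree
(BRT) model of visitation with influence, partial-dependence and
interaction inference. This note records the models, the conventions, and
the design choices that were genuinely open.

## Telemetry

A detection is one decoded tag transmission at one receiver. Detections are
screened for false decodes (tag-ID collisions, noise) with the
interval-ratio method: within each (tag, receiver) stream, inter-detection
intervals are classed *short* (< 30 min) or *long* (> 12 h). A detection is
flagged when it is temporally isolated — both neighbouring intervals long
(one suffices at stream endpoints) — *and* the stream contains fewer short
than long intervals. A stream rich in short intervals reflects genuine
residency and is never flagged; a single-detection stream has no short
intervals and is flagged. The published description names only the two
thresholds, so the isolation-plus-ratio rule here is the strictest reading
of the method; it is deterministic, idempotent on its own output, and makes
no claim of bit-equivalence with proprietary screening tools.

Resident events follow the standard two-rule state machine: an event at
receiver R opens at the second detection at R within 60 min of the previous
one, extends while same-receiver detections arrive within 60 min, and
closes at its last member detection when either the next detection at R is
more than 60 min away or two detections accumulate at a single other
receiver (which then seed the next candidate). Single intervening
detections elsewhere never close an event. Event detection is verified
against an independent forward-scan oracle on random logs.

Residency index: RI = 100 × (days detected) / (days tracked), with the
tracking span counted in inclusive calendar days (same-day span = 1). The
inclusive convention is forced by two facts: any other convention can
violate detection_days ≤ tracking_days, and published deployment tables
count this way (a 19/11–21/11 track prints 3 days). Report tables round
half-up; internal values keep full precision. All timestamps are treated as
UTC with no daylight-saving logic.

The packaged deployment summary (19 tags, Egmont Atoll, Nov 2019–Mar 2020)
carries one internally inconsistent row (CG-MA-0120: printed RI 76 vs
100 × 2/3 ≈ 67) and five rows whose printed RI sits one point above the
integer-day recomputation; the published indices were evidently computed
from fractional tracking spans (the source quotes a maximum RI of 80.3%
where the printed columns give exactly 80.0). `reference.recompute_ri`
flags all such rows rather than forcing the printed values; cohort RI
statistics use the table's own RI column.

Diel convention: hours 06–18 inclusive are "day", 19–05 "night", matching
the printed ranges; both hour sets are arguments.

## Environmental predictors

All predictors live on a common 5-minute grid of left-closed bins
(one row per bin; a 100-day deployment gives 28,800 bins).

* **Temperature** (2 m and 50 m above the bed): arithmetic mean of the
  ~60 five-second CTD samples per bin; empty bins are missing.
* **Backscatter** (zooplankton proxy): the 25 × 2-m ADCP profile is
  despiked along the vertical at each time step with a centred running
  median (window 3, maximum deviation 1, shrunken windows at the edges;
  values within the deviation are never altered, so the filter is
  idempotent), then depth-averaged and linearly interpolated from the
  10-min cadence onto the grid. Despiking is vertical, not temporal,
  because the artefacts being removed (large non-zooplankton targets) are
  single-bin in extent.
* **Currents**: eastward/northward components at the bins centred 5.5 m
  and 45.5 m from the transducer (8.5 m and 48.5 m above the bed for a 3-m
  mounting) are rotated 117° clockwise from north onto slope axes —
  longshore positive toward bearing 297°, cross-shore positive toward
  207° — and interpolated onto the grid. The rotation is orthonormal
  (speed-preserving, exactly invertible). Horizontal components are taken
  unfiltered; vertical velocity is depth-averaged with no despiking
  (averaged velocity is low-noise).
* **Tide phase**: pressure from the deep CTD is converted to depth with a
  fixed hydrostatic factor of 0.9928 m/dbar — only relative elevation
  matters for phase, so the constant is not critical — cleaned with a
  501-sample median filter and a 501-sample running mean, and peaks at
  least 5.5 h apart are taken as high tides (lows from the negated
  record). After merging, highs and lows must alternate; where two peaks
  of one type are adjacent the lower-prominence one is dropped and logged.
  Time-to-high-tide is the signed offset to the nearest high (negative on
  the flood), quantised to 5-min steps; bins farther than half a median
  tidal cycle from every detected high are missing, so phase is never
  extrapolated past the record ends.

The response is 1 when at least one kept detection of any tag falls in the
bin at the focal receiver (default: the Manta Alley site). Rows with any
missing predictor are dropped listwise and counted in the run report; this
matters mainly at the record edges and after an instrument stops early.
Collinearity is screened with pairwise Pearson correlations (flag |r| ≥
0.6) and variance inflation factors VIF_j = 1/(1 − R²_j) from OLS of each
predictor on the rest (flag ≥ 3.5; constant predictors report infinite
VIF).

## Boosted regression trees

The BRT is logistic gradient boosting with shallow least-squares regression
trees, written from scratch:

* F₀ is the logit of the training prevalence. Each stage fits a CART tree
  to the gradient residuals (y − p) on a without-replacement subsample of
  fraction *bf*; terminal nodes then take the one-step Newton estimate
  Σ(y−p)/Σp(1−p) over their training rows (the standard binomial update),
  and the ensemble advances by *lr* times the tree.
* Splits maximise the squared-error reduction over every (feature,
  midpoint) candidate, with at least `min_obs_in_node` rows (default 10)
  per child. Ties break on the lowest feature index, then the smallest
  threshold, so fits are bit-reproducible under a fixed seed. *tc* bounds
  the tree depth (the maximum interaction order a tree can express).
* Tree count is chosen by stepwise ten-fold cross-validation: stratified
  folds (preserving prevalence), *ss* trees added per step to each fold's
  booster, mean held-out deviance tracked, growth stopped after 5 steps
  without improvement (`patience`) or at `max_trees`, and the final model
  refit on all rows at the CV-deviance argmin. With *bf* = 1 the whole
  procedure is deterministic given the seed.

Evaluation reports the training AUC, the mean held-out AUC over folds,
their difference (the overfitting gauge), and the deviance explained
D² = 1 − residual/total deviance with the intercept-only model as total.
AUC is computed by average ranks (ties count one half) and is verified in
the tests against a brute-force concordant-pair count and scikit-learn.
The hyperparameter grid reproduces the standard screening design: tc 1–6 ×
lr {0.01, 0.005, 0.001, 0.0001} × bf {0.5, 0.7, 0.9} × ss {25, 50} = 144
configurations, ranked by cross-validated AUC with the training–CV gap as
tiebreak. No claim of bit-equivalence with the R `gbm`/`dismo`
implementations is made; class imbalance is handled by nothing beyond the
deviance itself.

## Interpretation

* **Relative influence** credits each predictor with the squared-error
  improvement of every split it provides across the selected trees,
  normalised to percentages summing to 100.
* **Partial dependence** sweeps one predictor over a quantile lattice with
  the others held at their means (the convention of the published
  dependency plots); a marginal variant averages the decision function
  over all rows on the link scale, which coincides with the at-means
  profile (up to a constant) for additive ensembles. Confidence bands come
  from a case-resampling bootstrap: rows resampled with replacement, the
  model refit per replicate with its own configuration and tree count, and
  pointwise percentile intervals taken (widened where needed to contain
  the point curve). Case resampling was chosen over residual resampling,
  which is ill-defined for a binary response.
* **Interaction strength** for a pair evaluates the fitted model on an
  n×n quantile lattice of the two predictors (others at means, link
  scale), fits a main-effects-only surface (grand mean + row effects +
  column effects) by least squares, and reports 1000 × the mean squared
  residual. Additive models score exactly zero and the statistic is
  symmetric. Lattices are trimmed to the central 95% of each predictor:
  fitted surfaces are unconstrained beyond the extreme observations and
  untrimmed corners dominate the statistic with extrapolation noise. The
  ×1000 scaling makes sizes order-of-magnitude comparable with published
  interaction tables; exact equivalence with the original implementation
  is not claimed.
* **Interaction significance** refits the model with the response randomly
  permuted (the published description — "randomly sampling the
  occurrence … before re-fitting" — is a permutation scheme even though
  the source calls it a bootstrap) and reports the add-one permutation
  p-value p = (1 + #{null ≥ observed}) / (n_null + 1), so p is bounded
  below by 1/(n_null+1). By default only pairs with observed size above
  the conventional screening threshold of 100 warrant testing.

## Synthetic deployments

The generator provides desk-scale data with known truth. It builds a
stochastic *environmental state* on the 5-min grid and lets the
instruments observe it:

* M2 (12.42 h) + S2 (12.00 h) tidal elevation in the pressure record, with
  non-zero constituent phases so the record does not begin exactly at high
  water.
* A cold-water-bore motif: a Gaussian bump centred 2 h before high tide
  (width 0.7 h) drives near-bed cooling, a backscatter pulse, cross-shore
  in/outflow and downwelling. Each covariate's bore response carries its
  own per-tidal-cycle amplitude jitter (uniform 1 ± 0.5): real bore
  expressions decouple across variables, and without that independence
  every covariate would be a deterministic proxy of tide phase and effect
  attribution would be meaningless.
* Slow process variability — meteorological temperature drift (12-h
  knots), biological backscatter drift (6-h), sub-tidal current
  fluctuations (2-h) — sized so that each bore response is roughly twice
  the background standard deviation; brief bumps otherwise acquire extreme
  standardized tails that dominate any rare-event fit regardless of their
  nominal coefficient.
* Diel near-surface warming peaking mid-afternoon.
* Presence per bin is Bernoulli with logit β₀ + Σβⱼzⱼ + β_int·z_a·z_b on
  internally standardized predictors. The tide-phase coefficient (−3.0) is
  deliberately dominant; the interacting pair is (temp_50m, backscatter),
  whose variability is predominantly tide-phase-independent — a product
  term involving any phase-locked covariate would re-express itself
  through tide phase and could never be attributed to the designed pair.
  β₀ = −4.0 targets ~15% of bins occupied, the occupancy implied by
  hundreds of multi-bin resident events at a busy aggregation site over a
  multi-month record.
* Present bins emit pings from 1–2 tags at uniform 30–90 s intervals, each
  detected with probability 0.9; about one spurious isolated ping per day
  exercises the false-detection screen. With detection probability 1 and
  no spurious pings the pipeline's recovered presence equals the ledger
  exactly.

What the generator does *not* emulate: animal trajectories (presence is
bin-level), hydrodynamics of internal waves or Langmuir circulation
(signals are phenomenological templates), detection-range variation,
receiver outages, and tag loss. Passing tests therefore demonstrate that
the machinery recovers known structure under realistic signal shapes and
noise — not that the field study's specific numbers are reproducible,
which its embargoed raw data preclude.

## Problem sizes and test protocol

The package's verification experiments use two grid lengths, chosen as its
own desk-scale conditions: a 7-day fixture (2,016 bins) for pipeline
round-trips, and a 28-day grid (8,064 bins) for parameter-recovery
replication. The 28-day length matters for a subtle reason: tide phase
advances only ~50 min per day against the clock, so over one week
tide-phase and diel covariates co-vary on a narrow joint manifold and
lattice-based interaction statistics are dominated by off-manifold
extrapolation; by four weeks the joint support is essentially full.
Recovery experiments fit tc = 5, lr = 0.03, bf = 0.7 ensembles of 1,300
trees (a fixed-size fit — stepwise CV is exercised separately, and the
recovery questions concern the fitted surface, not tree-count selection).
Bootstrap and permutation replicate counts are scaled down in tests (the
library defaults remain 1,000 and 100).

## Numerical details

* Probabilities are clipped at 1e-8 in the deviance; decision-function
  inputs to the logistic are clipped at ±700 to avoid overflow.
* A float-degenerate split midpoint (two adjacent values so close their
  midpoint rounds to the upper one) falls back to the lower value, so no
  child is ever empty.
* Empty 5-min bins, all-missing profile time steps and grid bins outside
  an instrument's span propagate as missing and are dropped (and counted)
  at design-matrix assembly.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived seeds use `SeedSequence` so
  sub-streams are independent and reproducible.
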