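# Methods

`pairforage` implements the full analysis chain for asking whether breeding
partners of a central-place foraging seabird are more similar or more
dissimilar in their foraging strategies than randomly matched male–female
combinations.  This note documents the models, the generator, the numerical
choices, and the limits of what the tests demonstrate.

## Study design emulated

Each bird carries a GPS/depth logger for ~72 h during chick rearing: a
position fix every 3 min, depth at 1 Hz (0.1 m resolution), plus
morphometrics (wing length, head–bill length, body mass before and after the
deployment).  The default design is 19 pairs in one season and 21 in a
second — 80 birds — matching the scale the pipeline is intended for.

## Track regularization

Fixes are resampled to a regular 5-min grid.  Positions at grid times are
interpolated along the great circle between the bracketing fixes; gaps longer
than `max_gap_s` (default 30 min) are still filled, so decoding operates on a
complete grid, but flagged and excluded from the distance numerators.  We use
straight great-circle interpolation rather than a continuous-time correlated
random walk: at a 3-min fix cadence the within-gap curvature is negligible
relative to the trip-level aggregates consumed downstream, and the contract
that matters — a position at every grid time with imputations flagged — is
identical.

Distances use the haversine formula on a 6371-km sphere; all metric-space
work (KDE grids, the 1-km colony radius) happens in a local azimuthal
equidistant plane centred on the colony, in which radial distances from the
colony are exact.

## Activity classification

A four-state hidden Markov model (colony, diving, flying, swimming) with
conditionally independent emissions per 5-min step:

- step length ~ Gamma(shape, rate) — flights have long steps (~5 km per step
  at 60 km/h), colony residency very short ones;
- flight intensity ~ Normal(μ, σ) — a per-step wing-beat-frequency stand-in;
  the generator emits it directly rather than simulating 50-Hz acceleration;
- dive indicator ~ Bernoulli(p), initialized at 0.95 for the diving state
  and ≤ 0.05 elsewhere.

Fitting is Baum–Welch EM over all birds jointly, entirely in log space
(no scaling factors), stopping at relative log-likelihood change < 1e-6 or
`max_iter`.  The weighted Gamma M-step inverts the digamma relation by
Newton's method.  A state left with < 1e-6 total posterior mass keeps its
parameters (with a warning): that is the benign limit when the data exercise
fewer than four activities.  A non-finite likelihood triggers a jittered
restart (≤ 5), then a hard failure.  Decoding is Viterbi (global MAP, ties
broken toward the lower state index) plus forward–backward posteriors;
emission densities are floored at 1e-300.  After decoding, steps within 1 km
of the colony that contain no dive are forced to the colony state — the
splashdown filter, which also stabilizes the model without needing a
distance emission.

Step lengths are floored at 1 m before the Gamma density is evaluated,
since exact zeros have no density under a Gamma family.

## Dives and trips

A dive is a maximal run of depth ≥ 1 m lasting ≥ 3 s.  Neither threshold is
externally fixed; 1 m sits well above the 0.1-m sensor resolution and
surface splash, and both are config keys.  A run of k samples at 1 Hz counts
as k seconds submerged (one sample interval is added to the first–last-sample
span).

A foraging trip is a maximal excursion with colony distance > 1 km, duration
> 20 min, containing ≥ 1 dive.  Excursions touching the deployment boundary
are flagged partial but kept.  Every emitted trip is re-audited against all
three predicates after segmentation.

Deployment metrics follow the conventional set: per-trip maxima/means/SDs of
colony distance, path length, duration and azimuth (colony → farthest
point); daily distance and trips per day use the exact deployment span in
days, not calendar days.  A single-trip deployment reports SD = 0 with a
flag rather than a missing value so pairwise differencing never drops a
bird.  Azimuth summaries are arithmetic means of bearings in [0, 360) with a
warning when a bird's trip bearings span more than 180°.  Dive metrics
include *differential depth*: a dive's mean depth minus the population mean
dive depth for that local hour of day (UTC−5 by default), removing the diel
cycle.  Hourly means are population-wide per year by default (the natural
reading of "average depth for each hour of the day"); per-bird averaging is
a config switch.

## Space use

Per-bird utilization distributions use all trip locations, an isotropic
Gaussian kernel and a 200-m grid.  The reference ("ad hoc") bandwidth is
h = 0.5·(sd_x + sd_y)·n^(−1/6); the workflow computes it per bird, averages
across birds, and applies one common bandwidth (2720 m in the reference
configuration) — per-bird bandwidths are available.  Points are binned to
the grid and convolved with the Gaussian; at cell ≤ h/13 the binning error
is far below the contour and overlap tolerances used anywhere in the
package.  Grids are snapped to integer multiples of the cell size in colony
coordinates, so any two UDs paste exactly onto a union grid.

Volume contours (50% core, 95% range) take cells in decreasing density
until the target mass is reached, retaining ties at the cut.  Overlap is
Bhattacharyya's Affinity Σ√(p₁p₂).  By default each UD is masked to its own
50% contour and renormalized before the affinity is taken, so identical UDs
score exactly 1 at any level; the unrenormalized variant is available for
cross-checks.

## Pairing inference

For each season, every tracked female is crossed with every tracked male
(19×19 + 21×21 = 802 rows), each row carrying |female − male| for every
trait, a real-pair indicator (40 ones), and a weight.  Before modelling,
variables with pairwise Pearson |r| > 0.8 are reduced to one representative,
preferring the "mean" variant of a metric over its max/min/total/SD
variants.  The maximum distance, total distance, mean trip distance and wing
length |Δ| columns are z-scored after differencing.  BA enters as
log(1 + BA).

The probability that a row is a real pair is modelled by weighted binomial
logistic regression fitted by IRLS (convergence max|Δβ| < 1e-8, ≤ 100
iterations; SEs from the weighted information matrix; diverging linear
predictors are reported as complete separation).  Weights balance the
classes: real pairs carry n_randomized/n_real within their year, randomized
pairs 1 — the exact weights behind the original unbalanced-design correction
are not published, so this documented choice is config-overridable.
Candidate sets (foraging, diving, morphology, BA — each as single-covariate
models against the intercept-only null) are ranked by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with Akaike weights.

We deliberately do not re-implement the nested random-effect structure
(bird-within-year intercepts).  The dependence it addresses — each bird
appearing in every cross-pair row of its year — is handled exactly by a
matching-permutation test: the statistic is the mean |Δ| over real pairs
minus the mean over all potential pairs, and the null redraws uniform random
perfect matchings of females to males within each year, preserving each
bird's single-mate constraint.  Two-sided p = (1 + #{|T*| ≥ |T|})/(1 + B);
when the total number of matchings is small the full set is enumerated.
This permutation null is exact for the exchangeability actually at stake,
whereas a crossed binomial GLMM with 1–2 observations per random-effect
level is fragile; the fixed-effect logistic + permutation combination is the
package's headline inference.

Sex comparisons use Student's t-tests (pooled variance when unpaired; paired
for pre/post deployment mass).  Tests are two-sided at α = 0.05 with no
multiple-testing correction.

## Synthetic generator

Latent phenotypes per bird: mean trip distance, dives per day, mean dive
depth, preferred azimuth, wing length, head–bill, body mass.  Sex-specific
means are scale-realistic for a large pursuit-diving auk (e.g. trip distance
40 km F / 30 km M, SD 10; dive rate 120/90 per day; wing 220 mm, SD 4 mm;
mass ~981 g pre-deployment with a ~20 g loss over the deployment).

Pairing structure per trait:

- **disassortment d < 0** (mates more similar): mates' deviations are
  positively correlated Gaussians with ρ = 1 − (1+d)², preserving marginals
  and giving E|real-pair Δ| = (1+d)·E|independent Δ| exactly.
- **d > 0** (mates more different): a complementary-role construction —
  each pair splits into a ±δ "near/far specialist" pair on that trait, with
  δ solved numerically so the same (1+d) identity holds exactly at equal sex
  means.  No coupling that preserves Gaussian marginals can push the ratio
  beyond √2, so the role mixture is what makes strong disassortment
  representable; the cost is that the trait's population distribution
  becomes a two-component mixture, which is also the biologically intended
  picture of within-pair specialization.
- **wing length**: mates' deviations correlate with coefficient
  `wing_assortment` (size assortment is conventionally a correlation).

Defaults for the recovery study — d = 0.5 on mean trip distance and dive
rate, wing correlation 0.7 — were fixed by an a-priori power analysis so
that a real effect of this design size (40 real vs 762 randomized rows) is
comfortably detectable; they are the study conditions, not tuning knobs.

Tracks are biased correlated walks in the colony plane: colony bouts
(1.5–3.5 h) alternate with out-and-back excursions along the bird's
preferred azimuth (±15°) at ~60 km/h commute speed, with a mean-reverting
foraging walk around the trip target.  V-shaped dives at the phenotype's
daily rate are placed in foraging windows (every trip carries ≥ 1 dive with
probability 1 − ε, ε = 0.01), truncated-normal depths around the
phenotype's mean.  Measurement noise on a measured trait is 20% of that
trait's between-individual SD — reliability stated relative to population
variation, so wings are measured to ~1 mm and trip distances to ~2 km.

What the generator does **not** emulate: oceanographic structure, prey
fields, weather, tag effects on behavior, inter-annual site fidelity,
GPS positional error, and accelerometer waveforms (flight intensity is
emitted directly).  Passing recovery tests therefore show that the inference
chain is correct and calibrated under a faithful rendering of the design —
not that field data meet the generator's assumptions.

## Problem sizes used in validation

- Recovery and calibration replicates (100 each) run at the full pair design
  (19 + 21 pairs) but at the trait level: phenotypes plus measurement noise
  feed the pair table directly.  Re-simulating 80 tracks with 1-Hz depth per
  replicate adds nothing to the question those replicates answer (does the
  inference recover the configured structure?) and is validated separately:
  one full-chain run at the complete design (80 birds, 72-h deployments,
  1-Hz depth) is part of the acceptance script, and the unit suite runs the
  chain end-to-end at reduced scale.
- Permutation tests use 499 draws in replicated studies, 999 in single runs.
- HMM transition-recovery uses 40 series × 500 steps (20,000 steps).

## Known limitations

- The Gamma step-length family needs the 1-m floor for stationary fixes; a
  zero-inflated emission would be the fuller treatment.
- Arithmetic azimuth means mislead for trip sets spanning the north
  discontinuity; the circular mean is available but not the default, to
  match the conventional tabulated summaries.
- BA is computed between renormalized core-masked UDs by default; published
  overlap values computed without renormalization are comparable only via
  the `renormalize=False` mode.
- The weighted logistic treats weights as frequency weights in the SEs; the
  permutation test, not the Wald SEs, is the inference of record for the
  pairing question.
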