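# Methods

This note records the models, conventions and numerical choices behind
`killicog`, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Coordinate and timing conventions

Pose tracks use image coordinates: origin top-left, y increasing downward.
All "upward / surface-bound" logic derives from this single convention —
upward displacement is −Δy, upward velocity is −Δy·fps, and displacement
angles are computed on upward-positive axes (0° rightward, 90° straight up
toward the water surface). Trial timing constants (cue light 2 s, nominal
food arrival 9 s, analysis end 18 s) live on each trial's metadata record
and are configurable; the success window [2, 9] s is closed on both ends
and deliberately conservative, since true food arrival can lag the nominal
drop by a couple of seconds. Frame rate defaults to 20 fps and is stored on
each track, never global.

## Track prefiltering

Three stages run in a fixed order on the head keypoint (configurable list):

1. **Likelihood gate** (threshold 0.999): coordinates of low-confidence
   frames become missing; the likelihood values themselves are retained.
2. **Jump filter** (quantile 0.05): Euclidean distances between consecutive
   currently-valid frames are pooled across *all* tracks of the dataset; a
   masked frame breaks contiguity, so no distance spans it. Steps strictly
   greater than the pooled 95th sample percentile (linear interpolation
   between order statistics) mark the second frame of the pair missing.
   Ties at the threshold are not flagged — conservative and deterministic.
   The filter runs one pass, never iterated to convergence.
3. **Spline fill**: each coordinate is interpolated through its remaining
   points with a natural cubic spline (zero second derivative at the end
   knots — the boundary type is our choice; "cubic spline" alone does not
   pin it down). Leading and trailing gaps are never extrapolated and stay
   missing. Tracks with fewer than four valid points pass through.

Per-track reports count gated, anomaly, interpolated and residual-missing
frames; for tracks with no missing data on input,
interpolated + residual = gated + anomalies.

Note that a fixed-fraction quantile filter is *not* the identity on clean
data: on any continuous-motion track about 5% of steps exceed the pooled
95th percentile. The pipeline therefore also masks (and immediately
re-interpolates) a small fraction of legitimate fast swimming; tests assert
this bounded behavior rather than a literal identity.

## Latency of the first surface-bound trajectory

Upward velocity is smoothed with a 20-frame **centered** rolling mean
(window incomplete or containing a missing value → missing). The rolling
convention is centered by choice and configurable to trailing. Per animal:

- **Food-drop site**: per video, the coordinate at maximum food-drop
  likelihood; the site is the mean across videos (videos with all-zero
  likelihood excluded).
- **Bursts**: threshold at v_min + 0.75·(v_max − v_min) of the rolling
  velocities pooled over all the animal's trials; bursts are maximal runs
  strictly above it, reported as first/last frame times.
- **Arrivals**: frames within the surface radius (default 125 px, sensible
  range 100–150) of the food-drop site; contiguous runs collapse to their
  first frame.
- **t₁ edge rules**, checked in order: at the surface on the first analyzed
  frame → 0 s; no arrival → trial end (18 s); otherwise the start of the
  burst nearest the *first* arrival (distance 0 if the arrival falls inside
  a burst; ties broken toward the earlier burst — the conservative, earlier
  initiation); with no burst at all, the arrival time itself.

Per-animal burst fraction and surface radius accept logged overrides (the
equivalent of hand-adjusting individual animals, but auditable: the
thresholds used are emitted with every per-trial result).

Manual score sheets (per-second upward / at-surface flags) yield a manual
t₁ by finding the first at-surface second and backtracking through the
unbroken run of upward flags ending there; a ≥1 s pause restarts the run,
so only the final continuous ascent counts.

Session summaries report early (trials 1–7) and late (trials 11–17) mean t₁
(missing-t₁ trials excluded from the mean, with the count used recorded)
and percent success with a fixed denominator of 7; learning indices for
k = 2, 3, 4 consecutive successes, with 0 for animals that never achieve
the run (so "never learned" ranks below every learner — configurable to
missing); and the eating rule (animals eating in fewer than 3 trials are
flagged excluded but still summarized).

## Statistics

- **Wilcoxon tests**: exact null distributions for ≤ 25 nonzero paired
  differences (signed-rank) or pooled n ≤ 20 (rank-sum) without ties,
  otherwise tie-corrected normal approximation; the `exact` flag is always
  reported. Cutoffs match mainstream implementations.
- **Cohen's d**: pooled-SD standardized mean difference (no small-sample
  correction), CI half-width t_{(1+c)/2, n₁+n₂−2}·√((n₁+n₂)/(n₁n₂) +
  d²/(2(n₁+n₂))).
- **WMW sample size** (A.R.E. method): solve the continuous two-sample
  noncentral-t sample size for the target power, divide by the parent
  distribution's asymptotic relative efficiency (normal 3/π ≈ 0.955,
  logistic π²/9, Laplace 1.5, uniform 1, distribution-free minimum 0.864),
  round up. Per-group floor of 2.
- **Bootstrap precision**: SD point estimate = mean sample SD over B
  (default 1000) ordinary nonparametric resamples, precision = 1/SD²; the
  seed is recorded in every result. (Mean-of-replicates is our convention;
  a bias-corrected variant would differ by a few percent at n ≈ 20.)
- Report-style percent fields are rounded half-up to one decimal; raw
  doubles are retained everywhere else.

## Survival

Lifespans are treated as exact event times (daily checks; no interval
censoring), censored records flagged observed = 0. The KM median is the
earliest time with survival ≤ 0.5 (with a tiny numerical slack so an
exact-0.5 step is not skipped through floating-point round-off) and is
reported missing when the curve never reaches 0.5. The Gompertz fit
maximizes Σ_deaths ln h(t) − Σ_all H(t) with h(t) = a·e^{bt},
H(t) = (a/b)(e^{bt} − 1) (→ a·t as b → 0), log-parameterized rate,
initialized from the exponential MLE, Nelder–Mead then BFGS; 95% CIs from
the observed information (log scale for the rate). `time_unit` (days per
unit) is explicit because a and b are unit-covariant: a slope quoted
against 27-day hazard bins is 27× the per-day slope, and day-scale values
are always derivable from the fit. The binned hazard uses the discrete
life-table convention — deaths in a bin over at-risk at bin start, censored
animals at risk through their censoring bin.

One caveat surfaced during validation: published Gompertz parameter pairs
quoted against 3-week/27-day bins do not always imply the same medians as
the accompanying KM curves under that unit; the unit-robust claim — the
DR rate of aging is lower than the AL one — is what the study-scale tests
assert, over replicates, because at ~40 animals per arm the significance
of that separation is itself borderline and seed-dependent.

## DEG enrichment

Classification removes genes with a missing adjusted p in either table,
then splits the shared universe at padj < 0.05 (strict). Enrichment is
g₁/(g₁+g₃) — the sex-DEG fraction of diet DEGs — with a two-tailed Fisher
exact p (sum of hypergeometric outcome probabilities ≤ the observed one).
The bootstrap null draws, per iteration, one expression-matched non-DEG per
diet DEG (window ±2% of the DEG's own mean expression — relative, since
expression spans orders of magnitude; an empty window is an error naming
the gene). Draws are independent across pools; a gene drawn twice is
collapsed when the control contingency is built, and the control universe
is every gene with a non-missing padj in the sex table. True diet DEGs are
not excluded from the "not in control set" margin (configurable reading of
an underspecified construction). Medians of enrichment and p over B
(default 1000) iterations summarize the null.

## Synthetic generators

All generators are pure functions of (config, seed).

**Tracks.** Per trial the fish wanders mid-low in an 800×600 px tank
(mean-reverting walk, occasional 15–30 px darting moves), initiates a
straight-line decelerating ascent at the trial's true latency (reaching a
point just under the food-drop site within 1.5 s — fast initiation, glide
to rest), eats at the surface for ~3 s, then dives back to depth over
~2.5 s. The dive matters: real sessions contain fast downward motion, and
without it the pooled velocity range has so weak a negative tail that the
75%-of-range burst threshold sits high and systematically lags ascent
initiation. True latencies follow a geometric decay from 12 s to ~3.7 s
over 17 trials (early failures, late successes; two consecutive successes
typically from trial 4) plus per-trial jitter. Artifacts: Gaussian keypoint
noise (5 px), likelihood dropouts (5% of frames; likelihood below 0.999 and
garbage coordinates), and single-frame 450 px teleports (1%) placed only
where both neighboring frames are clean — otherwise neither oversized step
is computable and the artifact would be undetectable by construction.
Manual score sheets are derived from the truth (idealized scorer), with an
optional pre-latency abandoned ascent plus pause to exercise the restart
rule.

What the generator does *not* emulate: real pose-estimator error structure
(correlated drift, identity swaps, likelihood miscalibration), wall
effects, or fish that approach the surface without feeding motivation.
Passing recovery tests therefore show the detector is correct under the
stated motion model and artifact rates, not that the thresholds transfer to
arbitrary recording conditions — per-animal overrides exist precisely
because real data sometimes needs them.

**Feeder logs** are Bernoulli misses on 7 scheduled feedings/day.
**Lifespans** are inverse-CDF Gompertz samples,
t = (1/b)·ln(1 − (b/a)·ln U), exponential at b = 0, with optional uniform
thinning to censor. **DEG tables** plant a joint sex×diet significance
distribution via P(sex DEG | diet DEG), adjust the complementary
conditional to preserve the marginal, and draw mean expression log-uniform
over four orders of magnitude so the ±2% matching density is constant
(a lognormal option retains sparse tails, which legitimately produce the
empty-matched-pool error). `expr_dependence` > 0 biases diet-DEG status
toward high expression to stress the matching.

## Problem sizes in the test suite

Study-scale checks use the assay's own dimensions: 16 fish × 17 trials ×
360 frames for latency recovery (10 generator seeds), 39 animals per diet
arm for the Gompertz separation (10 replicates), n = 500 × 100 replicates
for Gompertz coverage/bias, 4000-gene tables × 20 seeds × 200 bootstrap
iterations for enrichment calibration, and full enumeration for the exact
tests (≤ 2⁸ sign patterns; ≤ C(8,4) labelings per case). A clean-data
latency check asserts recovery within 0.25 s — with a 1 s rolling window
and a smooth ascent, the threshold crossing is inherently a few frames wide
of initiation, so frame-exact recovery is not a meaningful target.

## Known limitations

- The t₁ detector anchors on the rolling-velocity threshold crossing; its
  small systematic offset (±0.1–0.2 s) depends on the ascent speed profile
  and the pooled velocity range. It is accurate at frame-rate resolution,
  not sub-frame.
- Gompertz CIs are Wald-type from the observed information; for very small
  event counts a profile-likelihood interval would be preferable.
- The bootstrap precision point estimate inherits the small-n downward bias
  of resampled SDs (a few percent at n ≈ 20).
- The Cox proportional-hazards factorial analysis of sex×diet is outside
  this package's scope; use lifelines or R `survival` directly on the same
  lifespan tables.
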