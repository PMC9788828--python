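# killicog

Analysis toolkit for automated-feeder studies in the African turquoise
killifish (*Nothobranchius furzeri*): quantifying associative learning from
pose-estimation tracks, feeder fidelity and precision, dietary-restriction
lifespan effects, and sex-by-diet overlap in differential gene expression.

## Who this is for

Labs running Pavlovian conditioning assays in fish with video tracking
(DeepLabCut-style keypoint exports), automated feeders that log scheduled
vs. confirmed food deliveries, lifespan cohorts under ad libitum (AL) vs.
dietary-restricted (DR) regimens, and bulk RNA-seq DE tables. Every input
the pipeline consumes can also be produced by the built-in synthetic
generators with ground truth, so the whole chain is testable without any
recordings.

## What it computes

**Latency of the first surface-bound trajectory (t₁).** Keypoint tracks
(head/tail/food-drop/cue-light; x, y, likelihood per frame at 20 fps) are
prefiltered in three steps: likelihood gating (< 0.999 → missing), a pooled
jump filter that masks the second frame of any step in the top 5% of the
Euclidean step-distance distribution over all videos, and natural
cubic-spline interpolation of interior gaps (no extrapolation). Upward
velocity v(t) = −Δy·fps is smoothed with a 20-frame centered rolling mean;
per animal, velocity bursts are maximal runs above

    v_threshold = v_min + 0.75 · (v_max − v_min)

of the pooled rolling-velocity range, and surface arrivals are entries into
a 100–150 px radius around the food-drop site. t₁ is the start of the burst
closest to the first arrival (0 s if the trial starts at the surface, 18 s
if the fish never arrives). A trial is a successful association when
2 ≤ t₁ ≤ 9 — between cue-light onset and food arrival. Per fish the package
reports early (trials 1–7) vs late (trials 11–17) mean t₁ and percent
success, and the learning index 1/k*, where k* is the first trial starting
a run of two (or three, four) consecutive successes.

**Statistics.** Exact/tie-corrected Wilcoxon signed-rank and rank-sum
tests, Cohen's d with the t-based interval
d ± t·√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))), and a-priori sample sizes for the
two-group Wilcoxon–Mann–Whitney test by the A.R.E. method (t-test solution
inflated by 1/ARE; ARE = 3/π for a normal parent). Feeder precision is the
inverse variance 1/sd² of delivered food mass with the SD estimated by
bootstrap; fidelity is percent confirmed feedings plus a per-day deviation
histogram.

**Survival.** Kaplan–Meier medians and percent median-lifespan extension,
log-rank tests, binned empirical hazard curves, and censored maximum-
likelihood fits of the Gompertz mortality law h(t) = a·e^{bt} — baseline
hazard a ("frailty") and exponential slope b ("rate of aging"), with
observed-information CIs and an explicit time unit (a and b scale with it).

**Enrichment.** Sex-DEG enrichment among diet DEGs: genes with missing
adjusted p removed, 2×2 classification at padj < 0.05, enrichment
= |both| / |diet DEGs|, two-tailed Fisher's exact test, and a bootstrap
null from expression-matched control sets (for each diet DEG, one non-DEG
within ±2% of its mean expression), reporting median enrichment and median
p over iterations.

## Worked example

```python
from killicog.synthetic import TrackSimConfig, simulate_tracks
from killicog.pipeline import analyze_session
from killicog.stats import wilcoxon_signed_rank, wmw_sample_size

session, truth = simulate_tracks(TrackSimConfig(n_fish=4, seed=1))
t1_df, summary, reports = analyze_session(session)
print(summary[["fish_id", "mean_t1_early", "mean_t1_late",
               "pct_success_early", "pct_success_late",
               "learning_index_k2"]].round(2).to_string(index=False))
```

```
fish_id  mean_t1_early  mean_t1_late  pct_success_early  pct_success_late  learning_index_k2
 fish01           8.82          4.23              57.14             100.0               0.25
 fish02           8.84          4.24              57.14             100.0               0.25
 fish03           8.88          3.91              57.14             100.0               0.25
 fish04           8.94          4.03              57.14             100.0               0.25
```

The simulated animals associate the cue with food over the session: mean t₁
drops from ~8.9 s in the early trials to ~4 s in the late ones, late-trial
success reaches 100%, and each fish first strings two successful trials
together at trial 4 (learning index 1/4 = 0.25). A paired signed-rank test
of early vs late mean t₁ over these four fish gives p = 0.125 (the n = 4
floor for the exact test), and the automated t₁ lands within 0.25 s of the
generator's true initiation time in 100% of these trials. A power
calculation for a young-vs-old comparison at the observed learning-index
effect size:

```python
>>> wmw_sample_size(0.7862264, alpha=0.05, power=0.8, parent="normal")
28
```

i.e., 28 animals per age group.

The same pipeline runs from the shell on a directory of track CSVs:

```bash
killicog run --tracks tracks/ --meta meta.csv --out results/
killicog survival --input lifespans.csv --group diet --unit 27
killicog enrich --sex sex_degs.csv --diet diet_degs.csv -B 1000 --seed 7
```

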