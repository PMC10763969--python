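# Methods

## Scope and data model

The package analyzes three recording modalities at their native resolutions:
per-minute beam-cross counts (activity monitors), per-stimulus response
records (vibration-arousal assays), and per-5-minute VCO₂ bins (flow-through
respirometry with simultaneous activity recording). All times are handled as
0-based minutes since recording start plus a Zeitgeber anchor
(`zt0_offset_min`, the first minute's offset from lights-on), every interval
is half-open, and phase is derived as day iff (ZT minute mod 1440) < 720
under a 12:12 LD cycle. A minute is *active* iff its count exceeds zero;
this dichotomy is the foundation of every scorer, so the monitor reader
refuses silent timestamp gaps (zero-filling is opt-in) — an undetected gap
would corrupt minute-pair transition counts.

## Sleep scoring and architecture

Sleep is a maximal run of ≥ `min_bout` (default 5) consecutive inactive
minutes. Runs clipped by a recording edge still count as bouts but carry
truncation flags, since excluding them would systematically bias night
totals; the flags keep them auditable. Per-phase metrics assign bout
*minutes* by overlap, while a bout is counted in the bout *number* of every
phase it intersects (per-phase bout counting for boundary-spanning bouts has
no single convention in the field; this one is symmetric and is what the
per-phase mean bout length — phase sleep total over phase bout count —
assumes). Waking activity divides a phase's total counts by its waking
minutes. Quantities with empty denominators (no bouts, no waking minutes)
are reported as missing, never as zero, so they cannot drag group means.

## Transition propensities

P(Doze) and P(Wake) are conditional frequencies over minute pairs (t, t+1):
transitions out of the active (resp. inactive) state divided by the number
of active (inactive) origin minutes, with each pair assigned to the phase of
its origin minute t. The hourly profile applies the same ratios within ZT
hours of t, one value per fly per hour, summarized across flies with mean
and SEM. Undefined ratios (a fly never inactive during an hour) propagate
as missing.

## Arousal threshold and reactivity

A fly is "asleep at a stimulus" when the inactive run ending at the stimulus
minute is at least `min_bout` long — the causal application of the same
sleep rule, with the preceding-run length as its time asleep. In the
escalating design the threshold is the first intensity with a response
within 15 s, divided by the protocol maximum (1.2 g), so the default
four-level series yields thresholds in {0.25, 0.5, 0.75, 1.0}. The 0 g
delivery is treated as a sham: a "response" to it marks spontaneous waking
and never defines a threshold. Sleeping flies that respond at no level are
censored; the default policy excludes them from per-fly means but always
reports the censored fraction (an `assign_max` policy scores them 1.0
instead — both are defensible, so the choice is explicit and configurable).

Reactivity uses the fixed maximal stimulus with a 60 s window. Only
sleeping-fly trials enter; each is a 0/100 outcome at its prior time asleep.
The regression runs at trial level by default because bin-level percentages
discard the unequal trial counts per bin (binning to half-open 5-min bins
over 5–40 min plus an overflow bin is provided for description and plots).

## Metabolic downscaling

A calorimetry bin is *sleep* when all five of its minutes lie in one scored
bout, *wake* when none does, *mixed* otherwise; mixed bins are excluded from
state means and bout profiles so they cannot dilute the state contrast.
Bout profiles are taken only from bouts whose start lies on the instrument's
bin grid (the VCO₂ stream is never re-binned or interpolated; an
`allow_offset_min` tolerance instead starts the profile at the first full
grid bin inside the bout). Within a bout, Δₖ = (v₁ − vₖ)/v₁ × 100, so
positive values denote suppression; the statistic is scale-invariant, which
keeps the pipeline agnostic to instrument units. Bouts with v₁ = 0 cannot
be normalized and are dropped with a flag rather than treated as infinite
change. Δₖ is attributed to 5·k minutes asleep and averaged across each
fly's qualifying bouts per phase.

The Δ-vs-time regression uses points up to 40 minutes asleep by default.
Two reasons: long bouts are exponentially rare, so later time points rest on
a handful of high-leverage bouts; and once suppression bottoms out the
relationship flattens, so a straight line through the full range understates
the early-bout decline. The window matches the reactivity analysis's
5–40 min range and is configurable (`max_time_asleep_min=None` fits
everything).

## Regression and ANCOVA

`ols_fit` is the closed-form simple regression; the slope F statistic is the
squared slope t on (1, n−2) df. `ancova` compares residual sums of squares
of three nested models — separate lines, parallel lines, single line — and
tests sequentially: equal slopes on (g−1, n−2g) df, then, under a common
slope, equal intercepts on (g−1, n−g−1) df. The sequential structure
mirrors how slope and intercept differences are reported in practice:
intercept comparisons are only meaningful once a common slope is tenable.
Exact fits (zero residual variance, e.g. noiseless constructions) are
reported with an `exact_fit` flag and F ∈ {0, ∞} instead of dividing by
zero. No multiple-testing correction is applied inside this module.

## The synthetic cohort generator

The generator emulates the measurement chain so that every estimator has a
ground truth:

* **Activity** is a per-minute two-state chain with phase-dependent switch
  probabilities; active minutes emit zero-truncated Poisson counts (mean
  `lambda_active`), guaranteeing the active/inactive dichotomy exactly. The
  chain is simulated run-by-run with geometric dwell times, truncated and
  resampled at phase boundaries — by memorylessness this is exactly the
  per-minute law, at a fraction of the cost.
* **Arousal** responses at intensity s follow
  logistic((s − θ(t))/σ) with θ(t) = θ₀ + β·t (t = current time asleep);
  β > 0 produces deepening sleep, β = 0 a uniformly shallow sleeper.
  Latencies are uniform on the response window. A responder's assay minute
  is set active in the state copy used for subsequent bookkeeping
  (toggleable), and cohort monitor files are emitted from those
  post-stimulus states so the stimulus log and activity record agree.
* **VCO₂** per minute is `v_wake/5` awake and
  `v_sleep0/5 · max(1 − delta·t, floor_frac)` asleep, summed per bin and
  multiplied by mean-one lognormal noise with CV `cv_noise` (multiplicative
  noise keeps bins positive and respects the Δ statistic's scale
  invariance). Under this model E[Δₖ] ≈ 100·δ·5(k−1) in the pre-floor
  regime, which the recovery tests check against the exact per-minute bin
  means.

Determinism: every fly draws from an independent seed-sequence substream
keyed by (genotype, fly, purpose), so identical seeds give byte-identical
outputs and adding a fly never perturbs existing ones.

### Presets

The two shipped presets are invented emulations of a control genotype and a
shallow-sleep mutant, chosen once for realistic desk-scale cohorts; none of
the numbers is a measured value.

| parameter | control_like | nf1_like | meaning |
|---|---|---|---|
| p_doze day/night | 0.06 / 0.12 | 0.04 / 0.05 | per-minute fall-asleep propensity |
| p_wake day/night | 0.10 / 0.03 | 0.15 / 0.12 | per-minute waking propensity |
| lambda_active | 2.0 | 3.5 | beam crosses per active minute |
| theta0 (g) | 0.30 | 0.20 | baseline arousal threshold |
| beta_theta (g/min) | 0.02 | 0 | threshold rise per minute asleep |
| sigma_resp (g) | 0.30 | 0.30 | logistic response scale |
| v_wake / v_sleep0 | 1.0 / 0.8 | 1.3 / 1.1 | VCO₂ per bin awake / first sleep bin |
| delta (/min) | 0.01 | 0 | proportional VCO₂ decline (floor 0.5) |
| cv_noise | 0.05 | 0.05 | bin noise CV |

These encode the qualitative mutant phenotype: fragmented, shallower night
sleep (higher P(Wake), lower P(Doze)), hyperactivity, a flat and lower
arousal threshold, elevated CO₂ output in both states, and absent metabolic
downscaling.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the pipeline consumes —
minute-resolution state runs, phase dependence, stimulus-response coupling
to time asleep, bout-aligned metabolic decline — but not circadian drift
across days, anticipation peaks, inter-fly parameter heterogeneity beyond
sampling noise, sensor artifacts (stuck beams, double counts), or arousal
habituation. Passing recovery tests therefore demonstrates that the
estimators are correct under the stated model at realistic sizes, not that
the model captures every feature of real recordings.

## Numerical and procedural choices

* Monte-Carlo problem sizes: scorer oracle on 500 day-length traces; Markov
  recovery on 100 flies; downscaling recovery on 50 flies × 2 days with
  δ = 0.01/min and 200 replicates of 10 flies for the null-coverage check;
  reactivity recovery on 200 replicates of 50 flies; ANCOVA calibration on
  2000 null replicates; preset contrasts on 50 replicates of 30
  flies/genotype.
* Binomial-recovery tolerances are 3 standard errors of the pooled
  estimator; analytic Δₖ expectations use the exact deterministic bin means
  of the generative model.
* Exact-fit detection uses a relative residual threshold of 1e-14 against
  the response's total sum of squares.
* All-zero monitor channels are indistinguishable from unused channels in
  the fixed 32-channel dialect; the reader drops them unless channels are
  named explicitly.
* Files are ASCII with '.' decimal points; monitor dates are written ISO to
  avoid locale-dependent month names.

## Known limitations

* P(Doze)/P(Wake) assume a first-order chain; real flies show longer-range
  dependence (sleep inertia), which the estimator averages over.
* The ANCOVA is the classical homoscedastic sequential form; per-fly
  clustering of trials (reactivity) and of time points (downscaling) is not
  modeled, which is why the downscaling fit restricts to the well-replicated
  early-bout window.
* Censored arousal assays (no response at maximal intensity) make the
  default mean threshold a lower bound when censoring differs between
  groups; the censored fraction is always reported alongside.
* Bout profiles require grid-aligned bout starts by default, discarding
  roughly four of five bouts; the `allow_offset_min` tolerance trades
  alignment purity for sample size.
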