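# Methods

`limbuse` quantifies habitual upper-limb use in one-handed individuals
(congenital limb absence or acquired amputation) from bilateral body-worn
accelerometry, scores two questionnaire-based measures, and runs the
cohort-level statistical battery that relates these behavioural measures
to externally supplied sensorimotor activation estimates. This note
documents the models, the defaults and why, the synthetic data the tests
rely on, and the numerical choices.

## Movement detection

Each limb contributes a tri-axial acceleration trace in m/s² (gravity
included) sampled uniformly, by default at 100 Hz. The chain is:

1. **Smoothing.** Each axis is smoothed with a centred moving average
   spanning `smooth_ms` (default 500 ms). A boxcar was chosen as the
   simplest kernel that discards high-frequency noise; the published
   description names only a kernel duration. At the trace edges the
   window shrinks symmetrically (half-width `min(h, i, n−1−i)`), which
   preserves constants exactly and fabricates no samples.
2. **Windowed range.** For every window start (stride 1 sample) the range
   max − min is computed per axis over `window_ms` (default 400 ms).
   Stride 1 was chosen because non-overlapping windows would undercount
   short movements. Windows are evaluated only where fully inside the
   trace; padding would fabricate quiescence.
3. **Threshold + quiescence.** A candidate event is a maximal run of
   window positions whose range exceeds `threshold` (default 0.2 m/s²) on
   at least one axis. It is accepted only if the `quiescence_ms` interval
   (default 400 ms) immediately before its first supra-threshold window
   and after its last one lies inside the trace and contains only windows
   with range strictly below threshold on **all** axes. The quiescence
   duration is not part of the published description; one full window per
   side is the package's default and it is exposed as a parameter. An
   event's span is its run plus the window span of the last position,
   making events disjoint and order-deterministic.

Because the range statistic cancels constant offsets, no gravity removal
is performed and detection is invariant to adding a constant to any axis.
A range exactly equal to the threshold is neither "movement" (strictly
above) nor "quiet" (strictly below); this follows the rule literally and
matters only on a measure-zero set for continuous data.

Multi-day recordings are pooled per limb by summing counts before the
laterality ratio, so both limbs always cover the same epochs and the
ratio cancels differences in recording hours. Non-wear detection is out
of scope; wear time is taken to be the recorded duration.

## Behavioural scores

* **Laterality index** `LI = (intact − residual)/(intact + residual)`
  over detected movement counts: +1 exclusive intact-hand use, 0
  balanced, −1 exclusive residual-arm use. A zero total count raises an
  error rather than returning 0, because 0 encodes *balanced* use.
* **Modified Motor Activity Log (MAL).** 27 daily-activity items rated
  0/1/2 (never/sometimes/very often) for how frequently the residual arm
  is incorporated; the score is the item sum divided by 54, in [0, 1].
  Incomplete questionnaires are rejected rather than prorated — the /54
  normalisation presumes 27 answered items. Frequency, not movement
  quality, is rated.
* **Chronic pain magnitude** = intensity (0–10) / frequency code (1 =
  all the time … 5 = once or less per month); constant intense pain
  scores highest.

## Statistical battery

Two-sample contrasts are gated on Shapiro–Wilk normality (α = 0.05 per
group): Student's *t* with pooled variance when both groups pass (Welch
is available as an option but pooled variance is the default, as no
correction is named in the source analyses), Mann–Whitney *U* otherwise
(exact p for combined n ≤ 20 without ties; tie-corrected normal
approximation otherwise, matching common practice at these sample
sizes). The branch taken is a pure function of the Shapiro–Wilk p-values,
is recorded in the result, and can be forced for testing.

The group × limb ANOVA has one between-subjects factor (group) and a
two-level within factor (limb). With two within levels the classical
split-plot sums-of-squares decomposition reduces exactly to a one-way
ANOVA on per-subject difference scores, which is how the interaction
F(a−1, N−a) is computed here (verified against an independent cell-mean
decomposition and against pingouin, including unbalanced groups).
Sphericity is moot with two levels.

Covariate-adjusted group contrasts fit `y ~ group + covariates` by OLS
and report the group effect as the nested-model F(1, n−k−1). Covariates
are used unstandardised; rank-deficient covariate sets are an error
naming the columns. Partial correlations residualise both variables on
the nuisance columns (with intercept) and test the residual Pearson r on
n−2−k df; directional (one-tailed) hypotheses must declare their
direction, otherwise the test falls back to two-tailed with a warning.
Two independent correlations are compared with Fisher's r-to-z.

Planned comparisons (two per limb, hypothesis-driven) are tested at
α = 0.025; everything else at 0.05. Degrees of freedom are always
computed from the records actually used — participants missing a value
are excluded from that test only, and exclusions are logged. Per-analysis
exclusions (e.g. dropping participants whose residual arm ends above the
elbow from arm contrasts) are declarative subset filters in the analysis
plan, not code.

## Synthetic data

The generators make every stage verifiable without participant data;
they emulate structure, not biomechanics.

**Paired traces.** Each limb's trace is gravity offset + Gaussian sensor
noise (default σ = 0.02 m/s²) + single-cycle sinusoidal bursts on one
randomly chosen axis per event. Event counts are Poisson at per-limb
rates (defaults 6/min intact, 2/min residual) plus whole-body events at
`coupled_rate` (default 1/min) that share timing across limbs but draw
independent axes, mimicking trunk movements registering on both
monitors. Defaults: 0.5 m/s² peak-to-peak, 1000 ms duration. The burst
duration is deliberately double the smoothing kernel: a 500 ms boxcar
attenuates a single-cycle sinusoid roughly in proportion to the kernel/
burst-duration ratio, and a 1000 ms burst at 0.5 m/s² retains a smoothed
within-window range of ≈0.3 m/s², comfortably above the 0.2 m/s²
threshold. Onsets are placed with a minimum inter-burst gap
(`min_gap_ms`, default 3000 ms): smoothing smears each burst's
supra-threshold footprint by about half a kernel on each side, so the
gap must accommodate smear + quiescence + window (≈1.3 s) for adjacent
events to remain individually detectable; 3 s leaves a safety factor of
two. In this regime the detector recovers generated counts exactly
(verified over 200 seeds), which is a statement about the generator's
idealised bursts — real recordings have coloured noise, variable-duration
movements and non-wear periods, so exact recovery there is not implied.

**Cohorts.** Group sizes default to 11 congenital / 18 acquired / 21
controls. Within each one-handed group, MAL, intact-hand β and (acquired
only) the continuous pain score are drawn from a trivariate normal with
corr(MAL, β) = `usage_beta_rho` (default −0.43) and corr(pain, MAL) =
`pain_usage_rho` (default −0.40), pain and β conditionally independent
given usage. Laterality indices are independent per-group normals:
congenital N(0.40, 0.22), acquired N(0.65, 0.15) — a between-group
separation of ≈1.3 pooled SD with both groups well above zero, matching
the qualitative pattern (both groups favour the intact hand; the
acquired group more strongly). MAL defaults N(0.65, 0.15) congenital vs
N(0.43, 0.15) acquired (≈1.5 SD separation, congenital higher).
Activation cell means default to over-used-limb-high (congenital:
residual 1.0 / intact 0.3; acquired: 0.2 / 1.0; controls 0.5 / 0.5,
σ = 0.8). Bounded scores are clipped to their scales with a logged
count; at the defaults clipping affects ≈1% of draws, so the generating
moments are effectively the population moments. The continuous pain
score is encoded into intensity/frequency codes such that
intensity/frequency reproduces it to within rounding; congenital
participants get zero pain and deprivation age 0 (no amputation event).

Null-calibration checks use the same generator with all group means
equal and correlations zero; at 2000 replicates the gated two-sample
test and the ANOVA interaction reject at their nominal 0.05 / 0.025
rates within binomial 95% bounds. Correlation recovery uses homogeneous
group means so the generating ρ is the estimand; the mean recovered r
over 1000 replicates at n = 28 matches ρ up to the standard
small-sample bias of the Pearson estimator, ρ(1−ρ²)/(2n).

## Numerical and design choices

* Windowed max/min use order-statistic filters (O(n)); results are
  checked against a brute-force per-window scan in the tests.
* All randomness flows through one `numpy.random.Generator` per
  generator call, seeded explicitly; identical seed ⇒ bit-identical
  output, including written CSVs (floats are serialised at %.17g and
  parsed round-trip).
* Degrees of freedom are reported from the data (n−2 for Pearson,
  n−2−k for partial correlations), never copied from external sources.
* Problem sizes in the test suite (1000 randomized traces for oracle
  equivalence, 200 seeds for count recovery, 2000 replicates for null
  calibration, 1000 for correlation recovery) keep the full suite under
  a minute on one CPU while leaving Monte-Carlo error well below the
  asserted tolerances.

## Known limitations

* The detector presumes uniform sampling at the declared rate and does
  not model non-wear, posture or sensor orientation beyond a constant
  offset.
* The synthetic traces' noise is white and bursts are stereotyped; the
  detector's exact-recovery guarantee applies to that regime only.
* ROI activation values (β) are consumed as plain numeric columns; no
  imaging data are read or processed.
* The mixed ANOVA returns the interaction effect (the quantity the
  analysis plan uses); main effects are available through the underlying
  one-way decompositions but are not part of the standard battery.
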