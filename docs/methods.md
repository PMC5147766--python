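# Methods

## Scope and data model

The package analyzes circadian rhythmicity in three kinds of uniformly
sampled time courses: expression matrices (transcripts × ordered
circadian-time libraries), per-larva locomotor records, and reporter traces
(whole-larva bioluminescence, per-gland melatonin release). All share the
`CircadianSeries` container: values at interval `dt_hr`, a circadian-time
origin `t0_ct_hr` (CT0 = lights-on of the last entrainment cycle; CT is
folded modulo 24 and persists under constant conditions), an experiment-time
origin for schedule lookups, and a `LightingSchedule` of contiguous
light/dark/dim epochs.

## The G-factor screen

**Statistic.** The G-factor is the fraction of non-DC discrete-Fourier
power at the circadian harmonic `k* = round(n·dt/T)` (T = 24 hr by
default). Series are truncated to the largest whole multiple of the target
period before scoring, so `k*` is always an integer harmonic; constant
series raise a zero-variance error. The statistic is a Fisher-g-style ratio
restricted to one harmonic: invariant to affine transforms of the data and
to circular shifts by whole periods.

**Permutation null.** Each series' sample order is shuffled uniformly
(default 100 shuffles) and rescored; shuffling destroys temporal structure
while preserving each series' marginal distribution. Shuffle streams are
seeded per series label, which makes detection invariant to input row
order. Zero-variance series contribute g = 0 to the pool with a warning.

**List calibration.** Series are ranked by g (descending, ties stable in
input order). For list length L with threshold `g_L`, the estimated false
detections are `FP(L) = #{pool ≥ g_L}/n_permutations` (pool values tied
with `g_L` count as exceedances — conservative), and the estimated
true-positive rate is `max(0, 1 − FP(L)/L)`. The chosen length is the
largest L whose estimate meets the target (default 90%). Note a structural
property of this rule: on pure-noise data it still admits a short list in
roughly 10% of datasets at a 90% target, because the exceedance count given
the top-ranked score is approximately exponentially distributed with mean
`n_permutations`, and falls below `0.1·n_permutations` with probability
about `1 − e^{-0.1} ≈ 0.1` regardless of the permutation count. Raising the
target level tightens this in proportion.

**Group comparison.** Between-genotype differences in rhythmicity are
tested with the two-sample Kolmogorov–Smirnov statistic (asymptotic
p-values via scipy), reported with group medians.

## Transcriptome preprocessing

Fixed order: `log2(x+1)` (the pseudocount is a package choice; the log base
is not material because the screen is scale-invariant), quantile
normalization across all libraries given (rank values within each library,
replace by the mean across libraries of same-rank values; ties share the
mean of their tied ranks' reference values), then removal of the
`floor(N/4)` transcripts with the smallest maximum expression (lower
quartile by rank count — unambiguous for ties and small N — with ties
broken by input order). Quantile normalization is exactly idempotent on
tie-free data; with ties the tie-averaging step can perturb the shared
multiset by a vanishing amount.

The gene-list comparison is exact set algebra (maintained = A∩B,
lost = A∖B, acquired = B∖A). `classify_basal_change` exposes the
qualitative fates of clock-controlled genes as a reproducible rule:
a mutant-rhythmic gene is `maintained_rhythm`; otherwise the mutant/control
mean ratio classifies `arrhythmic_high` (≥50%), `arrhythmic_down`
(5–50%) or `arrhythmic_abolished` (<5%). The 50%/5% thresholds are package
parameters, not measured constants.

## Behavior metrics

* **Activity**: total distance per 10-min bin (half-open bins, trailing
  partial bin dropped); presentation uses a centered 20-point moving
  average with trimmed edges (centered was chosen; trailing would lag the
  phase by half a window).
* **Movement detection**: velocity hysteresis — moving starts at
  ≥0.6 cm/s, stops at ≤0.59 cm/s, and the state persists between the two
  thresholds (the two printed thresholds only make sense as a hysteresis
  pair; initial state is stopped).
* **Sleep**: a minute with zero movement-seconds is asleep; sleep minutes
  are summed per hour, so sleep + waking minutes = 60 exactly. **Waking
  activity** is movement seconds per awake minute and is undefined (NaN,
  never zero) for fully asleep hours.
* **Period**: Enright/Sokolove–Bushell chi-square periodogram,
  `Qp(P) = N · Var(column means) / Var(series)` after folding at P
  (whole-bin folding, remainder dropped), which is ~χ² with `P/dt − 1`
  degrees of freedom under white noise; the best period is the grid
  argmax above the χ²(1−α) line (α = 0.05, grid 20–28 hr in one-bin
  steps). A plainer reading of the usual "between-column over total
  variance" phrasing omits the row-count normalization and is then neither
  χ²-distributed nor able to cross its own significance line even for a
  noiseless signal, so the canonical normalization is used.
* **Amplitude**: (peak of day-7 activity − preceding trough)/2, windows
  anchored at CT0 on the days-post-fertilization clock (recordings start
  day 6); the preceding trough is searched between the previous day's peak
  and the day-7 peak.
* **Masking**: percent of total activity within light vs dark bouts of the
  schedule.
* **Place preference**: larvae are assigned to the top/middle/bottom
  thirds of the water column (boundary positions go to the upper zone — a
  deterministic tie rule); per-5-min-bin fractions always sum to 1.
* **Day/night summaries** partition hours by CT into subjective day
  (CT 0–12) and night (CT 12–24), or caller-specified windows (e.g.
  CT 5–6 vs CT 17–18), yielding per-individual means for paired tests.

## Reporter conditioning

Bioluminescence: 3-hr centered running-mean smoothing (suppressing counting
noise), division by a 2-day running mean (multiplicative detrending, chosen
over subtraction so sensitivity drift cancels; windows shrink at trace
edges to preserve length), then division by the trace mean — output mean is
exactly 1. Melatonin: each gland's series is divided by its own maximal
night-time level; "night" under constant darkness means subjective night
(CT 12–24), and the global night maximum over the recording is used (the
choice between first-night and global maximum is open; global is stable
when the two nights differ by noise).

## Synthetic data

Generators are pure functions of (parameters, seed) and emit ground truth
alongside every object; no pipeline stage reads the truth labels.

* **Expression**: 12 points, 4-hr spacing, two DD cycles starting CT14.
  Rhythmic rows are `baseline + A·cos(2π(t−φ)/24) + N(0, σ)` on the log2
  scale with `A = snr·σ` and uniform phases; null rows are baseline plus
  noise. Defaults: baseline 8, σ = 1 (log2 units) — chosen as realistic
  for quantile-normalized log counts; the upstream assays' noise is not
  characterized, so Gaussian-on-log is an explicit assumption.
* **Locomotion**: expected activity is a cosine (defaults: baseline
  20 cm/10 min, control amplitude 13.4 vs clock-blocked 4.5 — printed
  group estimates used as generator defaults, not fitted values) with
  truncated-at-zero Gaussian bin noise (σ = 6 cm/10 min, a package
  choice). Light masking is multiplicative (`masking_gain` in dark
  epochs); only the phenomenon, not a mechanism, is modeled. Per-frame
  velocities consistent with the binned distances are emitted for sleep
  scoring by spreading each bin's distance over a contiguous run of
  moving seconds at ~1 cm/s.
* **Bioluminescence**: cosine plus linear per-day drift plus fast Gaussian
  jitter, floored at zero.
* **Melatonin**: night-peaking cosine (acrophase CT18) with multiplicative
  lognormal noise (σ = 0.2); lights-on multiplies expected release by 0.02
  (clock-independent suppression), which keeps light-epoch values below 5%
  of the night maximum for any noise draw. The clock-blocked genotype is
  flattened (amplitude 0.1 vs 0.45) with a +0.25 subjective-day baseline
  elevation.

What the generators do **not** emulate: count-based mean–variance coupling
in expression data, bout structure and ultradian rhythms in locomotion,
developmental trends across days, or inter-individual phase dispersion.
Passing tests therefore demonstrate correctness of the procedures and
their calibration under the stated noise models, not robustness to every
property of real recordings.

## Problem sizes and numerical choices

The calibration simulation uses 1,000 transcripts (100 rhythmic at snr 2,
900 null), 100 permutations, 20 seeds — comfortably a desk-scale run.
Period recovery uses 10-day synthetic recordings so the fold has enough
rows to resolve a single 10-min grid step across generating periods
23.6–25.8 hr; amplitude recovery uses 3-day recordings at snr 5 with the
20-point moving average applied first (its ~3% attenuation of a 24-hr
cosine is well inside the 10% recovery tolerance). Behavioral series are
truncated to whole 24-hr multiples before G-factor scoring. All
tolerance-sensitive kernels (DFT scoring, periodogram, quantile
normalization, KS distance) are verified against independent brute-force
oracles in the test suite.

## Known limitations

The exact G-factor and permutation design of the original screen live in
an unpublished supplement; the definitions above are this package's
declared contract, chosen to match the printed phenomenology (ratio near 1
for clean 24-hr signals, permutation-estimated true-positive calibration,
90%/10% nominal levels). The all-null false-selection property of the list
rule (~10% of datasets admit a short spurious list at the 90% target) is
inherent to the rule, not an implementation artifact. The chi-square
periodogram grid is limited to periods at whole-bin multiples; periods
between grid points resolve to the nearest bin.
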