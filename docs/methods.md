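# Methods

`soflow` implements an event-related effective-connectivity analysis of
NREM sleep EEG. This note documents the models, the numerical choices
made where the procedure left latitude, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Slow-oscillation detection

SOs are detected per channel on the 0.1–4 Hz band-passed trace
(order-4 Butterworth, zero phase). A candidate wave starts at a
positive-to-negative zero crossing, its negative half-wave ends at the
next negative-to-positive crossing, and the candidate ends at the
following positive-to-negative crossing. A candidate becomes an SO iff

1. its trough is at or below −80 µV,
2. its peak-to-peak range is at least 80 µV,
3. the negative half-wave (first to second zero crossing) lasts between
   300 ms and 1 s, and
4. the whole candidate spans at most 10 s,

with the trough inside a Stage-2/SWS epoch. Note a geometric property of
this definition: because candidates are delimited by zero crossings, the
candidate maximum is ≥ 0, so any wave satisfying criterion 1
automatically satisfies criterion 2; criterion 2 can only reject waves
that already fail criterion 1. The test suite's distractor set reflects
this (its small-peak-to-peak wave necessarily violates both).

If two candidates on a channel ever share samples the deeper trough
wins. Detection is invariant to constant offsets (removed by the
band-pass). Sub-sample trough interpolation is not performed; at 256 Hz
the quantization is ±2 ms.

## MVAR estimation

Directed flow rests on a multivariate autoregressive model
X(n) = Σₖ Aₖ X(n−k) + w(n) over the 12 analysis channels
(F3 Fz F4 C3 Cz C4 P3 Pz P4 O1 POz O2), fitted in sliding 0.5-s windows
(128 samples at 256 Hz, 2-sample stride — 193 windows per ±1-s SO
epoch), after an order-46 zero-phase Butterworth high-pass (stopband
edge 0.5 Hz, critical frequency 0.75 Hz) that removes the SO wave
itself. Windows are demeaned per channel before fitting.

The default model order is p = 13, selectable by AIC
(ln det Σ̂ + 2pN²/W, median over sampled windows, one global order).
With N = 12 and p = 13 a 128-sample window supplies 115 equations
against 156 regressors per channel, so ordinary least squares is
underdetermined: an exact interpolating fit with zero residuals and a
singular noise covariance, which the GPDC normalization cannot use.
Two estimators are therefore provided:

* **`ols`** — stacked multivariate least squares with residual
  covariance Σ̂ = E Eᵀ/(W−p). Requires W − p > N·p and raises
  otherwise. Used for long windows and all oracle comparisons.
* **`vm`** — the Vieira–Morf multichannel Burg recursion, which builds
  the coefficients order-recursively from forward/backward reflection
  matrices and remains well conditioned on short windows. This is the
  sliding-window default. On long stationary data it agrees with OLS
  (coefficient differences < 0.01 in the test fixtures).

A consequence worth stating plainly: at p = 13 on 128-sample windows the
estimator is heavily over-parameterized and the GPDC quantifiers carry a
large estimation-noise floor (outflow ≈ 0.58 for 12 channels even
without any true coupling). True coupling shifts the mean above this
floor by a modest amount, so event-locked structure emerges only after
averaging over many SOs — which is exactly how the analysis uses it.

## GPDC and flow quantifiers

From fitted coefficients the spectral transfer matrix is
Ā_ij(f) = δ_ij − Σₖ a_ij(k) e^(−2πifk) on 128 uniform normalized
frequencies in (0, 0.5] (1-Hz spacing at 256 Hz). Generalized partial
directed coherence weights by residual variances:

|π̄_ij(f)| = (1/σ_i)|Ā_ij(f)| / sqrt(Σₖ |Ā_kj(f)|²/σ_k²),  σ_i = sqrt(Σ_ii)

Each column satisfies Σᵢ |π̄_ij(f)|² = 1 exactly (checked to 1e-8 on
every fitted window in the tests), which makes outflows comparable only
within a column and makes the measure insensitive to per-channel
amplitude scale — the reason GPDC is used instead of plain PDC.

The frequency-averaged matrix π(i,j) defaults to the mean of |π̄_ij(f)|
over the grid (averaging |π̄|² and taking the square root is available as
`average="power"`; the procedure's wording does not disambiguate).
Two quantifiers summarize a source channel CH ∈ {Fz, Cz, Pz, POz}:

* CH→R = Σ_{i∈R} π(i,CH)² for a sink region R ∈ {F, C, P, O},
* CHoutflow = Σ of CH→R over the regions other than CH's own.

## Phase machinery

Each SO's phase is the unwrapped analytic-signal angle of the *negated*
0.1–4 Hz epoch (±1 s around the trough; negation maps the trough onto
the analytic peak), shifted so the trough sample is exactly 0, with a
10% cosine (Tukey) taper against Hilbert edge artifacts (`taper=False`
disables it). Quantifier values at the 193 window centers are linearly
interpolated onto the fixed grid −π…π in steps of π/64 (129 points),
restricted to the largest interval around the trough where the phase
increases strictly monotonically, clipped to [−π, π] but keeping one
bracketing sample past each bound so the ±π grid endpoints are
reachable. Uncovered grid points are missing; subject means are
pointwise available-case averages. Peak extraction takes the maximum
over grid points in (−π, 0) (prepeak) and (0, π) (postpeak); ties
resolve to the earliest grid point.

## Clustering and coupling

Each detected SO (all 22 channels) gets a binary footprint: component j
is 1 iff any SO trough on channel j lies within ±400 ms. K-means under
Hamming distance with K = 2 is implemented as K-modes: centroids are
componentwise majorities (ties → 1), assignment is minimum Hamming
distance (ties → lower cluster index), 200 random restarts keep the
lowest total within-cluster distance, and the cluster with the larger
mean footprint is labelled Global. On 8 vectors the result matches
exhaustive enumeration. Stage-2 and SWS footprints are pooled. An SO is
spindle-coupled when any spindle interval on any channel intersects
±1 s of its trough (noncoupled = 1, coupled = 2 in the statistics).

## Statistics

Channels/regions are coded 1–4 anterior→posterior (Fz/F = 1 …
POz/O = 4); distances are absolute index differences and the relative
distance is D(sink, SO) − D(source, SO). Before each test, values
outside mean ± 2 SD of their cell (computed once) are dropped.

* SO vs non-SO: one-way ANOVA over the five canonical phases
  {−π, −π/2, 0, π/2, π} plus non-SO windows, Tukey-HSD post hoc
  contrasts of each phase against non-SO, tiers <0.005 / <0.05 / <0.1.
* Peak heights: linear mixed-effects model (random intercept per
  subject, REML via statsmodels MixedLM; the Powell fallback handles
  the zero-variance boundary, where the fit equals OLS).
* Behavior: per distance group, improvement ratio (post/pre-sleep
  word-pair accuracy) regressed on per-subject mean post-trough peak
  flow; Bonferroni across groups, Benjamini–Hochberg for the
  cluster-stratified grid.

Non-SO control windows (one per SO) are 0.5-s segments on a random
source channel, fully inside Stage-2/SWS and >10 s from every SO trough
on any channel.

## Synthetic-data generator

The generator is the package's test bed and defines its study
conditions: 22-channel, 256-Hz recordings of alternating 5-min
Stage-2/SWS blocks (default 10 min per subject).

* **Background**: a stable VAR(2) (diagonal AR 0.55/−0.25) scaled to
  15 µV RMS, with directed lag-1 coupling (gain 0.15) from each source
  channel to the analysis channels of more posterior regions.
  Anterior→posterior-only coupling makes the off-diagonal block
  strictly triangular in the anterior-posterior order, so stability is
  set by the diagonal autoregression alone and any boost gain is safe.
* **SOs**: ~2 per in-stage minute, ≥4-s spacing, trough −110 µV,
  800-ms down state flanked by 550-ms up-state lobes whose amplitude
  balances the cycle to zero mean. The up-state lobes matter twice:
  they give the pre-trough phase a real −π anchor, and they size the
  full cycle so the ±π phase points fall inside the ±750-ms
  window-center span (hence all five canonical phases are covered).
  Global SOs cover all 22 channels, local SOs only the seed channel's
  region, with 10 ms propagation lag per anterior-posterior row step.
* **Coupling boost**: inside two windows at trough ±450 ± 200 ms the
  coupling coefficients are multiplied by 5, so the planted flow
  increase is genuinely Granger-causal. The boost sits entirely
  outside ±250 ms of the trough because the 0.5-s analysis window
  integrates ±250 ms around its center: boost mass closer to the
  trough would raise the trough-centred window as much as the flanking
  ones and erase the trough dip. The measured profile is the boost
  schedule convolved with the window, so its peaks land near phase
  ±π/2 (≈ ±400–450 ms with the default down state) by construction of
  this geometry, not by assertion.
* **Spindles**: 13-Hz, 0.8-s Hann-windowed bursts on the seed channel
  overlapping half of the SOs.
* **Behavior**: improvement ratio = 1 + slope·z(flow) + N(0, sd²) with
  slope 0.2 and sd 0.05; the demo cohort varies the planted boost
  (2→8) across subjects so a real between-subject flow gradient exists.

What it does **not** emulate: 1/f spectra beyond the VAR background,
artifacts, REM, realistic spindle morphology, or traveling-wave
dynamics beyond fixed lags. Passing tests therefore demonstrate that
the pipeline recovers known causal structure under its own model
assumptions, not that it is robust to real-data pathologies.

## Problem sizes

The test suite and the acceptance script run at reduced scale as the
package's reference configuration: single-subject end-to-end runs use
10-minute recordings (~20 SOs), demo cohorts 2–6 subjects, statistical
calibrations 50–1000 simulation seeds at n = 40 subjects, and
direction-recovery fits 50 windows of 20 000 samples. All randomness is
seeded; identical configs reproduce outputs bit-exactly.

## Known limitations

* The Vieira–Morf estimator at p = 13 on 0.5-s windows is strongly
  over-parameterized; quantifier values are dominated by a noise floor
  and are meaningful only relative to matched controls (non-SO windows,
  other phases) — not as absolute flow magnitudes.
* Zero crossings are sample-quantized; no sub-sample interpolation.
* The ANOVA treats subjects as independent observations per condition
  (a repeated-measures structure is not modelled).
* EDF export is not provided; recordings are written as TSV + JSON
  sidecar (EDF input is supported when `mne` is installed).
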