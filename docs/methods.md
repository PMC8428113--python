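# Methods

`syncdecode` implements a connectivity-pattern decoding analysis for
auditory working memory (WM), together with the synthetic-cohort machinery
needed to validate every stage against a known ground truth.  The chain is:

    ripple stimuli / staircase  →  synthetic cohort  →  Morlet spectra
    →  imaginary-coherence features  →  SVM decoding  →  permutation inference
    →  impulse ("activity-silent") contrast  →  behavioral SVR

This note records the model, the defaults and why, the numerical choices,
and what the validation studies do and do not establish.

## Scientific background

The hypothesis under test is that the *content* of auditory WM — which of
six ripple-sound classes a subject is holding in mind — is represented in
frequency-specific phase-synchronization patterns between subregions of the
superior temporal cortex (STC, housing auditory cortex) and frontoparietal
regions, rather than only in local activation.  The analysis therefore
decodes the maintained class from the pattern of imaginary coherence (ImCoh)
between every seed sub-ROI and target sub-ROI, separately per frequency band
(theta 3–7, alpha 8–12, beta 13–30, low gamma 31–60, high gamma 61–120 Hz)
and maintenance time window (early 0.5–1.25 s, late 1.25–2 s after the
memory cue; encoding 0–1 s after sound onset).

A complementary probe of "activity-silent" traces asks whether a
task-irrelevant noise burst (the *impulse*, on 50 % of maintenance trials)
transiently re-expresses the memory content in local oscillatory *power*
patterns: decoding accuracy from STC power should be higher on impulse than
on no-impulse trials.

## Stimuli and psychophysics

Dynamic ripple sounds superimpose log-spaced sinusoidal carriers
(`sinusoids_per_octave` per octave, inclusive grid from `f0` to `f_max`;
200–1600 Hz at 20/octave gives 61 carriers) whose envelope is

    s(g, t) = D0 + D·cos(2π(ωt + Ωg) + ψ),   g = log2(f/f0),

with ripple velocity ω (cycles/s) the decoded stimulus dimension and
Ω (cycles/octave) the spectral density.  Each carrier gets an independent
random phase; the waveform is peak-normalized.

The just-noticeable difference in log2 ripple velocity is estimated by a
2-down/1-up staircase, which converges on the 70.7 %-correct point of the
observer.  The printed literature leaves the schedule open, so the default
is: initial interval 2.0 log2 units, steps 0.4 → 0.2 → 0.1 (halving after
each of the first two reversals), stop after 8 reversals, estimate = mean
of the last 6 reversal intervals, interval bounded by [0.05, 4.0] log2
units (the 3–48 cycles/s range).  A track that sits at the upper bound for
more than half its trials is flagged as non-converged.

## The synthetic cohort generator

The generator defines the study conditions for every validation experiment.
Each sub-ROI time series is a sum of independent components:

* **1/f background** — Gaussian noise with power spectral slope −1
  (amplitude 1.0); source-level noise is not characterized in the
  literature, and a −1 slope is the standard field approximation.
* **Band-limited oscillations** — independent Gaussian narrowband noise in
  each configured band (amplitude 1.0), equal across conditions, so power
  alone carries no content information.
* **Zero-lag common component** — one shared 1/f signal per subject
  (amplitude 0.7) added to every sub-ROI *before* sign flips.  Real sub-ROI
  source estimates share instantaneous activity (field spread, common
  input); this is what makes data-driven sign alignment possible.  Because
  it is exactly zero-lag it cancels in the imaginary part of coherency and
  cannot create spurious ImCoh.
* **Planted couplings** — the condition-specific signal.  A coupling gives
  a seed and a target sub-ROI a common narrowband driver; the target copy
  is phase-rotated by a per-epoch angle drawn von Mises(Δφ_c, κ) where
  Δφ_c is the condition's mean lag and κ the concentration.  With analytic
  driver z, seed = Re[z] and target = Re[z·e^(−iθ)], the expected ImCoh is
  +coh·sin(Δφ_c): lag patterns translate directly into decodable ImCoh
  patterns while leaving power untouched.  Default condition lags are
  arcsin of six equally spaced values in [−0.9, 0.9], giving equally
  spaced ImCoh targets.
* **Impulse gains** — on impulse trials (50 % of maintenance epochs), the
  band oscillations are scaled by condition-specific power gains
  (log-normal, exp(strength·z) per sub-ROI × band) for t ≥ the impulse
  latency (2.5 s into the delay by default; reduced designs use earlier
  latencies with proportionally shorter epochs).
* **Sign flips** — each sub-ROI of each subject is multiplied by a random
  ±1, emulating the surface-normal sign ambiguity of source estimates.

Behavior is linked to the per-subject *coupling fidelity* (a N(1, 0.15)
multiplier on coupling amplitude): proportion correct =
clip(0.70 + 0.14·fidelity + N(0, 0.08), 0, 1), centered on the observed
0.84 mean performance of such tasks.

All randomness flows from one master seed through named
`numpy.random.SeedSequence` streams (`_seeds.py`), so any stage can be
reproduced in isolation and same-seed runs are bit-identical.

### Sign alignment

`align_signs` flips each sub-ROI to correlate positively with the
leave-one-out sum of the subject's other sub-ROIs, iterating to a fixed
point.  Anchored by the shared zero-lag component, this recovers a sign
assignment consistent *across* subjects (what pooled cross-subject decoding
needs) without using the generative truth.  Alignment only flips signs — it
cannot alter ImCoh magnitudes — and is idempotent.

## Spectral analysis

* **Morlet transform** — complex Morlet wavelets of 7 cycles, truncated at
  ±3.5 cycles (≈ ±3.1 Gaussian SDs), unit L2 norm (the natural choice when
  no normalization is printed).  Convolution uses zero-padding, and every
  sample within half the wavelet support of an epoch edge is masked
  invalid; masked samples are NaN-poisoned in power time courses and
  excluded from all window averages, never silently included.  A frequency
  whose wavelet outgrows the epoch is fully masked.
* **Frequency grid** — log-spaced bins inside each band, 5/5/18/20/21 for
  theta/alpha/beta/low-gamma/high-gamma (69 bins).  The per-band counts are
  taken as authoritative because no global 73-bin log grid reproduces them;
  reduced designs use the same bands with fewer bins per band.
* **Multitaper power** — `mne.time_frequency.psd_array_multitaper` with
  `normalization="full"` (proper density units, Parseval-consistent), per
  single epoch, 3–120 Hz.
* **Windows** — half-open `[tmin, tmax)` in seconds relative to the epoch
  origin, everywhere.
* **Relative power change** — (mean analysis − mean baseline)/mean
  baseline with baseline −0.4 to −0.2 s and analysis 0–2 s defaults; a
  non-positive or fully masked baseline is an error.

## Connectivity features

ImCoh(f, t) = Im[⟨Sx·Sy*⟩_k / √(⟨|Sx|²⟩_k·⟨|Sy|²⟩_k)], averaged over the
epochs of a quarter at each (f, t) bin first, then averaged (signed) over
the band's bins and the window's valid samples.  Sign convention: the
conjugation sits on the second argument, so `imcoh(S, S·e^{iπ/2}) = −1` and
the swapped order gives +1; antisymmetry under argument swap is exact (the
imaginary cross-spectrum is computed in real arithmetic so the negation is
bit-exact).  The signed value is kept — a classifier can exploit sign, and
taking magnitudes would discard half the planted information.

Epochs are first equalized per subject to the minimum condition count, then
partitioned into 4 disjoint, equal-sized, seeded quarters (remainder
dropped); quarters of fewer than 2 epochs are an error because coherence is
undefined.  Features are ordered seed-major: a 13-sub-ROI seed × 9-sub-ROI
target yields 117 features.  The seed ROI is configurable, so control
analyses (e.g., a visual-cortex seed) need no special casing.

## Decoding

All decoders are scikit-learn SVMs with cost C = 1 and no hyperparameter
search.

* **Cross-subject connectivity decoding** — rows = subject × condition ×
  subsample (17 × 6 × 4 = 408), merged over subjects; 100 repeated
  class-stratified 75/25 row splits (306 train / 102 test), linear kernel.
  Features are z-scored with training-side statistics because C = 1 is
  scale-sensitive.  A subject-level split option (whole subjects held out)
  exists because the split unit is ambiguous at full scale; the row-level
  scheme is the default as it reproduces the printed 306/102 bookkeeping.
  Multiclass is one-vs-one voting, ties to the lowest class index.
* **Power-pattern decoding** — within-subject, RBF kernel with
  γ = 1/(H·σ²(X)) (sklearn `gamma="scale"`), leave-one-subsample-out
  4-fold CV: train 18 rows, test 6 per fold.
* **Temporal-PCA decoding** — 0.5–12 Hz band-pass (4th-order Butterworth,
  forward-backward), PCA to ≤ 100 components fit on training folds only,
  RBF SVM, stratified 10-fold CV.  PCs are *not* re-standardized: the
  γ rule sets the kernel scale, and inflating low-variance components to
  unit variance empirically buries the class structure.
* **Encoding→maintenance generalization** — per subject, fold q trains on
  the encoding rows of the other subsamples and tests on the maintenance
  rows of subsample q.
* **Behavioral SVR** — rows = subject × subsample (17 × 4 = 68); per fold
  the 51-row training block is standardized, PCA-reduced to 95 % explained
  variance, and fit with a linear SVR (ε = 0.1 × SD of the training
  targets; ε is unprinted, and 0.1·SD is the conventional default scale).
  RMSE is averaged over the 4 folds.  Subsample rows stand in for run-level
  rows, which the full-scale description leaves ambiguous.

## Inference

* **Label-permutation nulls** — training-side labels are shuffled
  (uniquely, seeded) and the decoder refit; test labels stay true.  The
  alternative reading (permuting all labels) was rejected because the
  described procedure generates the null "using the training data".  Null
  refits reuse a reduced number of the repeated splits (default 10 of the
  100; the calibration studies use 1) for tractability — fewer splits per
  permutation widen the null, which can only make the procedure more
  conservative.
* **Max-statistic correction** — pooled null = per-permutation maximum over
  the whole test family (e.g., 12 connections × 5 bands = 60);
  p = (1 + #{pooled ≥ observed}) / (1 + n_perm), which cannot reach zero.
  Monotonicity in the observed statistic and dominance over per-test
  p-values hold by construction and are asserted in tests.
* **Impulse LME** — accuracy rescaled by subtracting chance (1/6); fixed
  effects: impulse presence and log2 band center frequency; random subject
  intercept (statsmodels `MixedLM`, REML).  The model form is fixed (full
  main effects, no stepwise growth); t statistics use the residual
  degrees-of-freedom convention, Bonferroni-corrected across 13 tests.  On
  degenerate designs where the random-intercept variance collapses to the
  boundary the model reduces to OLS — the same limit as pinning the
  variance to zero.
* **SVR min-RMSE null** — behavior shuffled across subjects within each
  subsample; each permutation contributes the *minimum* RMSE over all
  connection × band × window tests; a connection/band is significant only
  if its observed RMSE beats the null's 2.5th percentile in **both** the
  early and the late window (two-tailed 0.05 rule).
* **Power-variation test** — one-sample t per band × window with sign-flip
  permutation (500 flips) and max-|t| pooling; the pipeline driver
  (`power_variation_analysis`) derives the subject × band × window relative
  power changes from a cohort's Morlet band power and feeds the test.  Note
  the discreteness floor: with n subjects only 2^n distinct sign flips
  exist, so the smallest attainable p is about 2/2^n.  This deliberately replaces
  threshold-free cluster enhancement: with a handful of discrete bands and
  no cortical geometry in scope, a discrete max-stat family is the
  appropriate analogue.  Zero-variance cells report p = 1 with a
  degenerate-input flag.

## Validation studies and problem sizes

The validation experiments (`syncdecode.experiments`) run at reduced size so
the full battery completes in minutes on one core:

| study | design | criterion |
|---|---|---|
| chance calibration | 20 null cohorts, 8 subjects, 2 sub-ROIs/ROI, 40 epochs/condition, 2 bands × 2 windows | pooled mean accuracy within 0.02 of 1/6 |
| max-stat FWER | 200 null replicates, 4 subjects, 1 connection × 2 bands × 2 windows (4 tests), 100 permutations, 1.2 s epochs | FWER ≤ 0.05 + 2 MC SEs |
| SVR rule FWER | 200 simulations, 8 subjects, 2 connections × 2 windows, 100 permutations, feature-independent behavior | ≤ 0.05 + 2 MC SEs |
| recovery | 50 replicates, 5 subjects, 32 epochs/condition, one planted coupling κ = 50, amplitude 3 | uniquely significant (pair, band) in ≥ 95 %; power decoding within 0.03 of 1/6 |
| impulse contrast | 100 replicates each for gain strength 0.8 and 0 (4 subjects, 32 epochs/condition) | detection ≥ 90 % planted, ≤ 7 % null |

The strong-recovery regime is documented as κ ≥ 50 with coupling amplitude
≥ 3 × the unit background: there the planted pair decodes at ~1.0 while
everything else sits at chance.  Short-epoch designs place both analysis
windows inside the valid wavelet region of the bands they use.

## What the synthetic studies do and do not show

The generator reproduces the *structure* of the real analysis problem —
epoch bookkeeping, sub-ROI layout, sign ambiguity, condition-blind power
with condition-specific phase coupling, impulse-gated power patterns,
behavior linked to coupling fidelity — and therefore validates the
*pipeline*: estimator correctness, chance-level calibration, FWER control,
and sensitivity to planted effects.  It does not emulate real MEG physics:
no forward/inverse modeling, no cortical geometry or field spread beyond a
single zero-lag common component, no trial-to-trial nonstationarity, no
artifacts, and stationary Gaussian sources.  Passing these studies says the
method is sound and calibrated, not that real cortex carries such couplings
— that is the empirical question the analysis is designed to ask.

## Known limitations

* Mean-reference sign alignment needs a shared component to anchor on; with
  fully independent sub-ROIs (no common signal) the generation signs are
  unidentifiable from data, and cross-subject pooled decoding of planted
  couplings degrades accordingly.
* The permutation nulls with 1 split per permutation are conservative;
  power near the significance threshold is reduced (irrelevant in the
  strong-recovery regime, documented for users who tune κ down).
* `MixedLM` on very small accuracy tables can hit the boundary of the
  random-effect space; the OLS fallback keeps the fixed-effect test
  well-defined but discards subject-level shrinkage there.
* The trial bookkeeping of the emulated study (runs × trials vs. reported
  epochs per condition) cannot be reconciled exactly; the generator
  honors the per-condition epoch counts.
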