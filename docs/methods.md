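# Methods

This note documents the models and procedures implemented in `eegconn`,
the parameter choices that matter, the design decisions taken where the
design was genuinely open, and the limits of what the synthetic tests
demonstrate.

## Preprocessing

The recording-to-epochs chain is: band-pass → resample → segment →
optional linear component removal → common average reference → channel
selection.

* **Filtering.** 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), i.e. zero-phase with ~8th-order magnitude roll-off.
  Zero phase is not cosmetic here: wPLI and PLI are phase statistics,
  and a causal filter's frequency-dependent group delay would bias them
  directly. The same filter family, at band edges, performs the
  per-band decomposition for the connectivity estimators. Defaults:
  1–45 Hz analysis band.
* **Resampling** (default target 200 Hz) uses polyphase anti-aliased
  decimation (`resample_poly`). Upsampling is refused — it cannot add
  information and would silently change epoch sample counts.
* **Epoching.** Consecutive non-overlapping epochs from the start of
  the recording, 10 s each, at most 10 per subject by default; a
  trailing remainder is dropped. Epoch placement is a convention; the
  start-anchored choice keeps reruns trivially reproducible.
* **Component removal** implements only the removal contract: given any
  invertible unmixing matrix (e.g. from an ICA computed elsewhere) and
  a reject list, the rejected sources are zeroed and the data
  reconstructed. Automatic artifact-component classification is out of
  scope: it requires labelled training data or heuristics that cannot
  be validated on synthetic recordings.
* **Average reference** subtracts the instantaneous channel mean — a
  linear projection, hence idempotent. Non-finite samples are an error
  at load time, never imputed.

The shipped 62-channel montage (61 standard 10-10 sites plus Iz) and
its 5-region / 8-region assignments are a documented best-effort
layout; both are overridable by a JSON scheme file, and channels not
assigned to any region are simply excluded from aggregation.

## wPLI / PLI

Eq.-level definitions: with analytic signals z₁, z₂ of the
band-filtered channels and X(t) = z₁(t)·conj(z₂(t)),

* PLI = |⟨sign Δφ(t)⟩| with Δφ wrapped to (−π, π] and sign(0) := 0;
* wPLI = |⟨Im X(t)⟩| / ⟨|Im X(t)|⟩.

Decisions:

* **Expectation over time.** The expectation is taken over time samples
  within an epoch; epoch-level values are then averaged across epochs.
  The analytic-signal route (rather than Welch segment averaging) is
  used because the amplitude/phase machinery above is defined exactly
  on it.
* **Edge trimming.** The discrete Hilbert transform is unreliable near
  epoch edges, so 5% of samples at *each* end are excluded from the
  expectation (10% of the epoch in total).
* **Degenerate pairs.** When the imaginary cross-spectrum is
  identically zero — identical signals, or purely zero-lag mixtures —
  the wPLI ratio is 0/0. The implementation reports 0 with a
  `DegenerateCaseWarning`. Numerically, "zero" means the mean |Im X| is
  below 1e-10 of the mean |X|: beyond that the imaginary part is
  floating-point noise and the ratio would be meaningless.
* **Null bias.** A single-window wPLI estimate is non-negative and has
  a positive finite-sample bias of order 1/√n_eff, where n_eff is set
  by the band's width, not the sample count: narrow bands decorrelate
  slowly. For this reason the zero-lag robustness checks evaluate wPLI
  on the full 1–45 Hz analysis band (n = 20000 → bound 0.1 holds with
  large margin), while narrowband group analyses rely on averaging over
  epochs and channel pairs, where the bias is common to both groups and
  cancels in the contrast.

Aggregation: within-region values are means over unordered channel
pairs inside a region (regions need ≥ 2 assigned channels);
transhemispheric values are means over all cross-region channel pairs
of a homologous pair.

## MVAR / DTF

The effective-connectivity stage fits one VAR(p) per 10 s epoch on the
8 hemisphere-region-averaged signals by ordinary least squares on the
lagged design matrix, with the residual covariance taken from the fit
residuals.

* **Region averaging first.** A 62-variate VAR on 2000 samples is not
  estimable (even p = 1 would need ~62² coefficients per lag);
  averaging each lateralized region's channels first yields an
  8-variate model that is comfortably identified (the fit requires
  ≥ 10·p·k post-lag rows) and directly targets the transhemispheric
  question. An averaged region signal also has a better SNR than any
  single channel. Channel-level DTF remains available through the same
  functions for sensitivity analyses.
* **Order selection** by SBC over 1..20 (AIC selectable), all candidate
  orders scored on a common sample range; a fixed order can be supplied
  for reproducibility and is used in the packaged simulation studies.
* **Spectral factorization.** Ā(f) = I − Σᵢ A(i) e^(−j2πf·i·Δt) and
  H(f) = Ā(f)⁻¹. The identity term is required for H to be the
  transfer function of the fitted VAR (the innovations enter the
  process with unit gain); omitting it would make H the inverse of the
  lag polynomial alone, which is not a transfer function of any
  stationary model.
* **DTF** is reported as the positive square root of the inflow ratio,
  so for every sink and frequency the squared values over sources sum
  to 1 (machine-verified to 1e-10). DTF measures total (direct plus
  mediated) directed influence: on a chain 0→1→2 the 0→2 entry is
  genuinely nonzero; only never-present reverse/skip-reverse edges are
  expected at null level.
* **Frequency grid** 1..30 Hz, step 1 Hz. Band averages are inclusive
  at both edges, so the boundary frequencies 4, 8 and 13 Hz contribute
  to both adjacent bands — a deliberate, documented overlap matching
  the band definitions as printed.

## Surrogate significance

Per channel, the Fourier phases of all non-DC, non-Nyquist bins are
replaced by i.i.d. uniform draws (the Nyquist bin of an even-length
epoch gets a random sign); the amplitude spectrum is preserved
bin-exactly, cross-channel phase relations are destroyed. The test
statistic — by default the full fit-then-DTF pipeline, band-averaged —
is recomputed on each of 100 surrogates, fresh draws per epoch; the
5th-largest surrogate value per connection is the α = 0.05 threshold,
and a real value is significant when *strictly greater*. Significant
values are averaged across epochs; a connection with no significant
epoch reports 0 with an all-censored flag.

Decisions: thresholding operates on the band-averaged statistic by
default; the threshold machinery is generic over the statistic
contract, so a per-frequency-bin statistic (the unaveraged DTF
spectrum) can be thresholded through the same function. Refitting the MVAR on every
surrogate (rather than reusing the original fit) makes the null
distribution reflect the entire estimation chain. Under the null the
data epoch is exchangeable with its surrogates, so the procedure's
type-I rate is ⌈α·n⌉/(n+1) ≈ 0.0495 by construction; the white-noise
calibration study measures ≈ 0.04, inside the [0.02, 0.10] acceptance
band.

One structural caveat: phase randomization cannot destroy the phase
locking of a *pure line spectrum* (a single-bin signal keeps a
constant, random relative phase in every surrogate). The procedure is
calibrated for broadband signals — which EEG and the MVAR-based
statistic are — and the test suite exercises exactly that regime.

## Group statistics

Independent two-sample t-tests (pooled-variance Student by default,
Welch as an option) per (band × cell), with Benjamini–Hochberg step-up
FDR across the family — all cells of one estimator at one aggregation
level, e.g. the 20 cells of 4 bands × 5 regions for within-region wPLI.
Significance is judged on adjusted p < 0.05. Degenerate inputs with
zero variance in both groups return t = 0, p = 1 when means agree and
are an error otherwise. The 2×2 Pearson χ² for demographic tables is
uncorrected by default (Yates optional).

A paired test is not applicable to two independent cohorts of unequal
size; the independent-samples test is the only coherent reading and is
what the module implements.

## Synthetic data generator

The generator provides exactly the statistical structure the
estimators are defined on, per subject:

1. a stable MVAR background built from a coupling graph (edge = source,
   sink, lag ≥ 1, weight placed in A(lag); diagonal self-decay 0.5 on
   A(1)); coefficients exceeding the target companion spectral radius
   (default 0.95) are uniformly shrunk by bisection; 10·p burn-in
   samples are discarded;
2. optionally, a shared narrowband oscillation planted into one
   region's channels at distinct phase offsets (default 6 Hz in the
   theta band, offsets 0/0.8/1.6/2.4 rad), so every within-region pair
   has a genuine, detectable phase lag; the amplitude may differ by
   group (defaults: 0.25 vs 0.50 against unit-SD innovations, with
   ±10% per-subject jitter), which is the planted group difference;
3. an instantaneous mixing matrix I + 0.05·U(−1,1) emulating volume
   conduction — it must *not* create wPLI, and the estimator checks
   confirm it does not.

Default study conditions: 200 Hz sampling, 10 s epochs, 10 epochs and
20 subjects per group, Gaussian i.i.d. innovations with diagonal
covariance. Per-subject RNG streams derive from the master seed via
`SeedSequence(master, spawn_key=(group_index, subject_index))` — a
counter-based rule that is stable across runs and platforms and makes
subjects mutually independent.

The packaged studies run on a compact 20-channel montage (4 channels
per region of the 5-region scheme, with a matching 8-region scheme);
this is the package's own problem-size choice for simulation studies
and changes nothing methodological relative to the full 62-channel
layout. The amplitudes above give the planted theta × F cell a group
contrast around t ≈ −30 at 20 subjects/group — comfortably, but not
trivially, detectable (other cells' null t values reach ±2.5).

What the generator does **not** emulate: 1/f background spectra,
artifacts (blinks, EMG), nonstationarity, realistic head-model mixing,
or between-subject anatomical variability. Passing tests therefore
demonstrate estimator and pipeline correctness on data with known
ground truth — not clinical validity on real recordings.

## Numerical conventions

* Phase wrapping to (−π, π]; sign(0) contributes 0 to PLI.
* wPLI degenerate-denominator convention: 0 with a warning (relative
  tolerance 1e-10 against the mean cross-spectrum magnitude).
* Connectivity matrices are symmetric with a zero diagonal.
* DTF normalization is exact to accumulation tolerance (1e-10 checked).
* Surrogate count must satisfy n ≥ ⌈1/α⌉; the threshold rank is
  ⌈α·n⌉.
* All stochastic components accept either an integer seed or a NumPy
  `Generator`; identical seeds give bit-identical outputs, including
  byte-identical pipeline CSVs.

## Known limitations

* Electrode-space analysis only; no source localization, so region
  labels mean "electrode neighbourhoods", not cortical structures.
* DTF does not separate direct from mediated influence (no partial
  directed coherence or dDTF variants).
* The ICA step is a removal contract, not a decomposition; users supply
  the unmixing matrix and reject list.
* EDF is read (via MNE) but not written; generated studies are stored
  as delimited matrices with JSON sidecars.
* The surrogate procedure assumes broadband signals (see above) and
  quasi-stationary epochs.
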