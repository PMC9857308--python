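# eegconn

Resting-state EEG connectivity analysis for group studies: **functional
connectivity** via the weighted phase lag index (wPLI) and **effective
(directed) connectivity** via the directed transfer function (DTF), with
phase-randomization surrogate significance testing and FDR-corrected
group comparison. A synthetic-data generator with planted coupling
ground truth makes every stage of the pipeline verifiable end-to-end.

The package is aimed at researchers comparing two cohorts of
multichannel resting-state EEG (e.g. a clinical group against typically
developing controls) who need phase-based connectivity measures that
are robust to volume conduction, together with a defensible
significance procedure.

## Methods in brief

**wPLI.** For two band-limited channels with analytic signals
z₁(t), z₂(t) (Hilbert transform), the time-resolved cross-spectrum is
X(t) = z₁(t)·conj(z₂(t)) and

    wPLI = |E{Im X}| / E{|Im X|} ∈ [0, 1]

Each sample's phase-lag sign is weighted by the magnitude of the
imaginary cross-spectrum, so purely instantaneous (volume-conducted)
mixing — which has a real cross-spectrum — contributes nothing. The
unweighted PLI = |E{sign Δφ(t)}| is also provided. Channel-pair values
are averaged over epochs and aggregated over a 5-region scheme
(F, LT, P, RT, O; within-region pairs) or an 8-region transhemispheric
scheme (LF/RF, LT/RT, LP/RP, LO/RO; cross-hemisphere pairs) in the four
canonical bands (delta 1–4, theta 4–8, alpha 8–13, beta 13–30 Hz).

**DTF.** Hemisphere-region-averaged signals are modelled per epoch by a
vector autoregression X(t) = Σᵢ A(i) X(t−i) + ε(t) (OLS fit, order by
SBC). With Ā(f) = I − Σᵢ A(i) e^(−j2πf·i·Δt) and transfer matrix
H(f) = Ā(f)⁻¹,

    DTF²(j→i, f) = |H_ij(f)|² / Σₘ |H_im(f)|²

the normalized inflow from region j into region i, evaluated on a
1–30 Hz grid (1 Hz step) and band-averaged. Significance per epoch,
band and connection is assessed against 100 phase-randomized surrogates
(amplitude spectra preserved bin-exactly, the full fit-then-DTF
statistic recomputed per surrogate, 5th-largest value as the α = 0.05
threshold); significant values are averaged across epochs.

**Group statistics.** One independent two-sample t-test per
(band × region or region-pair) cell with Benjamini–Hochberg FDR across
the family, significance at adjusted p < 0.05.

**Synthetic data.** Stable MVAR processes carry directed lagged
coupling ground truth; a phase-staggered narrowband oscillation planted
into one region provides wPLI ground truth and a controllable group
difference; an instantaneous mixing matrix emulates volume conduction.
A master seed determines the whole study bit-exactly.

## Worked example

```python
import numpy as np
from eegconn import simulate_phase_locked_pair, wpli_pair
from eegconn.containers import FrequencyBand
from eegconn.studies import wpli_group_study

# a 10 Hz pair locked at a quarter-cycle lag, in heavy noise
rec = simulate_phase_locked_pair(freq=10.0, phase_lag=np.pi/2, noise_sd=1.0,
                                 n_samples=20000, sampling_rate=200.0, seed=0)
wide = FrequencyBand("wide", 1.0, 45.0)
w = wpli_pair(rec.data[:, 0], rec.data[:, 1], wide, 200.0)
print(f"wPLI of the noisy quarter-cycle pair: {w:.3f}")

# a two-group study with elevated theta coupling planted in region F of group B
table = wpli_group_study(seed=0, effect=0.25, n_subjects_per_group=8, n_epochs=5)
print(table.head(4).round(4).to_string(index=False))
```

Output:

```
wPLI of the noisy quarter-cycle pair: 0.886
 band cell  mean_A  mean_B        t      p  p_adjusted  significant
theta    F  0.2796  0.6632 -20.8767 0.0000      0.0000         True
delta    P  0.1826  0.2080  -2.1875 0.0462      0.4617        False
theta    P  0.1800  0.2050  -1.7903 0.0950      0.6336        False
alpha    O  0.1746  0.1632   1.1898 0.2539      0.7960        False
```

The pair's wPLI of 0.886 reflects the genuine quarter-cycle lag
surviving unit-variance additive noise (it would be ≈ 1 noise-free and
≈ 0 for zero-lag mixing). In the group table, the planted cell —
theta band, frontal region — is the only cell surviving FDR correction:
group B's mean within-region theta wPLI (0.66) clearly exceeds group
A's (0.28), while all other band × region cells behave like null cells.

The same analysis is available from the shell:

```sh
eegconn simulate --out study/ --seed 1 --subjects 20 --epochs 10
eegconn run study/ --out results/
```

and as scikit-learn transformers (`EEGPreprocessor`, `WPLIConnectivity`,
`DTFConnectivity`) that compose with sklearn pipelines and model
selection.

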