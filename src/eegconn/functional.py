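"""Phase-based functional connectivity: PLI and weighted PLI.

Both estimators are built on the discrete analytic signal.  For two
band-limited channels with analytic signals z1(t), z2(t), the
time-resolved cross-spectrum is X(t) = z1(t) · conj(z2(t)), whose
argument is the instantaneous phase difference Δφ(t) and whose
imaginary part carries the lagged (non-volume-conducted) interaction:

* PLI  = |⟨sign Δφ(t)⟩|
* wPLI = |⟨Im X(t)⟩| / ⟨|Im X(t)|⟩

wPLI weights each sample's phase-lag sign by the magnitude of the
imaginary cross-spectrum, which suppresses the contribution of
near-zero-lag samples and makes the estimator insensitive to
instantaneous (volume-conducted) mixing.  Both statistics live in
[0, 1].  A pair with identically zero imaginary cross-spectrum (e.g.
identical or purely zero-lag-mixed signals) has an undefined wPLI ratio
and is reported as 0 with a :class:`DegenerateCaseWarning`.

The expectation is taken over time samples within an epoch, after
discarding a 5% margin at each epoch edge (Hilbert transform edge
artifacts); epoch-level values are then averaged across epochs.
"""

from __future__ import annotations

import warnings
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.signal import hilbert

from .containers import (
    CANONICAL_BANDS,
    AnalyticSignal,
    ConnectivityResult,
    DegenerateCaseWarning,
    EpochedRecording,
    FrequencyBand,
)
from .montage import RegionScheme
from .preprocessing import butter_bandpass_sos
from scipy.signal import sosfiltfilt

__all__ = [
    "analytic_signal",
    "pli",
    "wpli_from_imag",
    "wpli_pair",
    "pli_pair",
    "band_connectivity_matrix",
    "aggregate_within_region",
    "aggregate_cross_region",
    "EDGE_FRACTION",
]

#: Fraction of samples discarded at *each* end of an epoch before the
#: time expectation, to avoid Hilbert-transform edge artifacts.
EDGE_FRACTION = 0.05

#: A pair is degenerate (wPLI = 0 by convention) when the mean |Im X| is
#: below this fraction of the mean |X|: the imaginary cross-spectrum is
#: then numerical noise, as for identical or purely zero-lag signals.
_IMAG_REL_TOL = 1e-10


def analytic_signal(x: np.ndarray) -> AnalyticSignal:
    """Discrete analytic signal of one channel via the frequency domain.

    Returns instantaneous amplitude A(t) ≥ 0 and phase φ(t) ∈ (−π, π].
    A constant input has no defined phase and is flagged degenerate
    (amplitude and phase returned as zeros).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("analytic_signal expects a single channel (1-D)")
    if x.size < 16:
        raise ValueError("input too short (< 16 samples) for a stable analytic signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in input")
    if np.ptp(x) == 0.0:
        warnings.warn("constant input: instantaneous phase undefined",
                      DegenerateCaseWarning, stacklevel=2)
        return AnalyticSignal(np.zeros_like(x), np.zeros_like(x), degenerate=True)
    z = hilbert(x)
    return AnalyticSignal(np.abs(z), np.angle(z), degenerate=False)


def _wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences to (−π, π]."""
    wrapped = np.mod(dphi + np.pi, 2.0 * np.pi) - np.pi
    # np.mod maps exact multiples of 2π to −π; move them to +π
    wrapped[wrapped == -np.pi] = np.pi
    return wrapped


def pli(delta_phi: np.ndarray) -> float:
    """Phase lag index: |mean sign of the wrapped phase difference|.

    sign(0) contributes 0.  Result in [0, 1].
    """
    delta_phi = np.asarray(delta_phi, dtype=np.float64)
    if delta_phi.size == 0:
        raise ValueError("empty phase-difference series")
    return float(np.abs(np.mean(np.sign(_wrap_phase(delta_phi)))))


def wpli_from_imag(imag_x: np.ndarray) -> float:
    """Weighted PLI from a series of imaginary cross-spectrum samples.

    wPLI = |E{Im X}| / E{|Im X|}; returns 0 (flagged) when the
    denominator vanishes.
    """
    imag_x = np.asarray(imag_x, dtype=np.float64)
    if imag_x.size == 0:
        raise ValueError("empty imaginary cross-spectrum series")
    denom = np.mean(np.abs(imag_x))
    if denom == 0.0:
        warnings.warn("identically zero imaginary cross-spectrum; wPLI set to 0",
                      DegenerateCaseWarning, stacklevel=2)
        return 0.0
    return float(np.abs(np.mean(imag_x)) / denom)


def _edge_slice(n: int, edge_fraction: float) -> slice:
    margin = int(np.floor(n * edge_fraction))
    return slice(margin, n - margin if margin else n)


def _band_analytic(data: np.ndarray, band: FrequencyBand,
                   sampling_rate: float) -> np.ndarray:
    """Band-pass (zero phase) then analytic signal, channel-wise.

    ``data`` is (n_samples, n_channels); returns complex array of the
    same shape.
    """
    sos = butter_bandpass_sos(band.low, band.high, sampling_rate)
    filtered = sosfiltfilt(sos, data, axis=0)
    return hilbert(np.ascontiguousarray(filtered), axis=0)


def wpli_pair(x1: np.ndarray, x2: np.ndarray, band: FrequencyBand,
              sampling_rate: float, edge_fraction: float = EDGE_FRACTION) -> float:
    """wPLI between two channels of one epoch in a frequency band.

    Both channels are band-passed, converted to analytic signals, and
    the time expectation is taken over the epoch interior.
    Symmetric in its arguments.
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("wpli_pair expects two equal-length 1-D channels")
    z = _band_analytic(np.column_stack([x1, x2]), band, sampling_rate)
    sl = _edge_slice(x1.size, edge_fraction)
    cross = z[sl, 0] * np.conj(z[sl, 1])
    if np.mean(np.abs(cross.imag)) <= _IMAG_REL_TOL * np.mean(np.abs(cross)):
        warnings.warn("imaginary cross-spectrum at numerical-noise level "
                      "(identical or zero-lag signals); wPLI set to 0",
                      DegenerateCaseWarning, stacklevel=2)
        return 0.0
    return wpli_from_imag(cross.imag)


def pli_pair(x1: np.ndarray, x2: np.ndarray, band: FrequencyBand,
             sampling_rate: float, edge_fraction: float = EDGE_FRACTION) -> float:
    """PLI between two channels of one epoch in a frequency band."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("pli_pair expects two equal-length 1-D channels")
    z = _band_analytic(np.column_stack([x1, x2]), band, sampling_rate)
    sl = _edge_slice(x1.size, edge_fraction)
    dphi = np.angle(z[sl, 0]) - np.angle(z[sl, 1])
    return pli(dphi)


def band_connectivity_matrix(epochs: EpochedRecording, band: FrequencyBand,
                             estimator: Literal["wpli", "pli"] = "wpli",
                             edge_fraction: float = EDGE_FRACTION) -> ConnectivityResult:
    """Channel-pair connectivity matrix in one band, averaged over epochs.

    For each epoch a symmetric matrix is computed over all channel
    pairs; matrices are then averaged across epochs and the diagonal is
    set to 0.
    """
    if estimator not in ("wpli", "pli"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if epochs.n_channels < 2:
        raise ValueError("connectivity matrix requires at least 2 channels")
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    k = epochs.n_channels
    acc = np.zeros((k, k))
    sl = _edge_slice(epochs.n_samples, edge_fraction)
    with warnings.catch_warnings():
        # degenerate pairs (zero imaginary cross-spectrum) resolve to 0 by
        # convention inside the matrix; no need to warn per pair
        warnings.simplefilter("ignore", DegenerateCaseWarning)
        for e in range(epochs.n_epochs):
            z = _band_analytic(epochs.epochs[e], band, epochs.sampling_rate)[sl]
            mat = np.zeros((k, k))
            for i in range(k - 1):
                cross = z[:, i, None] * np.conj(z[:, i + 1:])
                if estimator == "wpli":
                    num = np.abs(cross.imag.mean(axis=0))
                    den = np.abs(cross.imag).mean(axis=0)
                    floor = _IMAG_REL_TOL * np.abs(cross).mean(axis=0)
                    vals = np.divide(num, den, out=np.zeros_like(num),
                                     where=den > floor)
                else:
                    dphi = _wrap_phase(np.angle(cross))
                    vals = np.abs(np.sign(dphi).mean(axis=0))
                mat[i, i + 1:] = vals
                mat[i + 1:, i] = vals
            acc += mat
    acc /= epochs.n_epochs
    np.fill_diagonal(acc, 0.0)
    return ConnectivityResult(estimator=estimator, band=band.name,
                              level="channel-pair", labels=epochs.channel_labels,
                              values=acc)


def _matrix_index(result: ConnectivityResult) -> dict[str, int]:
    if result.level != "channel-pair":
        raise ValueError("aggregation expects a channel-pair level result")
    return {lab: i for i, lab in enumerate(result.labels)}


def aggregate_within_region(result: ConnectivityResult,
                            scheme: RegionScheme) -> ConnectivityResult:
    """Mean connectivity over all unordered channel pairs inside each region."""
    index = _matrix_index(result)
    missing = [ch for ch in scheme.channels if ch not in index]
    if missing:
        raise KeyError(f"scheme channels absent from matrix: {missing}")
    values = []
    for region in scheme.region_labels:
        chans = scheme.channels_of(region)
        if len(chans) < 2:
            raise ValueError(
                f"region {region!r} has {len(chans)} channel(s); within-region "
                "aggregation needs at least 2"
            )
        idx = [index[c] for c in chans]
        sub = result.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        values.append(float(sub[iu].mean()))
    return ConnectivityResult(estimator=result.estimator, band=result.band,
                              level="within-region", labels=scheme.region_labels,
                              values=np.array(values), subject=result.subject)


def aggregate_cross_region(result: ConnectivityResult, scheme: RegionScheme,
                           pair: tuple[str, str]) -> float:
    """Mean connectivity over all channel pairs spanning two disjoint regions."""
    index = _matrix_index(result)
    a, b = pair
    chans_a, chans_b = scheme.channels_of(a), scheme.channels_of(b)
    overlap = set(chans_a) & set(chans_b)
    if overlap:
        raise ValueError(f"regions {a!r} and {b!r} overlap on {sorted(overlap)}")
    missing = [ch for ch in (*chans_a, *chans_b) if ch not in index]
    if missing:
        raise KeyError(f"scheme channels absent from matrix: {missing}")
    ia = [index[c] for c in chans_a]
    ib = [index[c] for c in chans_b]
    return float(result.values[np.ix_(ia, ib)].mean())


def transhemispheric_connectivity(epochs: EpochedRecording, scheme: RegionScheme,
                                  bands: Sequence[FrequencyBand] = CANONICAL_BANDS,
                                  estimator: Literal["wpli", "pli"] = "wpli",
                                  ) -> list[ConnectivityResult]:
    """wPLI between each homologous region pair, one result per band."""
    if not scheme.pairs:
        raise ValueError(f"scheme {scheme.name!r} declares no cross-hemisphere pairs")
    out = []
    for band in bands:
        matrix = band_connectivity_matrix(epochs, band, estimator=estimator)
        labels = tuple(f"{a}-{b}" for a, b in scheme.pairs)
        vals = np.array([aggregate_cross_region(matrix, scheme, p) for p in scheme.pairs])
        out.append(ConnectivityResult(estimator=estimator, band=band.name,
                                      level="region-pair", labels=labels, values=vals))
    return out


def within_region_connectivity(epochs: EpochedRecording, scheme: RegionScheme,
                               bands: Sequence[FrequencyBand] = CANONICAL_BANDS,
                               estimator: Literal["wpli", "pli"] = "wpli",
                               ) -> list[ConnectivityResult]:
    """Within-region connectivity for each band of ``bands``."""
    return [aggregate_within_region(band_connectivity_matrix(epochs, band,
                                                             estimator=estimator), scheme)
            for band in bands]
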