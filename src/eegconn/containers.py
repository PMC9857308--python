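"""In-memory containers shared across the pipeline.

All signal data is stored as ``float64`` arrays in samples-first layout:
``(n_samples, n_channels)`` for continuous recordings and
``(n_epochs, n_samples, n_channels)`` for epoched data.  Values are in
microvolts for real EEG; the synthetic generator uses arbitrary signal
units (nothing downstream depends on the physical unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "DegenerateCaseWarning",
    "MultichannelRecording",
    "EpochedRecording",
    "AnalyticSignal",
    "FrequencyBand",
    "CANONICAL_BANDS",
    "MVARModel",
    "TransferMatrix",
    "DTFSpectrum",
    "SurrogateDistribution",
    "ConnectivityResult",
]


class DegenerateCaseWarning(UserWarning):
    """Raised for well-defined conventions on degenerate inputs.

    Examples: wPLI of a zero-lag pair (identically zero imaginary
    cross-spectrum, reported as 0), analytic signal of a constant, or a
    connection whose DTF never exceeds its surrogate threshold in any
    epoch (reported as 0).
    """


def _check_labels(labels: Sequence[str], n_channels: int) -> tuple[str, ...]:
    labels = tuple(str(c) for c in labels)
    if len(labels) != n_channels:
        raise ValueError(
            f"{len(labels)} channel labels for {n_channels} data columns"
        )
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dupes = sorted({lab for lab in labels if lab in seen or seen.add(lab)})
        raise ValueError(f"channel labels are not unique: {dupes}")
    return labels


@dataclass
class MultichannelRecording:
    """A continuous multichannel recording.

    Parameters
    ----------
    data : ndarray of shape (n_samples, n_channels)
        Signal values; must be finite.
    sampling_rate : float
        Sampling rate in Hz, > 0.
    channel_labels : sequence of str
        Unique channel names (10-10 convention for real EEG).
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_samples, n_channels)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        self.sampling_rate = float(self.sampling_rate)
        self.channel_labels = _check_labels(self.channel_labels, self.data.shape[1])

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.sampling_rate

    def with_data(self, data: np.ndarray, sampling_rate: float | None = None,
                  channel_labels: Sequence[str] | None = None) -> "MultichannelRecording":
        return MultichannelRecording(
            data=data,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            channel_labels=self.channel_labels if channel_labels is None else tuple(channel_labels),
        )


@dataclass
class EpochedRecording:
    """Fixed-length epochs cut from a recording; the unit all estimators consume."""

    epochs: np.ndarray  # (n_epochs, n_samples, n_channels)
    sampling_rate: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, n_samples, n_channels)")
        if not np.all(np.isfinite(self.epochs)):
            raise ValueError("epochs contain non-finite samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        self.sampling_rate = float(self.sampling_rate)
        self.channel_labels = _check_labels(self.channel_labels, self.epochs.shape[2])

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[2]

    @property
    def epoch_length(self) -> float:
        """Epoch length in seconds (n_samples / sampling_rate, exact)."""
        return self.n_samples / self.sampling_rate

    def with_epochs(self, epochs: np.ndarray,
                    channel_labels: Sequence[str] | None = None) -> "EpochedRecording":
        return EpochedRecording(
            epochs=epochs,
            sampling_rate=self.sampling_rate,
            channel_labels=self.channel_labels if channel_labels is None else tuple(channel_labels),
        )


@dataclass
class AnalyticSignal:
    """Instantaneous amplitude and phase of a single channel.

    ``amplitude`` is ≥ 0 and ``phase`` lies in (−π, π].  ``degenerate``
    is set when the input was constant (phase undefined).
    """

    amplitude: np.ndarray
    phase: np.ndarray
    degenerate: bool = False


class FrequencyBand(NamedTuple):
    """A named frequency band [low, high] in Hz (0 < low < high)."""

    name: str
    low: float
    high: float


#: The four canonical EEG bands used throughout: delta 1–4, theta 4–8,
#: alpha 8–13, beta 13–30 Hz.  Boundary frequencies belong to both the
#: lower band's upper edge and the upper band's lower edge (inclusive).
CANONICAL_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("delta", 1.0, 4.0),
    FrequencyBand("theta", 4.0, 8.0),
    FrequencyBand("alpha", 8.0, 13.0),
    FrequencyBand("beta", 13.0, 30.0),
)


def band_by_name(name: str) -> FrequencyBand:
    for band in CANONICAL_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown canonical band {name!r}")


@dataclass
class MVARModel:
    """A fitted (or constructed) multivariate autoregressive model.

    The process is X(t) = sum_{i=1..p} A(i) X(t-i) + eps(t) with
    ``coefficients[i-1]`` holding A(i) and ``residual_cov`` the
    covariance of the innovations eps(t).
    """

    order: int
    coefficients: np.ndarray  # (p, k, k)
    residual_cov: np.ndarray  # (k, k)
    sampling_rate: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.ndim != 3 or self.coefficients.shape[0] != self.order:
            raise ValueError("coefficients must have shape (order, k, k)")
        k = self.coefficients.shape[1]
        if self.coefficients.shape[2] != k:
            raise ValueError("coefficient matrices must be square")
        self.residual_cov = np.asarray(self.residual_cov, dtype=np.float64)
        if self.residual_cov.shape != (k, k):
            raise ValueError("residual covariance shape mismatch")

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[1]

    def companion(self) -> np.ndarray:
        """Companion matrix of the VAR(p) process, shape (p·k, p·k)."""
        p, k = self.order, self.n_channels
        comp = np.zeros((p * k, p * k))
        comp[:k, :] = np.concatenate(list(self.coefficients), axis=1)
        if p > 1:
            comp[k:, :-k] = np.eye((p - 1) * k)
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self, tol: float = 0.0) -> bool:
        return self.spectral_radius() < 1.0 - tol


@dataclass
class TransferMatrix:
    """MVAR transfer matrix H(f) on a frequency grid."""

    freqs: np.ndarray  # (n_freqs,) Hz
    values: np.ndarray  # (n_freqs, k, k) complex; values[f, i, j] = H_ij(f)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 3 or self.values.shape[0] != self.freqs.shape[0]:
            raise ValueError("values must have shape (n_freqs, k, k)")


@dataclass
class DTFSpectrum:
    """Normalized directed transfer function on a frequency grid.

    ``values[f, i, j]`` is DTF(j→i, f): the positive square root of the
    inflow ratio from source j into sink i, so each row satisfies
    sum_j values[f, i, j]**2 == 1.
    """

    freqs: np.ndarray
    values: np.ndarray  # (n_freqs, k, k) in [0, 1]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[0] != self.freqs.shape[0]:
            raise ValueError("values must have shape (n_freqs, k, k)")


@dataclass
class SurrogateDistribution:
    """Null distribution of a statistic over phase-randomized surrogates.

    ``values`` holds the statistic per surrogate, sorted descending along
    axis 0; ``threshold`` is the rank-⌈α·n⌉ largest value (the 5th of 100
    at α = 0.05).
    """

    statistic_name: str
    values: np.ndarray  # (n_surrogates, *stat_shape), sorted descending
    threshold: np.ndarray  # (*stat_shape,)
    alpha: float
    rank: int

    @property
    def n_surrogates(self) -> int:
        return self.values.shape[0]


@dataclass
class ConnectivityResult:
    """Per-subject scalar connectivity values at one aggregation level.

    ``level`` is one of ``"channel-pair"`` (square matrix),
    ``"within-region"`` (one value per region) or ``"region-pair"``
    (one value per directed or undirected region pair).
    """

    estimator: str
    band: str
    level: str
    labels: tuple[str, ...]
    values: np.ndarray
    subject: str | None = None
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = tuple(self.labels)
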