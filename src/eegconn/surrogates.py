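"""Phase-randomization surrogates and empirical significance thresholds.

Each surrogate preserves every channel's amplitude spectrum bin-exactly
(hence its power spectrum and autocorrelation) while replacing the
Fourier phases of all non-DC, non-Nyquist bins with i.i.d. uniform
draws, independently per channel.  Cross-channel phase relations are
destroyed, so any directed or phase-lagged statistic computed on a
surrogate is a draw from its null distribution.

The default procedure draws 100 surrogates per epoch, evaluates the
statistic (the full fit-then-DTF pipeline by default) on each, sorts the
values from largest to smallest per connection, and takes the 5th
largest as the α = 0.05 threshold.  A real value strictly greater than
its threshold is declared significant; significant values are averaged
across epochs, and a connection with no significant value in any epoch
is reported as 0 with an all-censored flag.
"""

from __future__ import annotations

import math
import warnings
from typing import Callable

import numpy as np

from .containers import DegenerateCaseWarning, SurrogateDistribution

__all__ = [
    "phase_randomize",
    "surrogate_threshold",
    "apply_threshold_and_aggregate",
]


def phase_randomize(epoch: np.ndarray, rng: np.random.Generator | int) -> np.ndarray:
    """Phase-randomized surrogate of a real multichannel epoch.

    Parameters
    ----------
    epoch : ndarray of shape (n_samples,) or (n_samples, n_channels)
    rng : numpy Generator or int seed

    Returns
    -------
    ndarray of the same shape with identical per-channel amplitude
    spectra and independently randomized phases.
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(epoch, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("epoch must be 1-D or 2-D (n_samples, n_channels)")
    n = x.shape[0]
    spec = np.fft.rfft(x, axis=0)
    n_bins = spec.shape[0]
    has_nyquist = n % 2 == 0
    # interior bins get uniform phases; DC stays put; the Nyquist bin (even
    # n) must stay real, so it only gets a random sign
    hi = n_bins - 1 if has_nyquist else n_bins
    phases = rng.uniform(-np.pi, np.pi, size=(hi - 1, x.shape[1]))
    out = spec.copy()
    out[1:hi] = np.abs(spec[1:hi]) * np.exp(1j * phases)
    if has_nyquist:
        out[-1] = np.abs(spec[-1]) * rng.choice([-1.0, 1.0], size=x.shape[1])
    surrogate = np.fft.irfft(out, n=n, axis=0)
    return surrogate[:, 0] if squeeze else surrogate


def surrogate_threshold(epoch: np.ndarray,
                        statistic: Callable[[np.ndarray], np.ndarray],
                        n_surrogates: int = 100, alpha: float = 0.05,
                        seed: int | np.random.Generator | None = None,
                        statistic_name: str = "statistic",
                        ) -> SurrogateDistribution:
    """Empirical null threshold of ``statistic`` under phase randomization.

    ``statistic`` maps an epoch array to a (possibly multi-dimensional)
    array of connection statistics; it is evaluated on ``n_surrogates``
    independent surrogates and the rank-⌈α·n⌉ largest value per
    connection is the threshold (the 5th largest of 100 at α = 0.05).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_surrogates < math.ceil(1.0 / alpha):
        raise ValueError(
            f"n_surrogates={n_surrogates} too small for alpha={alpha}; "
            f"need >= {math.ceil(1.0 / alpha)}"
        )
    rng = np.random.default_rng(seed)
    values = None
    for s in range(n_surrogates):
        stat = np.asarray(statistic(phase_randomize(epoch, rng)), dtype=np.float64)
        if not np.all(np.isfinite(stat)):
            raise ValueError(f"statistic returned non-finite values on surrogate {s}")
        if values is None:
            values = np.empty((n_surrogates, *stat.shape))
        values[s] = stat
    values = np.sort(values, axis=0)[::-1]  # descending
    rank = math.ceil(alpha * n_surrogates)  # 5 for 100 @ 0.05
    return SurrogateDistribution(statistic_name=statistic_name, values=values,
                                 threshold=values[rank - 1], alpha=alpha, rank=rank)


def apply_threshold_and_aggregate(values: np.ndarray, thresholds: np.ndarray,
                                  axis: int = 0, warn: bool = False,
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Mask non-significant values and average the significant ones.

    Parameters
    ----------
    values, thresholds : ndarray
        Matching shapes (e.g. epoch × band × sink × source); a value is
        significant when *strictly greater* than its threshold.
    axis : int
        Axis to average over (the epoch axis).

    Returns
    -------
    aggregated : ndarray
        Mean of the significant values along ``axis``; 0 where no value
        was significant.
    all_censored : ndarray of bool
        True where every value along ``axis`` fell at or below its
        threshold (the reported 0 is a convention, not an estimate).
    """
    values = np.asarray(values, dtype=np.float64)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if values.shape != thresholds.shape:
        raise ValueError(
            f"shape mismatch: values {values.shape} vs thresholds {thresholds.shape}"
        )
    mask = values > thresholds
    count = mask.sum(axis=axis)
    total = np.where(mask, values, 0.0).sum(axis=axis)
    aggregated = np.divide(total, count, out=np.zeros_like(total, dtype=np.float64),
                           where=count > 0)
    all_censored = count == 0
    if warn and np.any(all_censored):
        warnings.warn(
            f"{int(all_censored.sum())} connection(s) had no significant value "
            "in any epoch; reported as 0", DegenerateCaseWarning, stacklevel=2)
    return aggregated, all_censored
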