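"""Effective connectivity: MVAR fitting and the directed transfer function.

The model is a vector autoregression

    X(t) = sum_{i=1..p} A(i) X(t-i) + eps(t)

fitted by ordinary least squares on the lagged design matrix, one model
per epoch (epochs are treated as quasi-stationary units).  In the
frequency domain the spectral coefficient polynomial is

    Abar(f) = I - sum_i A(i) exp(-j 2π f i Δt),      Δt = 1/fs

and the transfer matrix H(f) = Abar(f)^{-1} maps innovation spectra to
signal spectra.  The normalized DTF from source j into sink i is

    DTF²(j→i, f) = |H_ij(f)|² / Σ_m |H_im(f)|²

reported as its positive square root, so for every sink the squared
inflows over all sources sum to one at each frequency.

The MVAR stage operates on the 8 hemisphere-region-averaged signals
(LF, RF, LT, RT, LP, RP, LO, RO), not on all channels: averaging the
region signals first keeps the regression well-conditioned for 10 s
epochs, and directionality between hemispheres is exactly what the
transhemispheric analysis asks of the model.  DTF is evaluated on a
1–30 Hz grid with a 1 Hz step and averaged within the canonical bands
(band edges inclusive).
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np

from .containers import (
    CANONICAL_BANDS,
    DTFSpectrum,
    EpochedRecording,
    FrequencyBand,
    MVARModel,
    TransferMatrix,
)
from .montage import RegionScheme

__all__ = [
    "region_average_signals",
    "fit_mvar",
    "select_order",
    "transfer_matrix",
    "dtf",
    "band_average_dtf",
    "DEFAULT_FREQ_GRID",
    "MIN_SAMPLES_PER_PARAM",
]

#: DTF evaluation grid: 1..30 Hz, 1 Hz step.
DEFAULT_FREQ_GRID = np.arange(1.0, 31.0, 1.0)

#: Required samples per fitted parameter column: n - p >= this * p * k.
MIN_SAMPLES_PER_PARAM = 10


def region_average_signals(epochs: EpochedRecording,
                           scheme: RegionScheme) -> EpochedRecording:
    """Sample-wise mean of each region's channels, one output channel per region.

    Region order follows the scheme's declared order (for the shipped
    transhemispheric scheme: LF, RF, LT, RT, LP, RP, LO, RO).
    """
    index = {lab: i for i, lab in enumerate(epochs.channel_labels)}
    out = np.empty((epochs.n_epochs, epochs.n_samples, len(scheme.region_labels)))
    for r, region in enumerate(scheme.region_labels):
        chans = scheme.channels_of(region)
        missing = [c for c in chans if c not in index]
        if missing:
            raise KeyError(f"region {region!r}: channels {missing} absent from recording")
        cols = [index[c] for c in chans]
        out[:, :, r] = epochs.epochs[:, :, cols].mean(axis=2)
    return EpochedRecording(epochs=out, sampling_rate=epochs.sampling_rate,
                            channel_labels=scheme.region_labels)


def _lagged_design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Response (n-p, k) and design (n-p, k*p) for the lagged regression.

    Design columns are ordered lag-major: [X(t-1), X(t-2), ..., X(t-p)].
    """
    n, k = x.shape
    y = x[p:]
    design = np.empty((n - p, k * p))
    for i in range(1, p + 1):
        design[:, (i - 1) * k: i * k] = x[p - i: n - i]
    return y, design


def fit_mvar(epoch: np.ndarray, p: int, sampling_rate: float = 1.0) -> MVARModel:
    """Fit a VAR(p) by OLS on one epoch.

    Parameters
    ----------
    epoch : ndarray of shape (n_samples, k)
    p : int
        Model order (>= 1).
    sampling_rate : float
        Carried through to the frequency-domain stages.

    Raises
    ------
    ValueError
        If the sample is too short (fewer than ``10·p·k`` post-lag rows)
        or the design matrix is rank deficient (e.g. duplicated
        channels).
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim != 2:
        raise ValueError("epoch must be 2-D (n_samples, k)")
    n, k = epoch.shape
    if p < 1:
        raise ValueError("model order must be >= 1")
    if n - p < MIN_SAMPLES_PER_PARAM * p * k:
        raise ValueError(
            f"too few samples for VAR({p}) on {k} channels: need "
            f">= {MIN_SAMPLES_PER_PARAM * p * k + p}, got {n}"
        )
    y, design = _lagged_design(epoch, p)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient lagged design (rank {rank} < {design.shape[1]}); "
            "check for duplicated or constant channels"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    coeffs = np.empty((p, k, k))
    for i in range(p):
        # beta rows for lag i+1 hold A(i+1).T
        coeffs[i] = beta[i * k: (i + 1) * k].T
    resid = y - design @ beta
    dof = max(y.shape[0] - k * p, 1)
    resid_cov = resid.T @ resid / dof
    return MVARModel(order=p, coefficients=coeffs, residual_cov=resid_cov,
                     sampling_rate=sampling_rate)


def select_order(epoch: np.ndarray, p_max: int,
                 criterion: Literal["sbc", "aic"] = "sbc",
                 sampling_rate: float = 1.0) -> int:
    """Select the VAR order in 1..p_max by an information criterion.

    All candidate orders are scored on the common sample range (the
    first ``p_max`` rows are excluded for every candidate) so the
    criteria are comparable.  SBC (Schwarz/BIC) is the default; AIC is
    selectable.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    epoch = np.asarray(epoch, dtype=np.float64)
    n, k = epoch.shape
    scores = []
    n_eff = n - p_max
    if n_eff < MIN_SAMPLES_PER_PARAM * k:
        raise ValueError("sample too short for order selection")
    for p in range(1, p_max + 1):
        y, design = _lagged_design(epoch, p)
        y, design = y[p_max - p:], design[p_max - p:]
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        sigma = resid.T @ resid / n_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            logdet = -np.inf  # perfect fit; penalty alone decides
        n_params = p * k * k
        if criterion == "sbc":
            scores.append(logdet + np.log(n_eff) / n_eff * n_params)
        elif criterion == "aic":
            scores.append(logdet + 2.0 / n_eff * n_params)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    return int(np.argmin(scores)) + 1


def transfer_matrix(model: MVARModel, freqs: Sequence[float] | np.ndarray,
                    ) -> TransferMatrix:
    """Evaluate H(f) = [I − Σ A(i) e^(−j2πf·i·Δt)]⁻¹ on a frequency grid.

    Requires a stable model; raises if the spectral coefficient matrix
    is singular at any grid frequency (reporting the frequency).
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=np.float64))
    if not model.is_stable():
        raise ValueError(
            f"unstable MVAR model (companion spectral radius "
            f"{model.spectral_radius():.4f} >= 1)"
        )
    p, k = model.order, model.n_channels
    dt = 1.0 / model.sampling_rate
    lags = np.arange(1, p + 1)
    values = np.empty((freqs.size, k, k), dtype=np.complex128)
    eye = np.eye(k)
    for fi, f in enumerate(freqs):
        phase = np.exp(-2j * np.pi * f * lags * dt)  # (p,)
        a_bar = eye - np.tensordot(phase, model.coefficients, axes=(0, 0))
        try:
            values[fi] = np.linalg.inv(a_bar)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"spectral coefficient matrix singular at f={f} Hz") from exc
    return TransferMatrix(freqs=freqs, values=values)


def dtf(H: TransferMatrix) -> DTFSpectrum:
    """Normalized DTF from a transfer matrix.

    DTF(j→i, f) = |H_ij(f)| / sqrt(Σ_m |H_im(f)|²).  For every sink i
    and frequency the squared values over sources sum to 1.
    """
    mag2 = np.abs(H.values) ** 2
    inflow = mag2.sum(axis=2, keepdims=True)  # (n_f, k, 1)
    if np.any(inflow == 0.0):
        f_idx, i_idx = np.argwhere(inflow[:, :, 0] == 0.0)[0]
        raise ValueError(
            f"degenerate sink: all-zero transfer row i={int(i_idx)} at "
            f"f={H.freqs[int(f_idx)]} Hz"
        )
    return DTFSpectrum(freqs=H.freqs, values=np.sqrt(mag2 / inflow))


def band_average_dtf(spectrum: DTFSpectrum,
                     bands: Sequence[FrequencyBand] = CANONICAL_BANDS,
                     ) -> dict[str, np.ndarray]:
    """Arithmetic mean of DTF over grid frequencies inside each band.

    Band membership is inclusive at both edges (so on the 1 Hz grid the
    delta band averages f ∈ {1, 2, 3, 4} and a boundary frequency such
    as 4 Hz contributes to both delta and theta).
    """
    out: dict[str, np.ndarray] = {}
    for band in bands:
        mask = (spectrum.freqs >= band.low) & (spectrum.freqs <= band.high)
        if not np.any(mask):
            raise ValueError(
                f"band {band.name!r} [{band.low}, {band.high}] Hz does not "
                "intersect the evaluated frequency grid"
            )
        out[band.name] = spectrum.values[mask].mean(axis=0)
    return out


def epoch_dtf_bands(epoch: np.ndarray, p: int, sampling_rate: float,
                    freqs: np.ndarray = DEFAULT_FREQ_GRID,
                    bands: Sequence[FrequencyBand] = CANONICAL_BANDS,
                    ) -> np.ndarray:
    """Fit → transfer matrix → DTF → band averages for one epoch.

    Returns an array of shape (n_bands, k, k) with entry [b, i, j] the
    band-averaged DTF(j→i).  This is the statistic that the surrogate
    procedure recomputes on every surrogate draw.
    """
    model = fit_mvar(epoch, p, sampling_rate=sampling_rate)
    spec = dtf(transfer_matrix(model, freqs))
    by_band = band_average_dtf(spec, bands)
    return np.stack([by_band[b.name] for b in bands])
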