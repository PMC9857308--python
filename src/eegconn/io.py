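"""Readers, writers and run configuration.

Two recording formats are supported:

* **EDF** (input only), read through MNE's EDF reader; values are
  converted to microvolts.
* **Delimited text matrix** (input and output): a tab-separated
  samples × channels matrix alongside a JSON sidecar (same stem,
  ``.json``) holding ``sampling_rate`` and ``channel_labels``.

Epoched data round-trips through the delimited format by stacking
epochs along the sample axis and recording ``n_epochs`` in the sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .containers import EpochedRecording, MultichannelRecording

__all__ = [
    "read_recording",
    "write_recording",
    "read_epochs",
    "write_epochs",
    "PipelineConfig",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar header {sidecar} for delimited recording {path}"
        )
    with open(sidecar, "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    for key in ("sampling_rate", "channel_labels"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing required field {key!r}")
    return meta


def _read_edf(path: Path) -> MultichannelRecording:
    import mne  # heavyweight; imported only when EDF is actually read

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # volts → microvolts
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite samples in EDF file {path}")
    return MultichannelRecording(data=data, sampling_rate=float(raw.info["sfreq"]),
                                 channel_labels=tuple(raw.ch_names))


def read_recording(path: str | Path, format: str | None = None,
                   ) -> MultichannelRecording:
    """Read a recording from EDF or a delimited matrix with JSON sidecar.

    ``format`` is inferred from the extension when not given
    (``.edf`` → EDF, anything else → delimited).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path)
    if format != "delimited":
        raise ValueError(f"unknown recording format {format!r}")
    meta = _read_sidecar(path)
    data = np.loadtxt(path, ndmin=2)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite samples in {path}")
    return MultichannelRecording(data=data, sampling_rate=float(meta["sampling_rate"]),
                                 channel_labels=tuple(meta["channel_labels"]))


def write_recording(recording: MultichannelRecording, path: str | Path) -> Path:
    """Write a recording as a delimited matrix plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, recording.data, fmt="%.10g", delimiter="\t")
    meta = {"sampling_rate": recording.sampling_rate,
            "channel_labels": list(recording.channel_labels),
            "units": "uV"}
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
    return path


def write_epochs(epochs: EpochedRecording, path: str | Path) -> Path:
    """Write epoched data as stacked delimited rows plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stacked = epochs.epochs.reshape(-1, epochs.n_channels)
    np.savetxt(path, stacked, fmt="%.10g", delimiter="\t")
    meta = {"sampling_rate": epochs.sampling_rate,
            "channel_labels": list(epochs.channel_labels),
            "n_epochs": epochs.n_epochs, "units": "uV"}
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_epochs(path: str | Path) -> EpochedRecording:
    path = Path(path)
    meta = _read_sidecar(path)
    if "n_epochs" not in meta:
        raise ValueError(f"sidecar for {path} lacks 'n_epochs'; not an epochs file")
    data = np.loadtxt(path, ndmin=2)
    n_epochs = int(meta["n_epochs"])
    if data.shape[0] % n_epochs:
        raise ValueError(f"{data.shape[0]} rows not divisible by n_epochs={n_epochs}")
    epochs = data.reshape(n_epochs, data.shape[0] // n_epochs, data.shape[1])
    return EpochedRecording(epochs=epochs, sampling_rate=float(meta["sampling_rate"]),
                            channel_labels=tuple(meta["channel_labels"]))


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    Defaults follow the standard resting-state protocol: 1–45 Hz
    band-pass, 200 Hz target rate, 10 s epochs (at most 10), four
    canonical bands, a 1–30 Hz / 1 Hz DTF grid, 100 phase-randomization
    surrogates at α = 0.05, and α = 0.05 for the FDR-adjusted group
    tests.  The configuration serializes losslessly to JSON.
    """

    low: float = 1.0
    high: float = 45.0
    target_rate: float = 200.0
    epoch_length: float = 10.0
    max_epochs: int = 10
    scheme5: str = "regions5"
    scheme8: str = "regions8"
    estimator: str = "wpli"
    mvar_order: int | str = "auto"
    p_max: int = 20
    freq_lo: float = 1.0
    freq_hi: float = 30.0
    freq_step: float = 1.0
    n_surrogates: int = 100
    surrogate_alpha: float = 0.05
    stats_alpha: float = 0.05
    equal_var: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**doc)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @property
    def freq_grid(self) -> np.ndarray:
        return np.arange(self.freq_lo, self.freq_hi + 0.5 * self.freq_step,
                         self.freq_step)

    def manifest_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
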