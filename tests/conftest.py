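"""Shared fixtures: RNGs, tiny recordings, and a minimal EDF writer."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from eegconn import EpochedRecording, MultichannelRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_epochs(rng):
    """4 channels, 3 epochs of 2 s white noise at 200 Hz."""
    data = rng.normal(size=(3, 400, 4))
    return EpochedRecording(epochs=data, sampling_rate=200.0,
                            channel_labels=("c1", "c2", "c3", "c4"))


@pytest.fixture
def tone_recording():
    """10 s of a 10 Hz tone on 2 channels at 200 Hz (channel 2 lags 90°)."""
    t = np.arange(2000) / 200.0
    data = np.column_stack([np.cos(2 * np.pi * 10 * t),
                            np.cos(2 * np.pi * 10 * t - np.pi / 2)])
    return MultichannelRecording(data=data, sampling_rate=200.0,
                                 channel_labels=("a", "b"))


def write_minimal_edf(path: Path, data: np.ndarray, sampling_rate: int,
                      labels: list[str]) -> None:
    """Write a small EDF file (synthetic fixture, generated at test time).

    ``data`` is (n_samples, n_channels) in microvolts; n_samples must be
    a multiple of ``sampling_rate`` (whole 1 s records).
    """
    n_samples, ns = data.shape
    assert n_samples % sampling_rate == 0
    n_records = n_samples // sampling_rate
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    header_bytes = 256 * (1 + ns)

    def pad(text: str, width: int) -> bytes:
        return text.encode("ascii")[:width].ljust(width)

    with open(path, "wb") as fh:
        fh.write(pad("0", 8))
        fh.write(pad("X X X X", 80))
        fh.write(pad("Startdate 01-JAN-2020 X X X", 80))
        fh.write(pad("01.01.20", 8))
        fh.write(pad("00.00.00", 8))
        fh.write(pad(str(header_bytes), 8))
        fh.write(pad("EDF", 44))
        fh.write(pad(str(n_records), 8))
        fh.write(pad("1", 8))
        fh.write(pad(str(ns), 4))
        for lab in labels:
            fh.write(pad(f"EEG {lab}", 16))
        for _ in labels:
            fh.write(pad("AgAgCl electrode", 80))
        for _ in labels:
            fh.write(pad("uV", 8))
        for _ in labels:
            fh.write(pad(str(phys_min), 8))
        for _ in labels:
            fh.write(pad(str(phys_max), 8))
        for _ in labels:
            fh.write(pad(str(dig_min), 8))
        for _ in labels:
            fh.write(pad(str(dig_max), 8))
        for _ in labels:
            fh.write(pad("", 80))
        for _ in labels:
            fh.write(pad(str(sampling_rate), 8))
        for _ in labels:
            fh.write(pad("", 32))
        scale = (dig_max - dig_min) / (phys_max - phys_min)
        digital = np.clip(np.round((data - phys_min) * scale + dig_min),
                          dig_min, dig_max).astype("<i2")
        for r in range(n_records):
            chunk = digital[r * sampling_rate:(r + 1) * sampling_rate]
            for ch in range(ns):
                fh.write(chunk[:, ch].tobytes())
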