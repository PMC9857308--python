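"""Synthetic multichannel recordings with known coupling ground truth.

The generator produces the three ingredients the estimation stages must
recover or reject:

* **directed lagged coupling** — a stable MVAR process whose coefficient
  matrices carry user-specified edges (source → sink, lag, weight), the
  ground truth for DTF direction recovery;
* **within-region phase coupling** — a shared narrowband oscillation
  injected into a region's channels at distinct, nonzero phase offsets,
  the ground truth for wPLI recovery and for planted group differences;
* **zero-lag instantaneous mixing** — a channels × sources matrix applied
  sample-wise, emulating volume conduction; a correct phase-lag
  estimator must report (near-)zero coupling for it.

Everything is driven by a single master seed.  Per-subject random
streams are derived with NumPy's ``SeedSequence`` using the counter key
``(group_index, subject_index)``, so subjects are mutually independent
and the whole study is bit-reproducible; the derivation is stable across
runs and platforms.

The generator makes no attempt at biophysical realism (no 1/f
background, no artifacts, no head model); it provides exactly the
statistical structure the estimators are defined on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import EpochedRecording, MultichannelRecording
from .montage import RegionScheme

__all__ = [
    "CouplingGraph",
    "SimulationConfig",
    "PlantedCoupling",
    "GroundTruth",
    "StudySubject",
    "make_stable_mvar_coefficients",
    "simulate_mvar",
    "simulate_phase_locked_pair",
    "apply_instantaneous_mixing",
    "generate_group_study",
    "chain_graph",
    "compact_scheme5",
    "compact_scheme8",
    "make_planted_study",
]

#: Leading samples discarded from every MVAR simulation, per model order.
BURN_IN_PER_ORDER = 10


@dataclass(frozen=True)
class CouplingGraph:
    """Directed lagged coupling structure for an MVAR process.

    ``edges`` are (source, sink, lag, weight) tuples with lag ≥ 1 in
    samples; self-dynamics are specified separately (``self_decay`` in
    :func:`make_stable_mvar_coefficients`), so self-edges are not
    allowed here.
    """

    n_nodes: int
    edges: tuple[tuple[int, int, int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("graph needs at least one node")
        norm = []
        for src, dst, lag, weight in self.edges:
            src, dst, lag, weight = int(src), int(dst), int(lag), float(weight)
            if not (0 <= src < self.n_nodes and 0 <= dst < self.n_nodes):
                raise ValueError(f"edge ({src}->{dst}) references a missing node")
            if src == dst:
                raise ValueError(f"self-edge on node {src} not allowed")
            if lag < 1:
                raise ValueError(f"edge lag must be >= 1, got {lag}")
            if not np.isfinite(weight):
                raise ValueError("edge weight must be finite")
            norm.append((src, dst, lag, weight))
        object.__setattr__(self, "edges", tuple(norm))

    @property
    def max_lag(self) -> int:
        return max((lag for *_, lag, _ in self.edges), default=1)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation parameters; ``seed`` fully determines output."""

    sampling_rate: float = 200.0   # Hz
    epoch_length: float = 10.0     # s
    n_epochs: int = 10
    n_subjects_per_group: int = 20
    noise_sd: float = 1.0          # innovation SD, signal units
    self_decay: float = 0.5        # AR(1) diagonal of the background process
    mvar_order: int = 1
    target_radius: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be > 0")
        if self.n_epochs < 1 or self.n_subjects_per_group < 1:
            raise ValueError("need at least one epoch and one subject per group")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_length * self.sampling_rate))


@dataclass(frozen=True)
class PlantedCoupling:
    """A shared narrowband oscillation planted into one region.

    Channel ``channels[c]`` receives
    ``amp_group · cos(2π·freq·t + φ0 − phase_offsets[c])`` with a fresh
    random initial phase φ0 per subject and a small per-subject relative
    amplitude jitter.  Distinct, nonzero offset differences give every
    channel pair in the region a genuine phase lag, which is exactly
    what wPLI detects.
    """

    region: str
    channels: tuple[str, ...]
    band: str
    freq: float
    phase_offsets: tuple[float, ...]
    amplitude: Mapping[str, float]
    amplitude_jitter: float = 0.1

    def __post_init__(self) -> None:
        if len(self.phase_offsets) != len(self.channels):
            raise ValueError("one phase offset per planted channel required")
        if any(a < 0 for a in self.amplitude.values()):
            raise ValueError("amplitudes must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Ground truth of a two-group study.

    ``graphs`` maps group label → coupling graph (directed lagged
    coupling); ``mixing_matrix`` (channels × sources) is applied
    sample-wise after signal generation; ``planted`` describes the
    oscillatory within-region coupling whose strength may differ between
    groups.
    """

    channel_labels: tuple[str, ...]
    graphs: Mapping[str, CouplingGraph]
    mixing_matrix: np.ndarray | None = None
    planted: PlantedCoupling | None = None

    def __post_init__(self) -> None:
        if not self.graphs:
            raise ValueError("at least one group graph required")
        k = len(self.channel_labels)
        for group, graph in self.graphs.items():
            if graph.n_nodes != k:
                raise ValueError(
                    f"group {group!r} graph has {graph.n_nodes} nodes for "
                    f"{k} channels"
                )
        if self.mixing_matrix is not None:
            m = np.asarray(self.mixing_matrix, dtype=np.float64)
            if m.ndim != 2 or m.shape[1] != k:
                raise ValueError("mixing matrix must be (outputs, channels)")
            if np.linalg.matrix_rank(m) < m.shape[1]:
                raise ValueError("mixing matrix must have full column rank")
            object.__setattr__(self, "mixing_matrix", m)
        if self.planted is not None:
            unknown = [c for c in self.planted.channels if c not in self.channel_labels]
            if unknown:
                raise ValueError(f"planted channels not in montage: {unknown}")


@dataclass
class StudySubject:
    subject_id: str
    group: str
    epochs: EpochedRecording

    @property
    def recording(self) -> MultichannelRecording:
        """The subject's epochs re-concatenated into a continuous recording."""
        data = self.epochs.epochs.reshape(-1, self.epochs.n_channels)
        return MultichannelRecording(data=data, sampling_rate=self.epochs.sampling_rate,
                                     channel_labels=self.epochs.channel_labels)


def _companion_radius(coefficients: np.ndarray) -> float:
    p, k = coefficients.shape[:2]
    comp = np.zeros((p * k, p * k))
    comp[:k, :] = np.concatenate(list(coefficients), axis=1)
    if p > 1:
        comp[k:, :-k] = np.eye((p - 1) * k)
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def make_stable_mvar_coefficients(graph: CouplingGraph, p: int,
                                  self_decay: float = 0.5,
                                  target_radius: float = 0.95) -> np.ndarray:
    """Coefficient matrices A(1..p) realizing a coupling graph, stably.

    The diagonal of A(1) is ``self_decay``; every edge (j→i, lag d, w)
    sets A(d)[i, j] = w.  If the companion spectral radius exceeds
    ``target_radius`` all matrices are shrunk by a common factor (found
    by bisection) until it does not; edges remain nonzero.
    """
    if not 0.0 < target_radius < 1.0:
        raise ValueError("target_radius must be in (0, 1)")
    if p < 1:
        raise ValueError("model order must be >= 1")
    if graph.edges and graph.max_lag > p:
        raise ValueError(f"graph lag {graph.max_lag} exceeds model order {p}")
    k = graph.n_nodes
    coeffs = np.zeros((p, k, k))
    coeffs[0][np.diag_indices(k)] = self_decay
    for src, dst, lag, weight in graph.edges:
        coeffs[lag - 1, dst, src] = weight
    radius = _companion_radius(coeffs)
    if radius <= target_radius:
        return coeffs
    lo, hi = 0.0, 1.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _companion_radius(coeffs * mid) <= target_radius:
            lo = mid
        else:
            hi = mid
    if lo == 0.0 or _companion_radius(coeffs * lo) > target_radius:
        raise ValueError(
            "could not stabilize the coupling graph by uniform shrinkage"
        )
    return coeffs * lo


def _simulate_core(coefficients: np.ndarray, n_samples: int, noise_sd: float,
                   rng: np.random.Generator, burn_in: int | None = None) -> np.ndarray:
    p, k = coefficients.shape[:2]
    radius = _companion_radius(coefficients)
    if radius >= 1.0:
        raise ValueError(f"unstable coefficients (companion radius {radius:.4f} >= 1)")
    if burn_in is None:
        burn_in = BURN_IN_PER_ORDER * p
    total = n_samples + burn_in + p
    eps = rng.normal(0.0, noise_sd, size=(total, k))
    x = np.zeros((total, k))
    x[:p] = eps[:p]
    # flattened coefficients against the reversed lag window
    a_flat = np.concatenate(list(coefficients), axis=1)  # (k, k*p)
    for t in range(p, total):
        window = x[t - p: t][::-1].reshape(-1)  # [x(t-1); x(t-2); ...]
        x[t] = a_flat @ window + eps[t]
    return x[burn_in + p:]


def simulate_mvar(coefficients: np.ndarray, n_samples: int, noise_sd: float = 1.0,
                  seed: int | np.random.Generator | None = None,
                  sampling_rate: float = 1.0,
                  channel_labels: Sequence[str] | None = None,
                  burn_in: int | None = None) -> MultichannelRecording:
    """Run a stable MVAR process forward with Gaussian i.i.d. innovations.

    The first ``10·p`` post-initialization samples are discarded as
    burn-in, so the output is (approximately) a stationary draw.
    Raises before simulating if the coefficients are unstable.
    """
    coefficients = np.asarray(coefficients, dtype=np.float64)
    if coefficients.ndim != 3 or coefficients.shape[1] != coefficients.shape[2]:
        raise ValueError("coefficients must have shape (p, k, k)")
    rng = np.random.default_rng(seed)
    data = _simulate_core(coefficients, n_samples, noise_sd, rng, burn_in)
    k = coefficients.shape[1]
    labels = tuple(channel_labels) if channel_labels is not None else tuple(
        f"ch{i}" for i in range(k))
    return MultichannelRecording(data=data, sampling_rate=sampling_rate,
                                 channel_labels=labels)


def simulate_phase_locked_pair(freq: float, phase_lag: float, noise_sd: float,
                               n_samples: int, sampling_rate: float,
                               seed: int | np.random.Generator | None = None,
                               ) -> MultichannelRecording:
    """Two sinusoids at ``freq`` with a fixed phase lag plus independent noise.

    Channel 2 lags channel 1 by ``phase_lag`` radians.  A lag outside
    (−π, π] is wrapped with a warning.  With zero noise and a
    quarter-cycle lag the pair has wPLI 1; with zero lag the imaginary
    cross-spectrum vanishes and wPLI is 0 by convention.
    """
    if freq >= sampling_rate / 2.0:
        raise ValueError(f"freq {freq} Hz at or above Nyquist ({sampling_rate / 2} Hz)")
    wrapped = float(np.mod(phase_lag + np.pi, 2.0 * np.pi) - np.pi)
    if wrapped == -np.pi:
        wrapped = np.pi
    if abs(wrapped - phase_lag) > 1e-9:
        warnings.warn(
            f"phase_lag {phase_lag} outside (-pi, pi]; normalized to {wrapped:.6f}",
            UserWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n_samples) / sampling_rate
    base = 2.0 * np.pi * freq * t + phi0
    data = np.column_stack([
        np.cos(base) + rng.normal(0.0, noise_sd, n_samples),
        np.cos(base - wrapped) + rng.normal(0.0, noise_sd, n_samples),
    ])
    return MultichannelRecording(data=data, sampling_rate=sampling_rate,
                                 channel_labels=("ch1", "ch2"))


def apply_instantaneous_mixing(recording: MultichannelRecording,
                               mixing_matrix: np.ndarray) -> MultichannelRecording:
    """Sample-wise linear mixing (volume-conduction emulation); no temporal mixing."""
    m = np.asarray(mixing_matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[1] != recording.n_channels:
        raise ValueError(
            f"mixing matrix shape {m.shape} incompatible with "
            f"{recording.n_channels} channels"
        )
    mixed = recording.data @ m.T
    if m.shape[0] == recording.n_channels:
        labels: Sequence[str] = recording.channel_labels
    else:
        labels = tuple(f"mix{i}" for i in range(m.shape[0]))
    return MultichannelRecording(data=mixed, sampling_rate=recording.sampling_rate,
                                 channel_labels=labels)


def _subject_rng(master_seed: int, group_index: int,
                 subject_index: int) -> np.random.Generator:
    """Counter-based seed splitting: (master, group, subject) → stream."""
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(int(group_index), int(subject_index)))
    return np.random.default_rng(ss)


def generate_group_study(config: SimulationConfig, truth: GroundTruth,
                         ) -> list[StudySubject]:
    """Generate all subjects of a two-group study.

    Per subject: MVAR background from the group's coupling graph, plus
    the planted oscillation (if any) at the group's amplitude, then
    instantaneous mixing (if any), cut into ``n_epochs`` epochs.
    Subjects use independent random streams derived from
    ``config.seed`` by the (group, subject) counter rule.
    """
    k = len(truth.channel_labels)
    groups = list(truth.graphs)
    coeffs = {}
    order = max([config.mvar_order] + [g.max_lag for g in truth.graphs.values()])
    for group in groups:
        coeffs[group] = make_stable_mvar_coefficients(
            truth.graphs[group], order, self_decay=config.self_decay,
            target_radius=config.target_radius)
    n_total = config.n_epochs * config.samples_per_epoch
    t = np.arange(n_total) / config.sampling_rate
    chan_index = {lab: i for i, lab in enumerate(truth.channel_labels)}
    subjects = []
    for g_idx, group in enumerate(groups):
        for s_idx in range(config.n_subjects_per_group):
            rng = _subject_rng(config.seed, g_idx, s_idx)
            data = _simulate_core(coeffs[group], n_total, config.noise_sd, rng)
            if truth.planted is not None:
                planted = truth.planted
                amp = planted.amplitude.get(group, 0.0)
                if amp > 0.0:
                    jitter = 1.0 + planted.amplitude_jitter * rng.uniform(-1.0, 1.0)
                    phi0 = rng.uniform(0.0, 2.0 * np.pi)
                    base = 2.0 * np.pi * planted.freq * t + phi0
                    for ch, offset in zip(planted.channels, planted.phase_offsets):
                        data[:, chan_index[ch]] += amp * jitter * np.cos(base - offset)
            if truth.mixing_matrix is not None:
                data = data @ truth.mixing_matrix.T
            epochs = data.reshape(config.n_epochs, config.samples_per_epoch, k)
            subjects.append(StudySubject(
                subject_id=f"{group}{s_idx:02d}", group=group,
                epochs=EpochedRecording(epochs=epochs,
                                        sampling_rate=config.sampling_rate,
                                        channel_labels=truth.channel_labels)))
    return subjects


def chain_graph(n_nodes: int, weight: float = 0.4, lag: int = 1) -> CouplingGraph:
    """A directed chain 0→1→…→n−1 (node i drives node i+1)."""
    edges = tuple((i, i + 1, lag, weight) for i in range(n_nodes - 1))
    return CouplingGraph(n_nodes=n_nodes, edges=edges)


# ---------------------------------------------------------------------------
# Compact study layout used by the packaged simulation studies: a 20-channel
# subset of the 10-10 system with 4 channels per lobar region.  Small enough
# to run end-to-end studies quickly, structured like the full montage.

_COMPACT5 = {
    "F": ("F3", "Fz", "F4", "FCz"),
    "LT": ("FT7", "T7", "TP7", "CP5"),
    "P": ("C3", "Cz", "C4", "Pz"),
    "RT": ("FT8", "T8", "TP8", "CP6"),
    "O": ("O1", "Oz", "O2", "POz"),
}

_COMPACT8 = {
    "LF": ("F3",), "RF": ("F4",),
    "LT": ("FT7", "T7", "TP7", "CP5"), "RT": ("FT8", "T8", "TP8", "CP6"),
    "LP": ("C3",), "RP": ("C4",),
    "LO": ("O1",), "RO": ("O2",),
}


def compact_scheme5() -> RegionScheme:
    """5-region scheme over the compact 20-channel study montage."""
    return RegionScheme(name="compact5", kind="within", regions=dict(_COMPACT5))


def compact_scheme8() -> RegionScheme:
    """8-region transhemispheric scheme over the compact study montage."""
    return RegionScheme(name="compact8", kind="transhemispheric",
                        regions=dict(_COMPACT8),
                        pairs=(("LF", "RF"), ("LT", "RT"), ("LP", "RP"), ("LO", "RO")))


def compact_channels() -> tuple[str, ...]:
    return tuple(ch for chs in _COMPACT5.values() for ch in chs)


def make_planted_study(seed: int = 0, n_subjects_per_group: int = 20,
                       n_epochs: int = 10, effect: float = 0.25,
                       base_amplitude: float = 0.25,
                       mixing_strength: float = 0.05,
                       ) -> tuple[SimulationConfig, GroundTruth]:
    """Standard two-group study: theta coupling in F, elevated in group B.

    Group A's frontal channels share a 6 Hz oscillation of amplitude
    ``base_amplitude`` (phase-staggered so every pair has a genuine
    lag); group B's amplitude is ``base_amplitude + effect``.  With
    ``effect=0`` the groups are exchangeable (a null study).  A mild
    random dense mixing (I + mixing_strength·R) emulates volume
    conduction.  All other regions carry only the AR background.
    """
    channels = compact_channels()
    k = len(channels)
    config = SimulationConfig(n_subjects_per_group=n_subjects_per_group,
                              n_epochs=n_epochs, seed=seed)
    graph = CouplingGraph(n_nodes=k)
    mix_rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                           spawn_key=(999,)))
    mixing = np.eye(k) + mixing_strength * mix_rng.uniform(-1.0, 1.0, size=(k, k))
    planted = PlantedCoupling(
        region="F", channels=_COMPACT5["F"], band="theta", freq=6.0,
        phase_offsets=(0.0, 0.8, 1.6, 2.4),
        amplitude={"A": base_amplitude, "B": base_amplitude + effect},
    )
    truth = GroundTruth(channel_labels=channels, graphs={"A": graph, "B": graph},
                        mixing_matrix=mixing, planted=planted)
    return config, truth
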