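"""PLI / wPLI estimators and region aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegconn import (
    ConnectivityResult,
    DegenerateCaseWarning,
    MultichannelRecording,
    RegionScheme,
    aggregate_cross_region,
    aggregate_within_region,
    analytic_signal,
    band_by_name,
    band_connectivity_matrix,
    pli,
    segment_epochs,
    simulate_phase_locked_pair,
    wpli_from_imag,
    wpli_pair,
)
from eegconn.containers import EpochedRecording, FrequencyBand

ALPHA = band_by_name("alpha")


class TestAnalyticSignal:
    def test_unit_tone_amplitude(self):
        t = np.arange(2000) / 200.0
        a = analytic_signal(np.cos(2 * np.pi * 10 * t))
        assert np.allclose(a.amplitude[100:-100], 1.0, atol=0.01)

    def test_quadrature_pair_phase_offset(self):
        t = np.arange(2000) / 200.0
        ac = analytic_signal(np.cos(2 * np.pi * 10 * t))
        as_ = analytic_signal(np.sin(2 * np.pi * 10 * t))
        dphi = np.angle(np.exp(1j * (ac.phase - as_.phase)))[100:-100]
        assert np.allclose(dphi, np.pi / 2, atol=0.01)

    def test_chirp_instantaneous_frequency_tracks_ramp(self):
        fs = 1000.0
        t = np.arange(10000) / fs
        f0, f1 = 5.0, 40.0
        phase = 2 * np.pi * (f0 * t + (f1 - f0) / (2 * t[-1]) * t ** 2)
        a = analytic_signal(np.cos(phase))
        inst_freq = np.diff(np.unwrap(a.phase)) * fs / (2 * np.pi)
        expected = f0 + (f1 - f0) * t[:-1] / t[-1]
        interior = slice(500, -500)
        rel_err = np.abs(inst_freq[interior] - expected[interior]) / expected[interior]
        assert np.max(rel_err) < 0.02

    def test_constant_input_flagged_degenerate(self):
        with pytest.warns(DegenerateCaseWarning):
            a = analytic_signal(np.full(100, 3.0))
        assert a.degenerate

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="short"):
            analytic_signal(np.arange(8.0))


class TestPli:
    @pytest.mark.parametrize("dphi, expected", [
        ([0.1, 0.2, 0.3], 1.0),
        ([0.1, 0.2, -0.1, -0.2], 0.0),
        ([0.1, 0.2, 0.3, -0.1], 0.5),
    ])
    def test_hand_examples(self, dphi, expected):
        assert pli(dphi) == expected

    def test_sign_zero_contributes_zero(self):
        assert pli([0.0, 0.5]) == 0.5

    def test_wrapping_applied_before_sign(self):
        # 2π - 0.1 wraps to -0.1 (a lag, not a lead)
        assert pli([2 * np.pi - 0.1]) == 1.0
        assert np.sign(np.mean(np.sign([-0.1]))) < 0  # direction sanity

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pli([])


class TestWpli:
    def test_hand_example_imaginary_parts(self):
        assert wpli_from_imag([1.0, 2.0, -1.0]) == 0.5

    def test_uniform_sign_gives_one(self):
        assert wpli_from_imag([0.2, 1.5, 0.7]) == 1.0

    def test_zero_denominator_convention(self):
        with pytest.warns(DegenerateCaseWarning):
            assert wpli_from_imag([0.0, 0.0]) == 0.0

    def test_pair_symmetry(self, rng):
        x1, x2 = rng.normal(size=(2, 4000))
        w12 = wpli_pair(x1, x2, ALPHA, 200.0)
        w21 = wpli_pair(x2, x1, ALPHA, 200.0)
        assert w12 == pytest.approx(w21, abs=1e-12)

    def test_amplitude_rescaling_invariance(self, rng):
        x1, x2 = rng.normal(size=(2, 4000))
        w = wpli_pair(x1, x2, ALPHA, 200.0)
        w_scaled = wpli_pair(3.7 * x1, 0.2 * x2, ALPHA, 200.0)
        assert w_scaled == pytest.approx(w, abs=1e-10)

    def test_identical_channels_degenerate_zero(self, rng):
        x = rng.normal(size=4000)
        with pytest.warns(DegenerateCaseWarning):
            assert wpli_pair(x, x, ALPHA, 200.0) == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bounds_and_symmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        x1, x2 = rng.normal(size=(2, 1024))
        w = wpli_pair(x1, x2, ALPHA, 200.0)
        p = pli(np.angle(np.exp(1j * rng.uniform(-4, 4, size=256))))
        assert 0.0 <= w <= 1.0
        assert 0.0 <= p <= 1.0
        assert wpli_pair(x2, x1, ALPHA, 200.0) == pytest.approx(w, abs=1e-12)


class TestConnectivityMatrix:
    def test_white_noise_off_diagonal_below_finite_sample_bound(self, rng):
        data = rng.normal(size=(10, 2000, 4))
        epochs = EpochedRecording(epochs=data, sampling_rate=200.0,
                                  channel_labels=("a", "b", "c", "d"))
        res = band_connectivity_matrix(epochs, ALPHA)
        off = res.values[~np.eye(4, dtype=bool)]
        assert np.all(off <= 0.25)
        assert np.all(np.diag(res.values) == 0.0)

    def test_planted_pair_attains_matrix_maximum(self, rng):
        rec = simulate_phase_locked_pair(10.0, np.pi / 3, 0.5, 8000, 200.0, seed=4)
        noise = rng.normal(size=(8000, 2))
        data = np.column_stack([rec.data, noise])
        epochs = segment_epochs(MultichannelRecording(
            data=data, sampling_rate=200.0,
            channel_labels=("p1", "p2", "n1", "n2")), 10.0)
        res = band_connectivity_matrix(epochs, ALPHA)
        iu = np.triu_indices(4, k=1)
        top = np.argmax(res.values[iu])
        assert (iu[0][top], iu[1][top]) == (0, 1)

    def test_matrix_symmetric(self, noise_epochs):
        res = band_connectivity_matrix(noise_epochs, ALPHA)
        np.testing.assert_allclose(res.values, res.values.T, atol=1e-14)

    def test_epoch_average_of_identical_epochs_equals_single(self, rng):
        one = rng.normal(size=(1, 2000, 3))
        rep = np.repeat(one, 4, axis=0)
        labels = ("a", "b", "c")
        r1 = band_connectivity_matrix(EpochedRecording(
            epochs=one, sampling_rate=200.0, channel_labels=labels), ALPHA)
        r4 = band_connectivity_matrix(EpochedRecording(
            epochs=rep, sampling_rate=200.0, channel_labels=labels), ALPHA)
        np.testing.assert_allclose(r1.values, r4.values, atol=1e-12)

    def test_single_channel_rejected(self, noise_epochs):
        single = noise_epochs.with_epochs(noise_epochs.epochs[:, :, :1],
                                          channel_labels=("c1",))
        with pytest.raises(ValueError, match="at least 2"):
            band_connectivity_matrix(single, ALPHA)


def _matrix_result(values, labels):
    return ConnectivityResult(estimator="wpli", band="alpha",
                              level="channel-pair", labels=labels, values=values)


class TestAggregation:
    def test_three_channel_region_mean(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 0.2
        values[0, 2] = values[2, 0] = 0.4
        values[1, 2] = values[2, 1] = 0.6
        scheme = RegionScheme(name="s", kind="within",
                              regions={"R": ("a", "b", "c")})
        res = aggregate_within_region(_matrix_result(values, ("a", "b", "c")), scheme)
        assert res.values[0] == pytest.approx(0.4)

    def test_constant_matrix_aggregates_to_constant(self):
        values = np.full((4, 4), 0.3)
        np.fill_diagonal(values, 0.0)
        labels = ("a", "b", "c", "d")
        scheme = RegionScheme(name="s", kind="within",
                              regions={"R1": ("a", "b"), "R2": ("c", "d")})
        res = aggregate_within_region(_matrix_result(values, labels), scheme)
        np.testing.assert_allclose(res.values, 0.3)

    def test_two_channel_region_is_single_pair(self):
        values = np.array([[0.0, 0.7], [0.7, 0.0]])
        scheme = RegionScheme(name="s", kind="within", regions={"R": ("a", "b")})
        res = aggregate_within_region(_matrix_result(values, ("a", "b")), scheme)
        assert res.values[0] == pytest.approx(0.7)

    def test_undersized_region_named_in_error(self):
        values = np.zeros((2, 2))
        scheme = RegionScheme(name="s", kind="within",
                              regions={"tiny": ("a",), "ok": ("b",)})
        with pytest.raises(ValueError, match="tiny"):
            aggregate_within_region(_matrix_result(values, ("a", "b")), scheme)

    def test_cross_region_mean_of_four(self):
        values = np.zeros((4, 4))
        values[0, 2], values[0, 3] = 0.1, 0.2
        values[1, 2], values[1, 3] = 0.3, 0.4
        values += values.T
        scheme = RegionScheme(name="s", kind="transhemispheric",
                              regions={"L": ("a", "b"), "R": ("c", "d")},
                              pairs=(("L", "R"),))
        v = aggregate_cross_region(_matrix_result(values, ("a", "b", "c", "d")),
                                   scheme, ("L", "R"))
        assert v == pytest.approx(0.25)

    def test_single_channel_regions_pass_through(self):
        values = np.array([[0.0, 0.9], [0.9, 0.0]])
        scheme = RegionScheme(name="s", kind="transhemispheric",
                              regions={"L": ("a",), "R": ("b",)}, pairs=(("L", "R"),))
        v = aggregate_cross_region(_matrix_result(values, ("a", "b")), scheme,
                                   ("L", "R"))
        assert v == pytest.approx(0.9)

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="exactly one region|assigned to both"):
            RegionScheme(name="s", kind="transhemispheric",
                         regions={"L": ("a", "b"), "R": ("b", "c")},
                         pairs=(("L", "R"),))


def test_zero_lag_mixed_sources_stay_below_null_95th_percentile(rng):
    """Instantaneous mixing must not create spurious wPLI (volume conduction)."""
    wide = FrequencyBand("wide", 1.0, 45.0)
    mix = np.array([[1.0, 0.6], [0.6, 1.0]])
    null = []
    for _ in range(40):
        a, b = rng.normal(size=(2, 4000))
        null.append(wpli_pair(a, b, wide, 200.0))
    q95 = np.quantile(null, 0.95)
    mixed_vals = []
    for _ in range(10):
        src = rng.normal(size=(4000, 2)) @ mix.T
        mixed_vals.append(wpli_pair(src[:, 0], src[:, 1], wide, 200.0))
    assert np.median(mixed_vals) <= q95
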