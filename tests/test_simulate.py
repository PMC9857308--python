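"""Synthetic-data generator: coefficient construction, simulation, studies."""

import numpy as np
import pytest

from eegconn import (
    CouplingGraph,
    DegenerateCaseWarning,
    GroundTruth,
    MultichannelRecording,
    SimulationConfig,
    apply_instantaneous_mixing,
    band_by_name,
    generate_group_study,
    make_planted_study,
    make_stable_mvar_coefficients,
    simulate_mvar,
    simulate_phase_locked_pair,
    wpli_pair,
)
from eegconn.containers import FrequencyBand
from eegconn.simulate import _companion_radius, chain_graph

WIDE = FrequencyBand("wide", 1.0, 45.0)


class TestCouplingGraph:
    def test_rejects_self_edges_and_bad_lags(self):
        with pytest.raises(ValueError, match="self-edge"):
            CouplingGraph(2, ((0, 0, 1, 0.5),))
        with pytest.raises(ValueError, match="lag"):
            CouplingGraph(2, ((0, 1, 0, 0.5),))
        with pytest.raises(ValueError, match="missing node"):
            CouplingGraph(2, ((0, 5, 1, 0.5),))


class TestStableCoefficients:
    def test_empty_graph_is_scaled_identity(self):
        coeffs = make_stable_mvar_coefficients(CouplingGraph(3), p=1, self_decay=0.5)
        assert np.allclose(coeffs[0], 0.5 * np.eye(3))
        assert _companion_radius(coeffs) == pytest.approx(0.5)

    def test_single_edge_triangular_radius(self):
        graph = CouplingGraph(2, ((0, 1, 1, 0.4),))
        coeffs = make_stable_mvar_coefficients(graph, p=1, self_decay=0.5)
        assert np.allclose(coeffs[0], [[0.5, 0.0], [0.4, 0.5]])
        # triangular matrix: eigenvalues are the diagonal
        assert _companion_radius(coeffs) == pytest.approx(0.5)

    def test_strong_ring_is_rescaled_below_target(self):
        edges = tuple((i, (i + 1) % 4, 1, 2.0) for i in range(4))
        graph = CouplingGraph(4, edges)
        coeffs = make_stable_mvar_coefficients(graph, p=1, self_decay=0.5,
                                               target_radius=0.9)
        assert _companion_radius(coeffs) <= 0.9 + 1e-9
        # edges survive the shrinkage as nonzero entries
        for src, dst, lag, _ in edges:
            assert coeffs[lag - 1, dst, src] != 0.0

    def test_lag_exceeding_order_rejected(self):
        graph = CouplingGraph(2, ((0, 1, 3, 0.4),))
        with pytest.raises(ValueError, match="lag"):
            make_stable_mvar_coefficients(graph, p=2)


class TestSimulateMvar:
    def test_zero_coefficients_give_white_noise(self):
        coeffs = np.zeros((1, 2, 2))
        rec = simulate_mvar(coeffs, 20000, noise_sd=1.5, seed=0)
        assert rec.data.std(axis=0) == pytest.approx([1.5, 1.5], rel=0.05)

    def test_ar1_autocorrelation(self):
        coeffs = np.array([[[0.9]]])
        rec = simulate_mvar(coeffs, 20000, seed=1)
        x = rec.data[:, 0]
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(0.9, abs=0.02)

    def test_lagged_edge_peaks_cross_correlation_at_its_lag(self):
        graph = CouplingGraph(2, ((0, 1, 2, 0.8),))
        coeffs = make_stable_mvar_coefficients(graph, p=2, self_decay=0.2)
        rec = simulate_mvar(coeffs, 50000, seed=2)
        x, y = rec.data[:, 0], rec.data[:, 1]
        lags = range(-5, 6)
        cc = [np.corrcoef(x[5 + l: len(x) - 5 + l], y[5: -5])[0, 1] for l in lags]
        assert list(lags)[int(np.argmax(cc))] == -2  # ch0 leads ch1 by 2 samples

    def test_unstable_coefficients_rejected_before_simulation(self):
        with pytest.raises(ValueError, match="unstable"):
            simulate_mvar(np.array([[[1.05]]]), 100)

    def test_seed_determinism(self):
        coeffs = np.array([[[0.5, 0.0], [0.3, 0.5]]])
        a = simulate_mvar(coeffs, 500, seed=7)
        b = simulate_mvar(coeffs, 500, seed=7)
        np.testing.assert_array_equal(a.data, b.data)


class TestPhaseLockedPair:
    def test_quarter_cycle_noise_free_wpli_is_one(self):
        rec = simulate_phase_locked_pair(10.0, np.pi / 2, 0.0, 20000, 200.0, seed=0)
        w = wpli_pair(rec.data[:, 0], rec.data[:, 1], WIDE, 200.0)
        assert w >= 0.99

    def test_zero_lag_pair_has_zero_wpli_by_convention(self):
        rec = simulate_phase_locked_pair(10.0, 0.0, 0.0, 4000, 200.0, seed=0)
        with pytest.warns(DegenerateCaseWarning):
            w = wpli_pair(rec.data[:, 0], rec.data[:, 1], WIDE, 200.0)
        assert w == 0.0

    def test_noisy_intermediate_lag_gives_intermediate_wpli(self):
        rec = simulate_phase_locked_pair(10.0, np.pi / 4, 1.0, 20000, 200.0, seed=3)
        w = wpli_pair(rec.data[:, 0], rec.data[:, 1], band_by_name("alpha"), 200.0)
        assert 0.5 < w < 1.0

    def test_out_of_range_lag_normalized_with_warning(self):
        with pytest.warns(UserWarning, match="normalized"):
            rec = simulate_phase_locked_pair(5.0, 3 * np.pi, 0.0, 1000, 200.0, seed=0)
        ref = simulate_phase_locked_pair(5.0, np.pi, 0.0, 1000, 200.0, seed=0)
        np.testing.assert_allclose(rec.data, ref.data, atol=1e-12)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_phase_locked_pair(120.0, 0.1, 0.0, 1000, 200.0)


class TestInstantaneousMixing:
    def test_identity_mixing_is_identity(self, tone_recording):
        out = apply_instantaneous_mixing(tone_recording, np.eye(2))
        np.testing.assert_array_equal(out.data, tone_recording.data)

    def test_dimension_mismatch_rejected(self, tone_recording):
        with pytest.raises(ValueError, match="incompatible"):
            apply_instantaneous_mixing(tone_recording, np.eye(3))

    def test_zero_lag_mixing_of_independent_noise_yields_low_wpli(self):
        rng = np.random.default_rng(0)
        src = MultichannelRecording(data=rng.normal(size=(20000, 2)),
                                    sampling_rate=200.0, channel_labels=("s1", "s2"))
        rec = apply_instantaneous_mixing(src, np.array([[1.0, 0.5], [0.5, 1.0]]))
        w = wpli_pair(rec.data[:, 0], rec.data[:, 1], WIDE, 200.0)
        assert w <= 0.1

    def test_rank_one_mixing_gives_degenerate_zero(self, tone_recording):
        rec = apply_instantaneous_mixing(tone_recording.with_data(
            tone_recording.data[:, [0, 0]], channel_labels=("a", "b")),
            np.array([[1.0, 0.0], [2.0, 0.0]]))
        with pytest.warns(DegenerateCaseWarning):
            w = wpli_pair(rec.data[:, 0], rec.data[:, 1], WIDE, 200.0)
        assert w == 0.0


class TestGroupStudy:
    def test_seed_determinism_and_subject_independence(self):
        config, truth = make_planted_study(seed=5, n_subjects_per_group=2, n_epochs=2)
        a = generate_group_study(config, truth)
        b = generate_group_study(config, truth)
        assert [s.subject_id for s in a] == ["A00", "A01", "B00", "B01"]
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.epochs.epochs, sb.epochs.epochs)
        assert not np.array_equal(a[0].epochs.epochs, a[1].epochs.epochs)

    def test_study_shapes_follow_config(self):
        config, truth = make_planted_study(seed=1, n_subjects_per_group=3, n_epochs=4)
        study = generate_group_study(config, truth)
        assert len(study) == 6
        subj = study[0]
        assert subj.epochs.n_epochs == 4
        assert subj.epochs.n_samples == config.samples_per_epoch == 2000
        assert subj.epochs.channel_labels == truth.channel_labels

    def test_planted_theta_coupling_is_recoverable_in_region(self):
        config, truth = make_planted_study(seed=9, n_subjects_per_group=1,
                                           n_epochs=2, effect=0.75)
        study = generate_group_study(config, truth)
        b_subj = [s for s in study if s.group == "B"][0]
        theta = band_by_name("theta")
        f_chs = truth.planted.channels[:2]
        idx = [truth.channel_labels.index(c) for c in f_chs]
        epoch = b_subj.epochs.epochs[0]
        w_planted = wpli_pair(epoch[:, idx[0]], epoch[:, idx[1]], theta, 200.0)
        # an uncoupled pair from different regions for contrast
        j = truth.channel_labels.index("O1")
        w_null = wpli_pair(epoch[:, idx[0]], epoch[:, j], theta, 200.0)
        assert w_planted > 0.8
        assert w_planted > w_null

    def test_mixing_matrix_full_rank_enforced(self):
        config, truth = make_planted_study(seed=1, n_subjects_per_group=2)
        bad = np.zeros((len(truth.channel_labels), len(truth.channel_labels)))
        with pytest.raises(ValueError, match="full column rank"):
            GroundTruth(channel_labels=truth.channel_labels, graphs=truth.graphs,
                        mixing_matrix=bad, planted=truth.planted)

    def test_chain_graph_layout(self):
        g = chain_graph(3, weight=0.4, lag=1)
        assert g.edges == ((0, 1, 1, 0.4), (1, 2, 1, 0.4))
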