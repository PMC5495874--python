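"""Spike averaging, whitened fusion, sLORETA, clustering and ROI export."""

import numpy as np
import pytest

from conftest import split_modalities

from emegfem.inverse import (
    EvokedData,
    InverseConfig,
    RoiBox,
    SourceEstimate,
    average_spikes,
    combine_emeg,
    dipole_scan_goal,
    localize_at,
    roi_box,
    sloreta,
    threshold_clusters,
    whiten,
)
from emegfem.phantom import ChannelMeta, DipoleSource, RawTrials, SpikeSimConfig, simulate_ied_recordings


def make_trials(data, sampling_rate=1000.0, event_latency=100, noise_std=1.0):
    meta = [ChannelMeta(f"c{i}", "eeg", noise_std) for i in range(data.shape[0])]
    return RawTrials(data, meta, sampling_rate, event_latency)


class TestAverageSpikes:
    def test_single_trial_average_is_that_trial(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4, 300, 1))
        tr = make_trials(data)
        ev = average_spikes(tr, window_ms=(-50, 50), baseline_ms=(-50, -30))
        np.testing.assert_array_equal(ev.data, data[:, 50:151, 0])
        assert ev.time_zero == 50

    def test_identical_trials_average_identically(self):
        one = np.random.default_rng(1).standard_normal((3, 300))
        data = np.repeat(one[:, :, None], 7, axis=2)
        ev = average_spikes(make_trials(data), window_ms=(-60, 60), baseline_ms=(-60, -40))
        np.testing.assert_allclose(ev.data, one[:, 40:161], rtol=1e-14)

    def test_baseline_noise_shrinks_as_sqrt_n(self):
        """The average's estimated baseline noise tracks sigma/sqrt(n)
        within 20% (Monte-Carlo over seeds)."""
        n_trials, sigma = 16, 2.0
        est = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            data = sigma * rng.standard_normal((6, 400, n_trials))
            ev = average_spikes(make_trials(data, event_latency=200), window_ms=(-150, 100), baseline_ms=(-150, -50))
            est.append(np.mean(ev.noise_std()))
        assert np.mean(est) == pytest.approx(sigma / np.sqrt(n_trials), rel=0.2)

    def test_window_beyond_bounds_rejected(self):
        tr = make_trials(np.zeros((2, 100, 3)), event_latency=50)
        with pytest.raises(ValueError, match="beyond"):
            average_spikes(tr, window_ms=(-80, 80), baseline_ms=(-80, -60))


class TestWhitenAndCombine:
    def test_whitened_baseline_variance_is_unity(self, tiny_leadfield):
        cfg = SpikeSimConfig(
            onset_source=DipoleSource(tiny_leadfield.source_positions[0], [0, 10.0, 0]),
            peak_source=DipoleSource(tiny_leadfield.source_positions[1], [10.0, 0, 0]),
            n_trials=20,
            seed=3,
        )
        tr = simulate_ied_recordings(tiny_leadfield, cfg)
        ev = average_spikes(tr)
        wev, wlf = whiten(ev, tiny_leadfield)
        base = wev.data[:, : wev.time_zero - 120]
        assert np.mean(base.var(axis=1)) == pytest.approx(1.0, rel=0.35)
        assert all(m.noise_std == 1.0 for m in wev.channel_meta)

    def test_combining_modality_with_itself_duplicates_rows(self, tiny_leadfield):
        lf_e = tiny_leadfield.block("eeg")
        ev = EvokedData(
            np.ones((lf_e.matrix.shape[0], 10)),
            [ChannelMeta(n, "eeg", 2.0) for n in lf_e.row_names],
            1000.0,
            5,
        )
        jev, jlf = combine_emeg(ev, ev, lf_e, lf_e)
        n = lf_e.matrix.shape[0]
        np.testing.assert_array_equal(jlf.matrix[:n], jlf.matrix[n:])
        np.testing.assert_array_equal(jev.data[:n], jev.data[n:])

    def test_source_space_mismatch_rejected(self, tiny_leadfield):
        import copy

        lf_e = tiny_leadfield.block("eeg")
        lf_m = copy.deepcopy(tiny_leadfield.block("meg"))
        lf_m.source_positions = lf_m.source_positions + 1.0
        ev_e = EvokedData(np.ones((lf_e.matrix.shape[0], 4)), [ChannelMeta(n, "eeg", 1.0) for n in lf_e.row_names], 1000.0, 2)
        ev_m = EvokedData(np.ones((lf_m.matrix.shape[0], 4)), [ChannelMeta(n, "meg", 1.0) for n in lf_m.row_names], 1000.0, 2)
        with pytest.raises(ValueError, match="source spaces"):
            combine_emeg(ev_e, ev_m, lf_e, lf_m)


class TestSloreta:
    def test_noiseless_single_source_zero_localization_error(self, inverse_phantom):
        """The defining sLORETA property: argmax F at the true node."""
        lf = inverse_phantom["leadfields"]
        rng = np.random.default_rng(11)
        cfg = InverseConfig(lambda_value=1e-10)
        for j in rng.choice(lf.n_sources, 10, replace=False):
            m = rng.standard_normal(3)
            y = lf.column_block(int(j)) @ m
            est = sloreta(lf, y, cfg)
            assert int(np.argmax(est.f_values)) == j

    def test_f_map_shape_invariant_under_rescaling(self, inverse_phantom):
        """F is quadratic in the data, so rescaling the topography scales
        the whole map by c^2 and leaves its shape (and argmax) unchanged."""
        lf = inverse_phantom["leadfields"]
        y = lf.column_block(5) @ np.array([1.0, 2.0, -1.0])
        f1 = sloreta(lf, y, InverseConfig(lambda_relative=1e-8)).f_values
        f2 = sloreta(lf, 7.5 * y, InverseConfig(lambda_relative=1e-8)).f_values
        np.testing.assert_allclose(f2, 7.5**2 * f1, rtol=1e-8)
        np.testing.assert_allclose(f2 / f2.max(), f1 / f1.max(), rtol=1e-8)

    def test_two_separated_sources_recovered_at_their_latencies(self, inverse_phantom):
        """Two noiseless foci >= 40 mm apart activated at different latencies
        are each the argmax at their own latency."""
        lf = inverse_phantom["leadfields"]
        ss = inverse_phantom["source_space"]
        p_on = np.array([-30.0, 10.0, 25.0])
        p_pk = np.array([25.0, 20.0, 20.0])
        j_on = int(np.argmin(np.linalg.norm(ss.positions - p_on, axis=1)))
        j_pk = int(np.argmin(np.linalg.norm(ss.positions - p_pk, axis=1)))
        assert np.linalg.norm(ss.positions[j_on] - ss.positions[j_pk]) >= 40.0
        cfg = SpikeSimConfig(
            onset_source=DipoleSource(ss.positions[j_on], [0, 20.0, 0]),
            peak_source=DipoleSource(ss.positions[j_pk], [20.0, 0, 0]),
            snr_eeg=1e9,
            snr_meg=1e9,
            n_trials=1,
            seed=0,
        )
        tr = simulate_ied_recordings(lf, cfg)
        ev = average_spikes(tr)
        eeg_ev, meg_ev = split_modalities(ev)
        jev, jlf = combine_emeg(eeg_ev, meg_ev, lf.block("eeg"), lf.block("meg"))
        icfg = InverseConfig(lambda_relative=1e-12)
        est_pk = sloreta(jlf, jev.topography(0.0), icfg)
        est_on = sloreta(jlf, jev.topography(-23.0), icfg)
        assert int(np.argmax(est_pk.f_values)) == j_pk
        assert int(np.argmax(est_on.f_values)) == j_on

    def test_zero_topography_rejected(self, inverse_phantom):
        with pytest.raises(ValueError, match="all-zero"):
            sloreta(inverse_phantom["leadfields"], np.zeros(64))


class TestThresholdClusters:
    def _est(self, f, positions, spacing=6.0):
        return SourceEstimate(f_values=f, positions=positions, spacing=spacing, latency_ms=0.0, modality_set="EMEG")

    def test_all_equal_f_forms_one_cluster(self):
        pos = np.stack(np.meshgrid(*[np.arange(4) * 6.0] * 3, indexing="ij"), -1).reshape(-1, 3)
        est = self._est(np.ones(len(pos)), pos)
        out = threshold_clusters(est, InverseConfig(min_cluster_size=1))
        assert len(out.clusters) == 1
        assert len(out.clusters[0].nodes) == len(pos)

    def test_single_source_cluster_contains_true_node(self, inverse_phantom):
        lf = inverse_phantom["leadfields"]
        j = 100
        y = lf.column_block(j) @ np.array([5.0, 0.0, 5.0])
        est = sloreta(lf, y, InverseConfig(lambda_value=1e-10))
        out = threshold_clusters(est, InverseConfig(min_cluster_size=1))
        assert len(out.clusters) >= 1
        assert j in out.clusters[0].nodes  # clusters sorted by peak F

    def test_min_cluster_size_discards_small_islands(self):
        pos = np.array([[0.0, 0, 0], [6.0, 0, 0], [60.0, 0, 0]])
        f = np.array([1.0, 0.99, 0.95])
        out = threshold_clusters(self._est(f, pos), InverseConfig(min_cluster_size=2, threshold_fraction=0.85))
        assert len(out.clusters) == 1 and set(out.clusters[0].nodes) == {0, 1}

    def test_clusters_disjoint_and_above_threshold(self, inverse_phantom):
        lf = inverse_phantom["leadfields"]
        y = lf.column_block(40) @ np.array([3.0, 1.0, 0.0]) + lf.column_block(2200) @ np.array([0.0, 3.0, 1.0])
        cfg = InverseConfig(min_cluster_size=1, threshold_fraction=0.85)
        out = threshold_clusters(sloreta(lf, y, cfg), cfg)
        seen = set()
        fmax = out.f_values.max()
        for cl in out.clusters:
            assert not (seen & set(cl.nodes.tolist()))
            seen |= set(cl.nodes.tolist())
            assert cl.peak_f >= 0.85 * fmax


class TestRoiBox:
    def test_default_extents_and_span(self):
        box = roi_box([0.0, 0.0, 0.0])
        assert box.extents == (160.0, 82.0, 28.0)
        np.testing.assert_allclose(box.lower, [-80.0, -41.0, -14.0])
        np.testing.assert_allclose(box.upper, [80.0, 41.0, 14.0])

    def test_contains_cluster_smaller_than_extents(self, inverse_phantom):
        lf = inverse_phantom["leadfields"]
        y = lf.column_block(70) @ np.array([2.0, -1.0, 0.5])
        cfg = InverseConfig(min_cluster_size=1)
        out = threshold_clusters(sloreta(lf, y, cfg), cfg)
        cl = out.clusters[0]
        box = roi_box(out.positions[cl.peak_node], extents=(28.0, 28.0, 28.0))
        pts = out.positions[cl.nodes]
        diam = np.ptp(pts, axis=0).max()
        if diam < 28.0:
            assert box.contains(pts).all()

    def test_bad_extents_rejected(self):
        with pytest.raises(ValueError, match="extents"):
            RoiBox(center=np.zeros(3), extents=(0.0, 10.0, 10.0))


class TestDipoleScanGoal:
    def test_rv_zero_at_truth_and_bounded(self, inverse_phantom):
        lf = inverse_phantom["leadfields"]
        j = 321
        y = lf.column_block(j) @ np.array([1.0, -2.0, 0.5])
        rv = dipole_scan_goal(lf, y)
        assert rv[j] < 1e-12
        assert rv.min() >= 0.0 and rv.max() <= 1.0

    def test_rv_minimum_matches_sloreta_argmax(self, inverse_phantom):
        lf = inverse_phantom["leadfields"]
        j = 1234
        y = lf.column_block(j) @ np.array([0.0, 1.0, 1.0])
        rv = dipole_scan_goal(lf, y)
        est = sloreta(lf, y, InverseConfig(lambda_value=1e-10))
        assert int(np.argmin(rv)) == int(np.argmax(est.f_values)) == j

    def test_rv_invariant_to_data_scale(self, inverse_phantom):
        lf = inverse_phantom["leadfields"]
        y = lf.column_block(10) @ np.array([1.0, 0.0, 0.0])
        np.testing.assert_allclose(dipole_scan_goal(lf, y), dipole_scan_goal(lf, 3.7 * y), atol=1e-10)
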