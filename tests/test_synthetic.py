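"""Node placement, target W law, calibration and cohort generation."""

import numpy as np
import pytest

from obscor.errors import DomainError, GeometryError
from obscor.params import MethodParams
from obscor.synthetic import (CalibrationCurve, GroundTruth, SyntheticConfig,
                              analytic_calibration, calibrate_rho_to_W,
                              effective_sampling_period, fisher_z_W,
                              generate_cohort, place_nodes, target_W)


class TestPlaceNodes:
    def test_realistic_geometry(self):
        nodes = place_nodes(72, seed=1)
        assert len(nodes) == 72
        dm = nodes.distance_matrix()
        d = dm[np.triu_indices(72, k=1)]
        assert d.min() > 10.0
        assert d.max() < 180.0
        # distances cover the probed range
        assert d.min() < 15.0 and d.max() > 150.0
        assert set(nodes.hemispheres) == {"left", "right"}
        left = nodes.positions[[h == "left" for h in nodes.hemispheres]]
        assert np.all(left[:, 0] < 0)

    def test_two_nodes(self):
        nodes = place_nodes(2, seed=0)
        assert len(nodes) == 2

    def test_deterministic_given_seed(self):
        a = place_nodes(20, seed=5)
        b = place_nodes(20, seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.node_ids == b.node_ids

    def test_impossible_spacing_raises(self):
        with pytest.raises(GeometryError):
            place_nodes(60, seed=0, min_distance=60.0)


class TestTargetW:
    GT = GroundTruth(slopes=(7.0, 19.0, 7.0), breakpoints=(44.0, 68.3),
                     intercept=10.0, w_range=(0.2, 40.0))

    def test_continuity_at_breakpoints(self):
        for b in self.GT.breakpoints:
            below = target_W(b * (1 - 1e-9), self.GT)
            above = target_W(b * (1 + 1e-9), self.GT)
            assert below == pytest.approx(above, abs=1e-6)

    def test_closed_form_value_at_second_breakpoint(self):
        # hand computation: W(68.3) = W(44) + m2 * ln(68.3/44)
        expect = 10.0 + 19.0 * np.log(68.3 / 44.0)
        assert target_W(68.3, self.GT) == pytest.approx(expect, rel=1e-12)

    def test_clipping_at_w_min(self):
        gt = GroundTruth(slopes=(7.0, 19.0, 7.0), breakpoints=(44.0, 68.3),
                         intercept=1.0, w_range=(0.6, 30.0))
        assert target_W(5.0, gt) == pytest.approx(0.6)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(DomainError):
            target_W(0.0, self.GT)


class TestCalibration:
    def test_fisher_z_initializer_within_factor_two_of_monte_carlo(self):
        # near-white noise at 250 Hz: the analytic power heuristic should
        # land within a factor 2 of the simulated W at rho = 0.3
        cfg = SyntheticConfig(n_nodes=2, n_subjects=1, sampling_period=0.004,
                              duration=160.0, noise_band=None, seed=0,
                              max_probed_scale=2.0)
        params = MethodParams(w0=0.04, M=50, n_surrogates=30, surrogate="ft",
                              seed=0)
        cal = calibrate_rho_to_W(cfg, params, rho_grid=[0.3], n_reps=20)
        analytic = fisher_z_W(0.3, 0.004)
        assert analytic == pytest.approx(0.172, abs=0.01)
        assert cal.W_of_rho[0] == pytest.approx(analytic, rel=1.0)  # x2 band

    def test_curve_non_increasing_and_invertible(self):
        cfg = SyntheticConfig.reduced_desk(seed=2, n_nodes=2, n_subjects=1)
        params = MethodParams.reduced(seed=2)
        cal = calibrate_rho_to_W(cfg, params,
                                 rho_grid=[0.1, 0.2, 0.4, 0.7], n_reps=20)
        assert np.all(np.diff(cal.W_of_rho) <= 0)
        # inverse round-trip on the curve's own support
        mid_W = cal.W_of_rho[1]
        rho = cal.rho_for_W(mid_W)
        assert cal.rho_grid[0] <= rho <= cal.rho_grid[-1]

    def test_near_unity_correlation_floors_at_w0(self):
        cfg = SyntheticConfig.reduced_desk(seed=3, n_nodes=2, n_subjects=1)
        params = MethodParams.reduced(seed=3)
        cal = calibrate_rho_to_W(cfg, params, rho_grid=[0.99], n_reps=20)
        assert cal.W_of_rho[0] == pytest.approx(params.w0)

    def test_rho_grid_outside_unit_interval_rejected(self):
        cfg = SyntheticConfig.reduced_desk(seed=0)
        with pytest.raises(DomainError):
            calibrate_rho_to_W(cfg, MethodParams.reduced(), rho_grid=[1.2],
                               n_reps=20)

    def test_effective_sampling_period_band_limited(self):
        assert effective_sampling_period(0.004, None) == 0.004
        assert effective_sampling_period(0.004, (0.5, 45.0)) == \
            pytest.approx(1 / 89.0)
        assert effective_sampling_period(0.04, (0.5, 10.0)) == \
            pytest.approx(1 / 19.0)


class TestGenerateCohort:
    def test_pair_correlation_tracks_requested_rho(self):
        # 2 nodes at a distance whose target W is ~1 s
        gt = GroundTruth(slopes=(7.0, 19.1, 6.7), breakpoints=(44.0, 68.3),
                         intercept=11.9, unlinked_fraction=0.0)
        cfg = SyntheticConfig(n_nodes=2, n_subjects=3, sampling_period=0.01,
                              duration=180.0, noise_band=(0.5, 20.0), seed=4,
                              ground_truth=gt, position_jitter_mm=0.0,
                              max_probed_scale=30.0)
        cal = analytic_calibration(cfg)
        nodes, series, _ = generate_cohort(cfg, calibration=cal)
        d = np.linalg.norm(nodes.positions[0] - nodes.positions[1])
        rho_req = float(cal.rho_for_W(target_W(d, gt)))
        for ts in series:
            r = np.corrcoef(ts.samples[:, 0], ts.samples[:, 1])[0, 1]
            assert r == pytest.approx(rho_req, abs=0.1)

    def test_unlinked_fraction_one_gives_independent_noise(self):
        gt = GroundTruth(unlinked_fraction=1.0)
        cfg = SyntheticConfig(n_nodes=6, n_subjects=1, sampling_period=0.02,
                              duration=150.0, noise_band=(0.5, 10.0), seed=5,
                              ground_truth=gt, max_probed_scale=30.0)
        _, series, _ = generate_cohort(cfg)
        C = np.corrcoef(series[0].samples.T)
        off = C[np.triu_indices(6, k=1)]
        # effective sample count for band-limited noise
        n_eff = cfg.duration / effective_sampling_period(
            cfg.sampling_period, cfg.noise_band)
        assert np.all(np.abs(off) < 3 / np.sqrt(n_eff))

    def test_bit_identical_given_same_seed(self):
        cfg = SyntheticConfig.reduced_desk(seed=6, n_nodes=5, n_subjects=2)
        n1, s1, _ = generate_cohort(cfg)
        n2, s2, _ = generate_cohort(cfg)
        np.testing.assert_array_equal(n1.positions, n2.positions)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_subjects_carry_jittered_geometry(self):
        cfg = SyntheticConfig.reduced_desk(seed=7, n_nodes=5, n_subjects=2)
        nodes, series, _ = generate_cohort(cfg)
        assert series[0].nodes is not None
        assert not np.allclose(series[0].nodes.positions, nodes.positions)
        jit = np.abs(series[0].nodes.positions - nodes.positions)
        assert jit.max() < 15.0  # a few mm of anatomical variability

    def test_realized_correlations_track_targets_on_average(self):
        # mean absolute deviation between sample and requested pairwise
        # correlations stays small at 180 s
        gt = GroundTruth(unlinked_fraction=0.5)
        cfg = SyntheticConfig(n_nodes=12, n_subjects=1, sampling_period=0.02,
                              duration=180.0, noise_band=(0.5, 15.0), seed=8,
                              ground_truth=gt, position_jitter_mm=0.0,
                              max_probed_scale=30.0)
        cal = analytic_calibration(cfg)
        nodes, series, _ = generate_cohort(cfg, calibration=cal)
        iu = np.triu_indices(12, k=1)
        C_emp = np.corrcoef(series[0].samples.T)[iu]
        # reconstruct the requested correlations (same streams as the
        # generator: subject 0 draws jitter then the unlinked subset)
        rng = np.random.default_rng(np.random.SeedSequence((8, 1, 0)))
        rng.normal(0.0, 0.0, size=(12, 3))
        dm = nodes.distance_matrix()[iu]
        rho = cal.rho_for_W(target_W(dm, gt))
        unl = rng.choice(len(rho), size=int(round(0.5 * len(rho))),
                         replace=False)
        rho[unl] = 0.0
        assert np.mean(np.abs(C_emp - rho)) < 0.05


def test_config_requires_duration_much_longer_than_probe():
    with pytest.raises(ValueError, match="5x"):
        SyntheticConfig(duration=100.0, max_probed_scale=30.0)
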