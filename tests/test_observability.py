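"""Window grid, windowed Pearson diagrams, surrogates, efficiency and W."""

import numpy as np
import pytest

from obscor.errors import SequenceTooShortError
from obscor.io import NodeTable, TimeSeriesSet
from obscor.observability import (assess_links, build_window_grid, efficiency,
                                  make_surrogate, observability_from_pair,
                                  observability_timescale, pvalue_diagram,
                                  windowed_pearson, EfficiencyCurve,
                                  PValueDiagram)
from obscor.params import MethodParams


class TestWindowGrid:
    def test_standard_grid_numbers(self):
        # 240 s at 250 Hz with the default multiscale grid
        g = build_window_grid(60000, 0.004, w0=0.2, M=150)
        assert g.n_centers == 1051
        assert g.widths[0] == pytest.approx(0.2)
        assert g.widths[-1] == pytest.approx(30.0)
        assert g.centers[0] == pytest.approx(15.0)
        assert g.centers[-1] == pytest.approx(225.0)
        assert g.w0_samples == 50  # 50 samples in the 0.2 s window

    def test_single_width_grid(self):
        g = build_window_grid(100, 0.1, w0=1.0, M=1)
        assert g.centers[0] == pytest.approx(0.5)
        assert np.allclose(np.diff(g.centers), 1.0)

    def test_exact_fit_gives_single_center(self):
        g = build_window_grid(1000, 0.1, w0=10.0, M=10)
        assert g.n_centers == 1
        assert g.centers[0] == pytest.approx(50.0)

    def test_too_short_sequence_raises(self):
        with pytest.raises(SequenceTooShortError):
            build_window_grid(999, 0.1, w0=10.0, M=10)

    def test_centers_shared_across_widths(self):
        g = build_window_grid(5000, 0.004, 0.2, 20)
        for m in (1, 10, 20):
            off, length = g.window_bounds(m)
            # window midpoint equals the center for every width
            mid = (off + length / 2) * g.sampling_period
            assert mid == pytest.approx(g.centers[0], abs=g.sampling_period)


class TestWindowedPearson:
    def test_identical_series_give_unity(self, rng):
        x = rng.standard_normal(1000)
        g = build_window_grid(1000, 0.004, 0.2, 5)
        d = windowed_pearson(x, x, g)
        np.testing.assert_allclose(d.values, 1.0)

    def test_negative_affine_gives_minus_one(self, rng):
        x = rng.standard_normal(1000)
        g = build_window_grid(1000, 0.004, 0.2, 5)
        d = windowed_pearson(x, -2.0 * x + 3.0, g)
        np.testing.assert_allclose(d.values, -1.0)

    def test_four_point_window_matches_hand_value(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        g = build_window_grid(4, 1.0, w0=2.0, M=2)
        d = windowed_pearson(x, y, g)
        assert d.values[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_agrees_with_naive_loop(self, rng):
        x = rng.standard_normal(2500)
        y = rng.standard_normal(2500)
        g = build_window_grid(2500, 0.004, 0.2, 10)
        d = windowed_pearson(x, y, g)
        for m in range(1, g.M + 1):
            for k in range(0, g.n_centers, 17):
                sl = g.window_slice(m, k)
                expect = np.corrcoef(x[sl], y[sl])[0, 1]
                assert d.values[k, m - 1] == pytest.approx(expect, abs=1e-12)

    def test_constant_window_recorded_as_missing(self, rng):
        x = rng.standard_normal(400)
        y = np.ones(400)
        g = build_window_grid(400, 0.004, 0.2, 2)
        d = windowed_pearson(x, y, g)
        assert np.isnan(d.values).all()


class TestSurrogates:
    @pytest.mark.parametrize("method", ["ft", "aaft", "iaaft"])
    def test_deterministic_given_seed(self, rng, method):
        x = rng.standard_normal(256)
        s1 = make_surrogate(x, seed=7, method=method)
        s2 = make_surrogate(x, seed=7, method=method)
        np.testing.assert_array_equal(s1, s2)

    def test_ft_preserves_periodogram(self, rng):
        x = rng.standard_normal(512)
        s = make_surrogate(x, seed=1, method="ft")
        np.testing.assert_allclose(np.abs(np.fft.rfft(s)),
                                   np.abs(np.fft.rfft(x)), rtol=1e-5)

    def test_iaaft_preserves_amplitude_distribution(self, rng):
        x = rng.standard_normal(512) ** 3  # strongly non-Gaussian
        s = make_surrogate(x, seed=1, method="iaaft")
        np.testing.assert_allclose(np.sort(s), np.sort(x))

    def test_aaft_preserves_amplitude_distribution(self, rng):
        x = np.exp(rng.standard_normal(512))
        s = make_surrogate(x, seed=1, method="aaft")
        np.testing.assert_allclose(np.sort(s), np.sort(x))

    def test_surrogate_decorrelates_from_original(self, rng):
        # lag-0 correlation with the original, averaged over seeds
        x = np.cumsum(rng.standard_normal(512))  # autocorrelated
        x -= x.mean()
        cors = [np.corrcoef(x, make_surrogate(x, seed=s, method="ft"))[0, 1]
                for s in range(100)]
        assert abs(np.mean(cors)) < 0.05


class TestPValueDiagram:
    def test_identical_autocorrelated_series_attain_floor(self, rng):
        t = np.arange(1500) * 0.004
        x = np.sin(2 * np.pi * 1.3 * t) + 0.1 * rng.standard_normal(1500)
        g = build_window_grid(1500, 0.004, 0.2, 5)
        p = pvalue_diagram(x, x, g, n_surrogates=200, seed=0, method="ft")
        np.testing.assert_allclose(p.values, 1 / 201)

    def test_minimum_p_with_19_surrogates(self, rng):
        x = rng.standard_normal(600)
        g = build_window_grid(600, 0.004, 0.2, 3)
        p = pvalue_diagram(x, x, g, n_surrogates=19, seed=0, method="ft")
        assert np.nanmin(p.values) == pytest.approx(0.05)

    def test_independent_pair_has_uniform_p(self, rng):
        # mean p over >= 1e4 cells should sit near 0.5 under the null
        x = rng.standard_normal(26000)
        y = rng.standard_normal(26000)
        g = build_window_grid(26000, 0.004, 0.2, 25)
        p = pvalue_diagram(x, y, g, n_surrogates=99, seed=1, method="ft")
        assert p.values.size >= 1e4
        assert np.nanmean(p.values) == pytest.approx(0.5, abs=0.05)


class TestEfficiencyAndW:
    def _curve(self, eta):
        return EfficiencyCurve(eta=np.asarray(eta, float),
                               widths=0.2 * np.arange(1, len(eta) + 1),
                               alpha=0.05)

    def test_efficiency_counts_significant_centers(self):
        g = build_window_grid(600, 0.004, 0.2, 3)
        vals = np.ones((g.n_centers, 3))
        vals[: g.n_centers // 2, 1] = 0.01
        p = PValueDiagram(values=vals, grid=g, n_surrogates=200,
                          surrogate_method="ft")
        eta = efficiency(p, alpha=0.05)
        assert eta.eta[0] == 0.0
        assert eta.eta[1] == pytest.approx((g.n_centers // 2) / g.n_centers)

    def test_all_floor_p_gives_full_efficiency(self):
        g = build_window_grid(600, 0.004, 0.2, 3)
        p = PValueDiagram(np.full((g.n_centers, 3), 1 / 201), g, 200, "ft")
        assert np.all(efficiency(p).eta == 1.0)

    def test_crossing_at_first_width_above_half(self):
        assert observability_timescale(
            self._curve([0.1, 0.4, 0.62, 0.9])) == pytest.approx(0.6)

    def test_tie_at_threshold_does_not_qualify(self):
        assert observability_timescale(self._curve([0.5, 0.5])) is None
        assert observability_timescale(self._curve([0.5, 0.5]),
                                       strict=False) == pytest.approx(0.2)

    def test_no_crossing_means_no_link(self):
        assert observability_timescale(self._curve([0.0, 0.2, 0.49])) is None

    def test_everywhere_one_gives_smallest_width(self):
        assert observability_timescale(self._curve([1.0, 1.0])) == \
            pytest.approx(0.2)


class TestFastPathConsistency:
    def test_fast_scan_equals_full_chain(self, rng):
        params = MethodParams(w0=0.2, M=10, n_surrogates=30,
                              surrogate="ft", seed=0)
        g = build_window_grid(2500, 0.004, params.w0, params.M)
        z = rng.standard_normal(2500)
        for i, rho in enumerate([0.0, 0.2, 0.5]):
            e1 = rng.standard_normal(2500)
            e2 = rng.standard_normal(2500)
            x = np.sqrt(rho) * z + np.sqrt(1 - rho) * e1
            y = np.sqrt(rho) * z + np.sqrt(1 - rho) * e2
            w_fast = observability_from_pair(x, y, g, params, seed=100 + i)
            p = pvalue_diagram(x, y, g, n_surrogates=params.n_surrogates,
                               seed=100 + i, method=params.surrogate)
            w_chain = observability_timescale(efficiency(p, params.alpha),
                                              params.eta_threshold)
            assert w_fast == w_chain

    def test_affine_rescaling_invariance(self, rng):
        params = MethodParams(w0=0.2, M=8, n_surrogates=25, surrogate="ft",
                              seed=3)
        g = build_window_grid(2000, 0.004, params.w0, params.M)
        z = rng.standard_normal(2000)
        x = z + 0.7 * rng.standard_normal(2000)
        y = z + 0.7 * rng.standard_normal(2000)
        w1 = observability_from_pair(x, y, g, params, seed=9)
        w2 = observability_from_pair(5.0 * x - 2.0, -0.3 * y + 11.0, g,
                                     params, seed=9)
        assert w1 == w2


def test_W_independent_of_sequence_length():
    """For a fixed generating correlation, the median W from 120 s and
    240 s inputs agrees within one width-grid step."""
    params = MethodParams.reduced(seed=0)
    rho = 0.3
    medians = {}
    for dur in (120.0, 240.0):
        N = int(dur / 0.02)
        grid = build_window_grid(N, 0.02, params.w0, params.M)
        ws = []
        for rep in range(25):
            r = np.random.default_rng((int(dur), rep))
            z = r.standard_normal(N)
            x = np.sqrt(rho) * z + np.sqrt(1 - rho) * r.standard_normal(N)
            y = np.sqrt(rho) * z + np.sqrt(1 - rho) * r.standard_normal(N)
            w = observability_from_pair(x, y, grid, params, seed=(9, rep))
            ws.append(np.inf if w is None else w)
        medians[dur] = np.median(ws)
    assert abs(medians[120.0] - medians[240.0]) < params.w0 + 1e-9


class TestAssessLinks:
    def _series(self, rng, nodes, n=1500, T=0.004):
        z = rng.standard_normal(n)
        cols = np.column_stack([z + 0.5 * rng.standard_normal(n)
                                for _ in range(len(nodes))])
        return TimeSeriesSet("s1", T, list(nodes.node_ids), cols)

    def test_one_record_per_unordered_pair(self, rng, tiny_nodes):
        ts = self._series(rng, tiny_nodes)
        params = MethodParams(w0=0.2, M=5, n_surrogates=20, surrogate="ft",
                              seed=0)
        recs = assess_links(ts, tiny_nodes, params)
        assert len(recs) == 3
        assert {(r.node_a, r.node_b) for r in recs} == \
            {("L1", "L2"), ("L1", "R1"), ("L2", "R1")}
        assert {r.hemisphere_pair for r in recs} == {"LL", "LR"}
        d = {(r.node_a, r.node_b): r.d for r in recs}
        assert d[("L1", "L2")] == pytest.approx(40.0)
        assert d[("L1", "R1")] == pytest.approx(60.0)

    def test_identical_columns_link_at_smallest_width(self, rng, tiny_nodes):
        n = 1500
        z = np.cumsum(rng.standard_normal(n))
        ts = TimeSeriesSet("s", 0.004, ["L1", "L2"],
                           np.column_stack([z, z]))
        params = MethodParams(w0=0.2, M=5, n_surrogates=20, surrogate="ft",
                              seed=0)
        recs = assess_links(ts, tiny_nodes.subset(["L1", "L2"]), params)
        assert recs[0].W == pytest.approx(params.w0)

    def test_node_order_does_not_change_records(self, rng, tiny_nodes):
        ts = self._series(rng, tiny_nodes)
        params = MethodParams(w0=0.2, M=5, n_surrogates=20, surrogate="ft",
                              seed=4)
        rev = TimeSeriesSet("s1", ts.sampling_period,
                            list(reversed(ts.node_ids)),
                            ts.samples[:, ::-1])
        a = assess_links(ts, tiny_nodes, params)
        b = assess_links(rev, tiny_nodes, params)
        assert [(r.node_a, r.node_b, r.W) for r in a] == \
            [(r.node_a, r.node_b, r.W) for r in b]
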