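"""Synchronized ensembles, contour grids, and the OLS regression."""

import numpy as np
import pytest

from slipfret import FretTrace, SyncRule, contour, linear_fit, \
    post_sync_histogram, synchronize
from slipfret.inference import Dwell, IdealizedTrace


def step_pair(n_pre, n_post, hi=0.8, lo=0.2, dt=0.033):
    values = np.r_[np.full(n_pre, hi), np.full(n_post, lo)]
    ft = FretTrace(values, np.ones(values.size, bool), dt,
                   truncation_frame=values.size)
    ideal = IdealizedTrace([Dwell("hi", 0, n_pre, hi),
                            Dwell("lo", n_pre, n_post, lo)], dt,
                           values.size)
    return ideal, ft


class TestSynchronize:
    def test_offset_zero_is_the_sync_event(self):
        ideal, ft = step_pair(100, 50)
        sync = synchronize([ideal], [ft], SyncRule("first_below", 0.5))
        col0 = np.flatnonzero(sync.offsets == 0)[0]
        assert sync.aligned[0, col0] == pytest.approx(0.2)
        assert sync.aligned[0, col0 - 1] == pytest.approx(0.8)

    def test_last_entry_rule(self):
        dt = 0.033
        values = np.r_[np.full(30, 0.8), np.full(30, 0.5), np.full(30, 0.8),
                       np.full(60, 0.5)]
        ft = FretTrace(values, np.ones(values.size, bool), dt,
                       truncation_frame=values.size)
        ideal = IdealizedTrace(
            [Dwell("S", 0, 30, 0.8), Dwell("N", 30, 30, 0.5),
             Dwell("S", 60, 30, 0.8), Dwell("N", 90, 60, 0.5)], dt, 150)
        sync = synchronize([ideal], [ft], SyncRule("last_entry", "S"))
        col0 = np.flatnonzero(sync.offsets == 0)[0]
        assert sync.aligned[0, col0] == pytest.approx(0.8)
        assert sync.aligned[0, col0 + 30] == pytest.approx(0.5)

    def test_order_invariance(self):
        pairs = [step_pair(80, 40), step_pair(120, 30), step_pair(60, 90)]
        rule = SyncRule("first_below", 0.5)
        fwd = synchronize([p[0] for p in pairs], [p[1] for p in pairs], rule)
        rev = synchronize([p[0] for p in pairs[::-1]],
                          [p[1] for p in pairs[::-1]], rule)
        np.testing.assert_array_equal(np.sort(fwd.aligned, axis=0),
                                      np.sort(rev.aligned, axis=0))

    def test_no_qualifying_trace_is_an_error(self):
        values = np.full(50, 0.8)
        ft = FretTrace(values, np.ones(50, bool), 0.033, truncation_frame=50)
        ideal = IdealizedTrace([Dwell("hi", 0, 50, 0.8)], 0.033, 50)
        with pytest.raises(ValueError):
            synchronize([ideal], [ft], SyncRule("first_below", 0.5))


class TestContour:
    def test_step_ensemble_has_two_ridges(self):
        pairs = [step_pair(100, 100) for _ in range(10)]
        sync = synchronize([p[0] for p in pairs], [p[1] for p in pairs],
                           SyncRule("first_below", 0.5))
        grid, t, edges = contour(sync, (-1.0, 1.0))
        centers = 0.5 * (edges[:-1] + edges[1:])
        pre_cols = t < 0
        assert centers[np.argmax(grid[:, pre_cols].sum(axis=1))] == \
            pytest.approx(0.8, abs=0.02)
        assert centers[np.argmax(grid[:, ~pre_cols].sum(axis=1))] == \
            pytest.approx(0.2, abs=0.02)

    def test_column_mass_conservation(self):
        pairs = [step_pair(80, 40), step_pair(30, 120), step_pair(50, 60)]
        sync = synchronize([p[0] for p in pairs], [p[1] for p in pairs],
                           SyncRule("first_below", 0.5))
        grid, t, _ = contour(sync, (-3.0, 3.0))
        cols = np.flatnonzero((sync.offsets * 0.033 >= -3.0) &
                              (sync.offsets * 0.033 < 3.0))
        for j, c in enumerate(cols):
            present = np.isfinite(sync.aligned[:, c]).sum()
            assert grid[:, j].sum() == pytest.approx(
                present / sync.n_included, abs=1e-12)

    def test_empty_time_range_is_an_error(self):
        ideal, ft = step_pair(50, 50)
        sync = synchronize([ideal], [ft], SyncRule("first_below", 0.5))
        with pytest.raises(ValueError):
            contour(sync, (100.0, 101.0))


class TestPostSyncHistogram:
    def test_matches_pooled_when_synced_at_zero(self):
        from slipfret import pooled_histogram
        values = np.r_[np.full(40, 0.4), np.full(60, 0.2)]
        ft = FretTrace(values, np.ones(100, bool), 0.033,
                       truncation_frame=100)
        ideal = IdealizedTrace([Dwell("c", 0, 40, 0.4),
                                Dwell("p", 40, 60, 0.2)], 0.033, 100)
        sync = synchronize([ideal], [ft], SyncRule("first_below", 0.5))
        h_sync = post_sync_histogram(sync)
        h_pool = pooled_histogram([ft])
        np.testing.assert_array_equal(h_sync.counts, h_pool.counts)

    def test_bimodal_after_sync(self):
        pairs = [step_pair(50, 100, hi=0.8, lo=0.2) for _ in range(5)]
        sync = synchronize([p[0] for p in pairs], [p[1] for p in pairs],
                           SyncRule("first_below", 0.5))
        h = post_sync_histogram(sync)
        centers = h.centers[h.counts > 0]
        assert np.any(np.abs(centers - 0.2) < 0.02)


class TestLinearFit:
    def test_identity_line(self):
        r = linear_fit([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        assert r.slope == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(0, 1, rng.integers(3, 9))
            y = rng.uniform(0, 1, x.size)
            r = linear_fit(x, y)
            xc = x - x.mean()
            slope = float(np.dot(xc, y) / np.dot(xc, xc))
            intercept = float(y.mean() - slope * x.mean())
            assert r.slope == pytest.approx(slope, abs=1e-12)
            assert r.intercept == pytest.approx(intercept, abs=1e-12)

    def test_frameshifting_efficiency_regression(self):
        # slow-mode fraction vs frameshifting efficiency, slope near 1.3
        rng = np.random.default_rng(1)
        x = np.array([0.19, 0.35, 0.55, 0.85])
        y = 1.3 * x + rng.normal(0, 0.005, 4)
        r = linear_fit(x, y)
        assert r.slope == pytest.approx(1.3, abs=0.1)
        assert r.r_squared > 0.99

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([0.1, 0.2], [0.1, 0.2])
        with pytest.raises(ValueError):
            linear_fit([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])
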