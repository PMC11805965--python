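"""Brownian-bridge UDs, contours, centroids, movement rates, LDMs, habitat."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reeftrack.spaceuse import (
    CELL_M, Centroid, IneligibleFishError, UdGrid, centroid_occupancy, contour,
    daily_ud, detect_ldm, detect_shifts, estimate_motion_variance, find_centroids,
    movement_rates, rank_correlation, tracking_ud,
)
from reeftrack.io import HabitatMap
from reeftrack.spaceuse import assign_habitat
from shapely.geometry import box


def _positions(times, xs, ys, tag="F1"):
    return pd.DataFrame({"tag_id": tag,
                         "timestamp": pd.to_datetime(times, utc=True),
                         "x_m": xs, "y_m": ys})


def _gaussian_grid(sd=30.0, cell=5.0, half=300.0):
    xs = np.arange(-half, half, cell) + cell / 2
    X, Y = np.meshgrid(xs, xs)
    d = np.exp(-(X ** 2 + Y ** 2) / (2 * sd ** 2)) / (2 * np.pi * sd ** 2)
    ud = UdGrid(origin=(-half, -half), cell_m=cell, density=d, scale="daily")
    return ud.normalize()


class TestContour:
    def test_uniform_density_area(self):
        n = 40
        d = np.full((n, n), 1.0)
        ud = UdGrid(origin=(0, 0), cell_m=10.0, density=d, scale="daily").normalize()
        c = contour(ud, 0.95)
        assert c.area_m2 == np.ceil(0.95 * n * n) * 100.0

    def test_monotone_density_top_k(self):
        d = np.arange(1.0, 26.0).reshape(5, 5)
        ud = UdGrid(origin=(0, 0), cell_m=10.0, density=d, scale="daily").normalize()
        c = contour(ud, 0.5)
        # selected cells are exactly the top-k by density
        thresh = ud.density[c.mask].min()
        assert (ud.density[~c.mask] < thresh + 1e-15).all()

    def test_gaussian_chi2_closed_forms(self):
        """On an exactly Gaussian density the isopleth areas follow the
        chi-square(2 df) quantiles: area_p = -2 ln(1-p) pi sd^2."""
        sd = 30.0
        ud = _gaussian_grid(sd=sd, cell=5.0)
        a95 = contour(ud, 0.95).area_m2
        a50 = contour(ud, 0.50).area_m2
        assert a95 == pytest.approx(-2 * np.log(0.05) * np.pi * sd ** 2, rel=0.03)
        assert a95 / a50 == pytest.approx(np.log(0.05) / np.log(0.5), rel=0.05)

    def test_bad_level(self):
        ud = _gaussian_grid()
        with pytest.raises(ValueError):
            contour(ud, 1.5)


class TestDailyUd:
    def test_integrates_to_one(self):
        ts = pd.date_range("2021-01-01", periods=6, freq="20min", tz="UTC")
        pos = _positions(ts, 500 + 30 * np.arange(6), 500 + 10 * np.arange(6))
        ud = daily_ud(pos, sigma_m2=0.05, error_sd=20.0)
        assert ud.total_mass() == pytest.approx(1.0, abs=1e-9)

    def test_identical_points_mixture_closed_form(self):
        """Two identical positions with sigma_m -> 0: the bridge kernel is a
        scale mixture of Gaussians with variance ((1-a)^2 + a^2) delta^2.
        The 95% area of that mixture (numerical oracle) is ~0.68x the naive
        single-Gaussian chi-square area."""
        err = 20.0
        ts = ["2021-01-01T00:00:00Z", "2021-01-01T00:30:00Z"]
        pos = _positions(ts, [500.0, 500.0], [500.0, 500.0])
        ud = daily_ud(pos, sigma_m2=1e-12, error_sd=err, cell_m=2.5)
        a95 = contour(ud, 0.95).area_m2

        # oracle: radial mixture density integrated on rings
        alphas = (np.arange(10) + 0.5) / 10
        variances = ((1 - alphas) ** 2 + alphas ** 2) * err ** 2
        r = np.linspace(0, 120, 4000)
        dens = np.mean([np.exp(-r**2 / (2 * v)) / (2 * np.pi * v)
                        for v in variances], axis=0)
        pdf_r = 2 * np.pi * r * dens
        cdf = np.cumsum(pdf_r) * (r[1] - r[0])
        r95 = r[np.searchsorted(cdf, 0.95)]
        assert a95 == pytest.approx(np.pi * r95 ** 2, rel=0.05)

    def test_time_weights_scale_invariant(self):
        ts1 = pd.date_range("2021-01-01", periods=4, freq="10min", tz="UTC")
        ts2 = pd.date_range("2021-01-01", periods=4, freq="20min", tz="UTC")
        xs, ys = [100, 160, 100, 40.0], [0, 40, 80, 40.0]
        grid = (-200.0, -200.0, 60, 60)
        u1 = daily_ud(_positions(ts1, xs, ys), 0.0, 20.0, grid=grid)
        u2 = daily_ud(_positions(ts2, xs, ys), 0.0, 20.0, grid=grid)
        # doubling every interval rescales weights uniformly -> same UD
        np.testing.assert_allclose(u1.density, u2.density, atol=1e-12)

    def test_no_eligible_pair_returns_none(self):
        ts = ["2021-01-01T00:00:00Z", "2021-01-01T03:00:00Z"]  # gap > 60 min
        assert daily_ud(_positions(ts, [0, 10.0], [0, 0.0]), 0.1, 20.0) is None

    def test_matches_monte_carlo_bridge_oracle(self, rng):
        """Quadrature UD equals dense Monte-Carlo bridge sampling within 2%
        total variation on random position pairs."""
        for trial in range(5):
            x0, y0 = rng.uniform(200, 800, 2)
            x1, y1 = x0 + rng.uniform(-150, 150), y0 + rng.uniform(-150, 150)
            T = rng.uniform(600, 3000)
            s2, err = rng.uniform(0.01, 0.2), rng.uniform(10, 25)
            ts = pd.to_datetime([0, T], unit="s", utc=True)
            ud = daily_ud(_positions(ts, [x0, x1], [y0, y1]), s2, err,
                          cell_m=10.0, n_quad=50)
            n = 4_000_000
            a = rng.random(n)
            var = a * (1 - a) * T * s2 + ((1 - a) ** 2 + a ** 2) * err ** 2
            mx = (1 - a) * x0 + a * x1 + rng.normal(0, 1, n) * np.sqrt(var)
            my = (1 - a) * y0 + a * y1 + rng.normal(0, 1, n) * np.sqrt(var)
            gx0, gy0 = ud.origin
            ny, nx = ud.density.shape
            ii = np.floor((mx - gx0) / 10.0).astype(int)
            jj = np.floor((my - gy0) / 10.0).astype(int)
            ok = (ii >= 0) & (ii < nx) & (jj >= 0) & (jj < ny)
            hist = np.bincount(jj[ok] * nx + ii[ok], minlength=nx * ny) / n
            tv = 0.5 * np.abs(hist - ud.density.ravel() * 100.0).sum()
            assert tv < 0.02


class TestTrackingUd:
    def _stack_of_days(self, n_days, shift=0.0):
        uds = []
        base = pd.Timestamp("2021-01-01", tz="UTC")
        for d in range(n_days):
            ts = pd.date_range(base + pd.Timedelta(days=d), periods=4,
                               freq="15min")
            xs = 500 + shift * (d >= n_days // 2) + np.array([0, 20, 40, 20.0])
            ys = 500 + np.array([0, 10, 0, -10.0])
            uds.append(daily_ud(_positions(ts, xs, ys), 0.02, 20.0))
        return uds

    def test_identical_days_equal_daily_ud(self):
        uds = []
        for d in range(35):
            ts = pd.date_range(f"2021-01-01 0{d % 9}:00", periods=3,
                               freq="15min", tz="UTC")
            uds.append(daily_ud(_positions(ts, [500, 520, 540.0], [500, 500, 500.0]),
                                0.02, 20.0, grid=(300.0, 300.0, 45, 45)))
        td = tracking_ud(uds, min_ud_days=33)
        np.testing.assert_allclose(td.density, uds[0].density, atol=1e-12)

    def test_too_few_ud_days_excluded(self):
        uds = self._stack_of_days(32)
        with pytest.raises(IneligibleFishError, match="32"):
            tracking_ud(uds, min_ud_days=33)

    def test_low_daily_positions_excluded(self):
        uds = self._stack_of_days(35)
        with pytest.raises(IneligibleFishError, match="daily positions"):
            tracking_ud(uds, min_ud_days=33, daily_position_counts=[4] * 35)

    def test_disjoint_half_ranges_add_areas(self):
        uds = self._stack_of_days(40, shift=3000.0)
        td = tracking_ud(uds, min_ud_days=33)
        a_td = contour(td, 0.95).area_m2
        a_half = contour(tracking_ud(uds[:20], min_ud_days=1), 0.95).area_m2
        a_half2 = contour(tracking_ud(uds[20:], min_ud_days=1), 0.95).area_m2
        assert a_td == pytest.approx(a_half + a_half2, rel=0.15)

    def test_daily_median_below_tracking_duration(self):
        uds = self._stack_of_days(40, shift=200.0)
        td = tracking_ud(uds, min_ud_days=33)
        daily_areas = [contour(u, 0.95).area_m2 for u in uds]
        assert np.median(daily_areas) <= contour(td, 0.95).area_m2


class TestCentroidsAndShifts:
    def _mk(self, centers, n_days_each, start_day=1):
        """One daily-position frame + UD per (center, day-range) block."""
        uds, rows = [], []
        day = start_day
        for (cx, cy), nd in zip(centers, n_days_each):
            for _ in range(nd):
                ts = pd.Timestamp("2021-01-01", tz="UTC") + pd.Timedelta(days=day)
                tss = [ts + pd.Timedelta(minutes=15 * i) for i in range(4)]
                xs = cx + np.array([0, 15, 30, 15.0])
                ys = cy + np.array([0, 10, 0, -10.0])
                uds.append(daily_ud(_positions(tss, xs, ys), 0.02, 15.0))
                rows.append(_positions(tss, xs, ys))
                day += 1
        return uds, pd.concat(rows, ignore_index=True)

    def test_single_home_range_one_centroid_no_shift(self):
        uds, posn = self._mk([(500, 500)], [40])
        td = tracking_ud(uds, min_ud_days=33)
        cents = find_centroids(td)
        assert len(cents) == 1
        centroid_occupancy(cents, td, posn)
        assert detect_shifts(cents) == []

    def test_hard_shift_two_centroids_one_shift(self):
        uds, posn = self._mk([(500, 500), (3500, 500)], [20, 20])
        td = tracking_ud(uds, min_ud_days=33)
        cents = find_centroids(td)
        assert len(cents) == 2
        centroid_occupancy(cents, td, posn)
        shifts = detect_shifts(cents)
        assert len(shifts) == 1

    def test_alternating_use_no_shift(self):
        uds, posn = self._mk([(500, 500), (3500, 500), (500, 500), (3500, 500)],
                             [10, 10, 10, 10])
        td = tracking_ud(uds, min_ud_days=33)
        cents = find_centroids(td)
        assert len(cents) == 2
        centroid_occupancy(cents, td, posn)
        assert detect_shifts(cents) == []  # temporal overlap: no clean shift


class TestMovementRates:
    def test_rate_and_corrected_rate(self):
        ts = ["2021-01-01T00:00:00Z", "2021-01-01T00:00:50Z"]
        mr = movement_rates(_positions(ts, [0.0, 100.0], [0.0, 0.0]),
                            error_threshold_m=20.0)
        assert mr.rate_mps.iloc[0] == pytest.approx(2.0)
        assert mr.corrected_rate_mps.iloc[0] == pytest.approx(1.2)

    def test_corrected_rate_floored_at_zero(self):
        ts = ["2021-01-01T00:00:00Z", "2021-01-01T00:00:50Z"]
        mr = movement_rates(_positions(ts, [0.0, 30.0], [0.0, 0.0]),
                            error_threshold_m=20.0)
        assert mr.corrected_rate_mps.iloc[0] == 0.0

    def test_predator_speed_flaggable(self):
        ts = pd.date_range("2021-01-01", periods=3, freq="100s", tz="UTC")
        mr = movement_rates(_positions(ts, [0.0, 120.0, 130.0], [0.0, 0.0, 0.0]))
        assert ((mr.corrected_rate_mps > 0.75).sum()) == 1

    def test_zero_interval_skipped_with_warning(self):
        ts = ["2021-01-01T00:00:00Z"] * 2
        with pytest.warns(UserWarning, match="zero-interval"):
            mr = movement_rates(_positions(ts, [0.0, 10.0], [0.0, 0.0]))
        assert mr.empty


class TestLdm:
    def test_simple_ldm(self):
        ts = ["2021-01-01T00:00:00Z", "2021-01-02T00:00:00Z"]
        out = detect_ldm(_positions(ts, [0.0, 2500.0], [0.0, 0.0]))
        assert len(out) == 1
        assert out.max_distance_m.iloc[0] == pytest.approx(2500.0)

    def test_outside_window_not_ldm(self):
        ts = ["2021-01-01T00:00:00Z", "2021-01-04T00:00:00Z"]  # 72 h
        assert detect_ldm(_positions(ts, [0.0, 2500.0], [0.0, 0.0])).empty

    def test_round_trip_merges_into_two_events(self):
        """Out-and-back traverses separated by a quiet week: two events."""
        t0 = pd.Timestamp("2021-01-01", tz="UTC")
        rows = []
        # leg 1: out and back within 24 h
        for i, x in enumerate([0, 3000, 0.0]):
            rows.append((t0 + pd.Timedelta(hours=8 * i), x))
        # quiet residency
        for d in range(3, 10):
            rows.append((t0 + pd.Timedelta(days=d), 50.0))
        # leg 2
        for i, x in enumerate([0, 3000, 0.0]):
            rows.append((t0 + pd.Timedelta(days=12, hours=8 * i), x))
        pos = _positions([r[0] for r in rows], [r[1] for r in rows],
                         [0.0] * len(rows))
        out = detect_ldm(pos)
        assert len(out) == 2

    def test_sub_threshold_distance_ignored(self):
        ts = ["2021-01-01T00:00:00Z", "2021-01-01T12:00:00Z"]
        assert detect_ldm(_positions(ts, [0.0, 1900.0], [0.0, 0.0])).empty


class TestHabitat:
    HM = HabitatMap({"AR": box(0, 0, 30, 30), "HB": box(100, 100, 700, 700)})

    def test_point_in_polygon(self):
        pts = pd.DataFrame({"x_m": [10.0, 300.0, 900.0], "y_m": [10.0, 300.0, 50.0]})
        labels = assign_habitat(pts, self.HM)
        assert list(labels) == ["AR", "HB", "sand"]

    def test_far_outside_warns_sand(self):
        pts = pd.DataFrame({"x_m": [99_999.0], "y_m": [99_999.0]})
        with pytest.warns(UserWarning, match="sand"):
            labels = assign_habitat(pts, self.HM)
        assert labels.iloc[0] == "sand"


class TestRankCorrelation:
    def test_perfect_monotone(self):
        rho, _ = rank_correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_small_sample_oracle_value(self):
        # rank formula: sum d^2 = 10 -> rho = 1 - 60/60 = 0
        rho, p = rank_correlation([1, 2, 3, 4], [3, 1, 4, 2])
        assert rho == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_exact_permutation_matches_scipy_exact(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        rho, p = rank_correlation(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)

    def test_large_sample_uses_approximation(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        rho, p = rank_correlation(x, y)
        ref = stats.spearmanr(x, y)
        assert p == pytest.approx(ref.pvalue)


def test_motion_variance_recovers_brownian_scale(rng):
    """Positions from a true Brownian path with known diffusion and
    location error: the leave-one-out estimate lands near truth."""
    s2_true, err = 0.15, 10.0
    n = 1500
    dt = 300.0
    steps = rng.normal(0, np.sqrt(s2_true * dt), (n, 2))
    path = np.cumsum(steps, axis=0) + 5000
    obs = path + rng.normal(0, err, (n, 2))
    pos = _positions(pd.to_datetime(np.arange(n) * dt, unit="s", utc=True),
                     obs[:, 0], obs[:, 1])
    s2_hat = estimate_motion_variance(pos, err)
    assert s2_hat == pytest.approx(s2_true, rel=0.25)
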