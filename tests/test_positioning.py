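"""Position-error calibration, filtering, range estimation, COAs, RI."""

import numpy as np
import pandas as pd
import pytest

import reeftrack as rt
from reeftrack.positioning import (
    CalibrationError, PositionErrorModel, SeparationError, compute_2drms_bins,
    compute_coas, detection_gaps, estimate_range, remove_spurious_detections,
    residence_index,
)
from reeftrack.synthetic import SimConfig, simulate_calibration_positions, simulate_range_trials
from conftest import make_config


def _calib_frame(errors_xy, hpes, known=(0.0, 0.0)):
    n = len(errors_xy)
    return pd.DataFrame({
        "tag_id": "SYNC",
        "timestamp": pd.date_range("2021-01-01", periods=n, freq="10min", tz="UTC"),
        "x_m": [known[0] + e[0] for e in errors_xy],
        "y_m": [known[1] + e[1] for e in errors_xy],
        "hpe": hpes,
        "known_x_m": known[0], "known_y_m": known[1],
    })


class Test2drms:
    def test_zero_errors_zero_2drms(self):
        df = _calib_frame([(0, 0)] * 10, np.linspace(0.5, 4.5, 10))
        bins = compute_2drms_bins(df, hpe_censor_quantile=1.0)
        assert (bins["twodrms_m"] == 0).all()

    def test_hand_worked_bin(self):
        # one bin holding errors (3,4) and (4,3): 2*sqrt((25+25)/2) = 10 m
        df = _calib_frame([(3, 4), (4, 3)], [1.2, 1.7])
        bins = compute_2drms_bins(df, hpe_censor_quantile=1.0)
        assert len(bins) == 1
        assert bins["twodrms_m"].iloc[0] == pytest.approx(10.0)

    def test_homogeneity(self, rng):
        errs = rng.normal(0, 3, (200, 2))
        hpes = rng.uniform(0, 5, 200)
        b1 = compute_2drms_bins(_calib_frame([tuple(e) for e in errs], hpes))
        b3 = compute_2drms_bins(_calib_frame([tuple(3 * e) for e in errs], hpes))
        np.testing.assert_allclose(3 * b1["twodrms_m"], b3["twodrms_m"])

    def test_upper_hpe_tail_censored(self, rng):
        hpes = np.concatenate([rng.uniform(0, 5, 950), rng.uniform(50, 60, 50)])
        errs = [(0.0, 0.0)] * 1000
        bins = compute_2drms_bins(_calib_frame(errs, hpes))
        assert bins["hpe_bin"].max() < 50

    def test_no_calibration_records_errors(self):
        empty = _calib_frame([], [])
        empty[["known_x_m", "known_y_m"]] = np.nan
        with pytest.raises(CalibrationError):
            compute_2drms_bins(empty)


class TestErrorModelFit:
    def test_slope_recovers_isotropic_error_scale(self):
        """Isotropic Gaussian error of SD a*HPE gives E[2DRMS] = 2*sqrt(2)*a*HPE."""
        cfg = SimConfig(seed=5)
        calib = simulate_calibration_positions(cfg, 20_000, (0.0, 0.0))
        res = PositionErrorModel(calib).fit()
        slope, intercept = res.lines["pooled"]
        a = cfg.position_error.error_per_hpe_m
        assert slope == pytest.approx(2 * np.sqrt(2) * a, rel=0.05)
        assert abs(intercept) < 0.5  # error proportional to HPE -> ~0 intercept

    def test_single_global_relationship_selects_one_region(self):
        cfg = SimConfig(seed=6)
        c1 = simulate_calibration_positions(cfg, 6000, (0, 0), 1.0, "S1").assign(region="A")
        c2 = simulate_calibration_positions(cfg, 6000, (0, 0), 1.0, "S2").assign(region="B")
        res = PositionErrorModel(pd.concat([c1, c2])).fit()
        assert res.comparison.loc[res.comparison.selected, "partition"].iloc[0] == "1-region"

    def test_distinct_regions_select_two_regions(self):
        cfg = SimConfig(seed=6)
        c1 = simulate_calibration_positions(cfg, 6000, (0, 0), 1.0, "S1").assign(region="A")
        c2 = simulate_calibration_positions(cfg, 6000, (0, 0), 3.0, "S2").assign(region="B")
        res = PositionErrorModel(pd.concat([c1, c2])).fit()
        assert res.comparison.loc[res.comparison.selected, "partition"].iloc[0] == "2-region"
        assert res.lines["B"][0] > 2 * res.lines["A"][0]

    def test_single_bin_fit_errors(self):
        df = _calib_frame([(1, 1), (2, 1), (1, 2)], [0.5, 0.6, 0.7])
        with pytest.raises(CalibrationError):
            PositionErrorModel(df).fit()


@pytest.fixture(scope="module")
def fitted():
    cfg = SimConfig(seed=5)
    calib = simulate_calibration_positions(cfg, 20_000, (0.0, 0.0))
    fish = simulate_calibration_positions(cfg, 30_000, (0.0, 0.0), tag_id="F1")
    fish = fish.drop(columns=["known_x_m", "known_y_m"])
    return PositionErrorModel(calib).fit(), fish


class TestFilter:
    def test_infinite_threshold_keeps_everything(self, fitted):
        res, fish = fitted
        assert res.filter_positions(fish, threshold_m=np.inf).retention == 1.0

    def test_zero_threshold_with_positive_intercept_drops_everything(self, fitted):
        res, fish = fitted
        res2 = type(res)(lines={"pooled": (res.lines["pooled"][0], 0.5)},
                         bins=res.bins, comparison=res.comparison,
                         partition=res.partition,
                         hpe_censor_quantile=res.hpe_censor_quantile)
        assert res2.filter_positions(fish, threshold_m=0.0).retention == 0.0

    def test_default_retention_near_study_value(self, fitted):
        """Generator defaults put ~86% of positions under the 20 m threshold."""
        res, fish = fitted
        assert res.filter_positions(fish).retention == pytest.approx(0.86, abs=0.03)

    def test_filtered_error_below_unfiltered(self, fitted):
        res, _ = fitted
        cfg = SimConfig(seed=15)
        fish = simulate_calibration_positions(cfg, 20_000, (0.0, 0.0), tag_id="F2")
        err = np.hypot(fish.x_m, fish.y_m)
        kept = res.filter_positions(fish).positions
        err_kept = np.hypot(kept.x_m, kept.y_m)
        assert np.median(err_kept) < np.median(err)
        assert np.quantile(err_kept, 0.9) < np.quantile(err, 0.9)


class TestRange:
    def test_d50_recovery_within_5pct(self):
        cfg = SimConfig(seed=8)
        trials = simulate_range_trials(cfg, np.arange(50, 1300, 50), 200)
        res = estimate_range(trials)
        assert res.d50_m == pytest.approx(346.0, rel=0.05)

    def test_probability_at_d50_is_half_p0(self):
        cfg = SimConfig(seed=8)
        trials = simulate_range_trials(cfg, np.arange(50, 1300, 50), 100)
        res = estimate_range(trials)
        assert res.predict(res.d50_m) == pytest.approx(res.p0 / 2, rel=1e-6)

    def test_complete_separation_errors(self):
        trials = pd.DataFrame({"distance_m": np.arange(10.0, 100.0, 10),
                               "detected": True})
        with pytest.raises(SeparationError, match="span"):
            estimate_range(trials)

    def test_consistency_larger_n_tighter(self):
        cfg = SimConfig(seed=9)
        trials = simulate_range_trials(cfg, np.arange(25, 1300, 25), 200)  # ~10^4
        res = estimate_range(trials)
        assert res.d50_m == pytest.approx(346.0, rel=0.05)


def _det(tag, times, receivers):
    return pd.DataFrame({
        "tag_id": tag,
        "receiver_id": receivers,
        "timestamp": pd.to_datetime(times, utc=True),
        "depth_m": 30.0,
    })


class TestCoa:
    RECV = pd.DataFrame({"receiver_id": ["R1", "R2", "R3"],
                         "x_m": [0.0, 100.0, 0.0],
                         "y_m": [0.0, 0.0, 100.0]})

    def test_mean_of_distinct_receivers(self):
        det = _det("F1", ["2021-01-01T00:05:00Z"] * 3 + ["2021-01-01T00:10:00Z"],
                   ["R1", "R2", "R3", "R1"])
        coas = compute_coas(det, self.RECV, 30)
        assert len(coas) == 1
        assert coas.x_m.iloc[0] == pytest.approx(100 / 3)
        assert coas.y_m.iloc[0] == pytest.approx(100 / 3)

    def test_two_receiver_bin_dropped_except_final_date(self):
        mid = _det("F1", ["2021-01-01T00:05:00Z", "2021-01-01T00:10:00Z"],
                   ["R1", "R2"])
        final_day = _det("F1", ["2021-01-05T00:05:00Z", "2021-01-05T00:10:00Z"],
                         ["R1", "R2"])
        filler = _det("F1", ["2021-01-02T12:00:00Z", "2021-01-02T12:05:00Z",
                             "2021-01-02T12:10:00Z"], ["R1", "R2", "R3"])
        coas = compute_coas(pd.concat([mid, filler, final_day]), self.RECV, 30)
        days = coas.bin_start.dt.normalize().dt.day.tolist()
        assert 1 not in days      # 2-receiver mid-study bin dropped
        assert 5 in days          # same situation on the final date retained

    def test_spurious_rule_boundary(self):
        base = ["2021-01-01T02:00:00Z", "2021-01-01T03:00:00Z"]  # 60 min apart
        kept = remove_spurious_detections(_det("F1", base, ["R1", "R1"]))
        assert len(kept) == 2
        far = ["2021-01-01T01:30:00Z", "2021-01-01T03:00:00Z"]  # 90 min apart
        kept = remove_spurious_detections(_det("F1", far, ["R1", "R1"]))
        assert len(kept) == 0

    def test_single_receiver_coa_equals_receiver_coordinates(self):
        times = [f"2021-01-01T00:{m:02d}:00Z" for m in range(0, 30, 5)]
        det = _det("F1", times, ["R2"] * 6)
        coas = compute_coas(det, self.RECV, 30, min_receivers=1)
        assert (coas.x_m == 100.0).all() and (coas.y_m == 0.0).all()

    def test_bad_bin_minutes(self):
        with pytest.raises(ValueError):
            compute_coas(_det("F1", ["2021-01-01T00:00:00Z"], ["R1"]), self.RECV, 37)


class TestResidence:
    def _daily(self, days):
        times = [f"2021-01-{d:02d}T06:00:00Z" for d in days]
        extra = [f"2021-01-{d:02d}T06:30:00Z" for d in days]
        return _det("F1", times + extra, ["R1"] * (2 * len(days)))

    def test_continuous_presence(self):
        det = self._daily(range(1, 29))
        ri = residence_index(det)
        assert ri.ri.iloc[0] == 1.0
        assert detection_gaps(det).empty

    def test_sparse_days(self):
        det = self._daily([1, 2, 10])
        ri = residence_index(det)
        assert ri.detection_days.iloc[0] == 3
        assert ri.period_days.iloc[0] == 10
        assert ri.ri.iloc[0] == pytest.approx(0.3)
        gaps = detection_gaps(det)
        assert len(gaps) == 1 and gaps.gap_days.iloc[0] == 7

    def test_single_day_degenerate(self):
        ri = residence_index(self._daily([7]))
        assert ri.ri.iloc[0] == 1.0
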