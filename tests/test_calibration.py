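"""Calibration regressions, cross-validation, Moran's I and outliers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pearlclim import calibration as c
from pearlclim import synthetic
from pearlclim.errors import (
    InsufficientDataError,
    MeasureUndefinedError,
    ModelFitError,
)

EQ1 = dict(intercept=18.207, slope=0.666)
EQ2 = dict(intercept=632.846, slope=-19.122)


def closed_form_ols(x, y):
    """Independent least-squares oracle via the direct formulas on sums."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope


class TestFitCalibration:
    def test_noiseless_line_exact(self):
        x = np.linspace(11, 18, 20)
        y = EQ1["intercept"] + EQ1["slope"] * x
        cal = c.fit_calibration(x, y)
        assert cal.intercept == pytest.approx(EQ1["intercept"], abs=1e-10)
        assert cal.slope == pytest.approx(EQ1["slope"], abs=1e-12)
        assert cal.pearson_r == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self, rng):
        x = rng.uniform(11, 18, 49)
        y = EQ1["intercept"] + EQ1["slope"] * x + rng.normal(0, 1.1, 49)
        cal = c.fit_calibration(x, y)
        b0, b1 = closed_form_ols(x, y)
        assert cal.intercept == pytest.approx(b0, rel=1e-10)
        assert cal.slope == pytest.approx(b1, rel=1e-10)
        # invariants: F = t^2 of the slope, df mirror n
        assert cal.df_num == 1 and cal.df_den == cal.n - 2
        assert np.sign(cal.slope) == np.sign(cal.pearson_r)

    def test_slope_unbiased_over_replicates(self):
        rng = np.random.default_rng(606)
        slopes = []
        for _ in range(500):
            x, y = synthetic.generate_calibration_dataset(rng)
            slopes.append(c.fit_calibration(x, y).slope)
        assert np.mean(slopes) == pytest.approx(EQ1["slope"], abs=0.02)

    def test_preconditions(self):
        with pytest.raises(InsufficientDataError):
            c.fit_calibration([1, 2, 3, 4], [1, 2, 3, 4])
        with pytest.raises(ModelFitError):
            c.fit_calibration([2.0] * 6, [1, 2, 3, 4, 5, 6])

    def test_parameter_recovery_bias_below_one_percent(self):
        """Generating from either published-scale calibration and refitting
        recovers both coefficients with < 1% bias over 500 replicates."""
        rng = np.random.default_rng(31)
        fits1 = [c.fit_calibration(*synthetic.generate_calibration_dataset(rng))
                 for _ in range(500)]
        fits2 = [c.fit_calibration(*synthetic.generate_age_dataset(rng))
                 for _ in range(500)]
        assert abs(np.mean([f.slope for f in fits1]) - EQ1["slope"]) < 0.01 * abs(EQ1["slope"])
        assert abs(np.mean([f.intercept for f in fits1]) - EQ1["intercept"]) < 0.01 * EQ1["intercept"]
        assert abs(np.mean([f.slope for f in fits2]) - EQ2["slope"]) < 0.01 * abs(EQ2["slope"])
        assert abs(np.mean([f.intercept for f in fits2]) - EQ2["intercept"]) < 0.01 * EQ2["intercept"]


class TestPredict:
    def test_published_scale_predictions(self):
        cal_sci = c.LinearCalibration(18.207, 0.666, 0.76, 64.2, 1, 47, 1e-5, 49, 1.1)
        cal_age = c.LinearCalibration(632.846, -19.122, -0.80, 48.7, 1, 28, 1e-5, 30, 29.0)
        sci = c.predict(cal_sci, 15.0)
        assert sci == pytest.approx(28.197, abs=1e-3)
        assert c.predict(cal_age, sci) == pytest.approx(93.66, abs=0.01)
        assert c.predict(cal_age, 30.04) == pytest.approx(58.42, abs=0.01)

    def test_vectorized(self):
        cal = c.LinearCalibration(1.0, 2.0, 1.0, 0, 1, 3, 0.5, 5, 0.0)
        np.testing.assert_allclose(c.predict(cal, np.array([0.0, 1.0])), [1.0, 3.0])


class TestComparePredictors:
    @staticmethod
    def _battery(rng, n=49):
        mst = rng.uniform(11, 18, n)
        sci = EQ1["intercept"] + EQ1["slope"] * mst + rng.normal(0, 1.1, n)
        frame = pd.DataFrame(
            {
                "mst_20": mst,
                "annual": mst - 8 + rng.normal(0, 2.0, n),
                "spring": mst - 6 + rng.normal(0, 2.0, n),
                "winter": mst - 20 + rng.normal(0, 3.0, n),
                "ets_5": 110 * mst + rng.normal(0, 400, n),
                "noise_var": rng.normal(size=n),
            }
        )
        return frame, sci

    def test_driver_ranked_first(self):
        rng = np.random.default_rng(21)
        firsts = 0
        for _ in range(200):
            frame, sci = self._battery(rng)
            table = c.compare_predictors(frame, sci)
            firsts += table.loc[0, "variable"] == "mst_20"
        assert firsts / 200 >= 0.95

    def test_constant_candidate_excluded(self, rng):
        frame, sci = self._battery(rng)
        frame["flat"] = 3.0
        table = c.compare_predictors(frame, sci)
        assert "flat" not in set(table["variable"])

    def test_window_coefficients_similar_on_slow_climate(self):
        """With slowly varying climate the 20/30/40/50-year MST windows give
        nearly interchangeable calibration slopes."""
        from pearlclim import climate as cl

        spec = synthetic.WorldSpec(seed=5, lon_range=(5.0, 8.0),
                                   interannual_sd_c=0.2,
                                   trend_c_per_decade=0.05)
        grid = synthetic.generate_climate(spec)
        pops, _, truth = synthetic.generate_populations(spec, grid)
        slopes = {}
        for k in (20, 30, 40, 50):
            msts, scis = [], []
            for p in pops:
                cell = cl.locate_cell(grid, p.latitude_deg, p.longitude_deg)
                try:
                    msts.append(cl.mst_window(grid, cell, p.year_collected, k))
                except Exception:
                    continue
                scis.append(p.mean_sci)
            slopes[k] = c.fit_calibration(msts, scis).slope
        vals = np.array(list(slopes.values()))
        assert np.ptp(vals) / np.abs(vals).max() < 0.10


class TestKfoldCv:
    def test_hand_computed_metrics(self):
        obs = np.array([10.0, 20.0])
        pred = np.array([9.0, 22.0])
        assert c.mape(obs, pred) == pytest.approx(10.0)
        assert c.minmax_accuracy(obs, pred) == pytest.approx(0.90455, abs=1e-5)
        assert c.tofallis_accuracy(obs, pred) == pytest.approx(0.10034, abs=1e-5)

    def test_perfect_predictions(self):
        x = np.linspace(11, 18, 20)
        y = EQ1["intercept"] + EQ1["slope"] * x
        rep = c.kfold_cv(x, y, k=5, seed=0)
        assert rep.pooled_mape == pytest.approx(0.0, abs=1e-10)
        assert rep.pooled_tofallis == pytest.approx(0.0, abs=1e-12)
        assert rep.pooled_minmax == pytest.approx(1.0)

    def test_fold_sizes_near_equal(self, rng):
        x, y = synthetic.generate_calibration_dataset(rng, n=23)
        rep = c.kfold_cv(x, y, k=5, seed=1)
        sizes = sorted(rep.fold_metrics["n"])
        assert sizes == [4, 4, 5, 5, 5]

    def test_leave_one_out_partition_independent(self, rng):
        x, y = synthetic.generate_calibration_dataset(rng, n=12)
        r1 = c.kfold_cv(x, y, k=12, seed=1)
        r2 = c.kfold_cv(x, y, k=12, seed=999)
        assert r1.pooled_mape == pytest.approx(r2.pooled_mape, rel=1e-12)
        assert r1.pooled_minmax == pytest.approx(r2.pooled_minmax, rel=1e-12)

    def test_accuracy_bounds_on_calibration_scale_data(self):
        """On data matching the published calibration's scale, pooled MAPE
        stays within a few percent (headroom below the reported 5.5%)."""
        rng = np.random.default_rng(77)
        mapes = []
        for s in range(100):
            x, y = synthetic.generate_calibration_dataset(rng)
            mapes.append(c.kfold_cv(x, y, k=5, seed=s).pooled_mape)
        assert np.quantile(mapes, 0.95) <= 5.5

    def test_preconditions(self, rng):
        x, y = synthetic.generate_calibration_dataset(rng, n=10)
        with pytest.raises(InsufficientDataError):
            c.kfold_cv(x, y, k=11)
        with pytest.raises(MeasureUndefinedError):
            c.kfold_cv(x, y - y.mean() - 100, k=5, seed=0)


def naive_morans_i(values, w):
    """Double-loop Moran's I oracle."""
    v = np.asarray(values, float)
    z = v - v.mean()
    n = v.size
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / w.sum() * num / (z @ z)


class TestMoransI:
    def test_expected_value(self, rng):
        lat = rng.uniform(45, 70, 49)
        lon = rng.uniform(5, 40, 49)
        res = c.morans_i(rng.normal(size=49), lat, lon)
        assert res.expected_i == pytest.approx(-1 / 48)
        assert res.expected_i == pytest.approx(-0.02, abs=0.001)

    def test_matches_double_loop_oracle(self, rng):
        lat = rng.uniform(45, 70, 20)
        lon = rng.uniform(5, 40, 20)
        vals = rng.normal(size=20)
        res = c.morans_i(vals, lat, lon)
        d = c.great_circle_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        w = np.zeros_like(d)
        off = ~np.eye(20, dtype=bool)
        w[off] = 1 / np.maximum(d[off], 1.0)
        assert res.observed_i == pytest.approx(naive_morans_i(vals, w), rel=1e-10)

    def test_null_z_calibration(self):
        rng = np.random.default_rng(55)
        inside = 0
        for _ in range(500):
            lat = rng.uniform(45, 70, 50)
            lon = rng.uniform(5, 40, 50)
            res = c.morans_i(rng.normal(size=50), lat, lon)
            inside += abs(res.z_score) <= 1.96
        assert 0.90 <= inside / 500 <= 0.99

    def test_latitude_gradient_detected(self, rng):
        lat = rng.uniform(45, 70, 49)
        lon = rng.uniform(5, 40, 49)
        res = c.morans_i(lat, lat, lon)
        assert res.observed_i > res.expected_i
        assert res.z_score > 1.96

    def test_duplicate_coordinates_floored(self, rng, caplog):
        lat = np.concatenate([[60.0, 60.0], rng.uniform(45, 70, 8)])
        lon = np.concatenate([[10.0, 10.0], rng.uniform(5, 40, 8)])
        with caplog.at_level("WARNING"):
            res = c.morans_i(rng.normal(size=10), lat, lon)
        assert "floored" in caplog.text
        assert np.isfinite(res.observed_i)


class TestFlagOutliers:
    @staticmethod
    def _data(rng, displaced=0):
        x = np.linspace(11, 18, 49)
        y = EQ1["intercept"] + EQ1["slope"] * x + rng.normal(0, 0.05, 49)
        ids = [f"s{i}" for i in range(49)]
        y[:displaced] += 5.0
        return pd.DataFrame({"population_id": ids, "x": x, "y": y})

    def test_displaced_points_flagged(self, rng):
        rep = c.flag_outliers(self._data(rng, displaced=3))
        assert set(rep.flagged_ids) == {"s0", "s1", "s2"}
        assert rep.excluded_ids == []  # flagged but not removed by default

    def test_clean_data_no_flags(self):
        # bounded deterministic perturbation: every studentized residual ~ O(1)
        x = np.linspace(11, 18, 49)
        y = EQ1["intercept"] + EQ1["slope"] * x + 0.05 * np.sin(np.arange(49))
        data = pd.DataFrame(
            {"population_id": [f"s{i}" for i in range(49)], "x": x, "y": y}
        )
        rep = c.flag_outliers(data)
        assert rep.flagged_ids == []
        assert len(rep.retained_ids) == 49

    def test_explicit_list_removed_regardless(self, rng):
        drop = [f"s{i}" for i in range(40, 46)]
        rep = c.flag_outliers(self._data(rng), exclude_ids=drop)
        assert set(rep.excluded_ids) == set(drop)
        assert len(rep.retained_ids) == 43
        assert not set(drop) & set(rep.retained_ids)

    def test_auto_exclude_removes_flagged(self, rng):
        rep = c.flag_outliers(self._data(rng, displaced=3), auto_exclude=True)
        assert len(rep.retained_ids) == 46
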