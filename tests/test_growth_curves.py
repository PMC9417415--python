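"""Lag, rate and capacity read-off rules, replicate aggregation and QC."""

import math

import numpy as np
import pandas as pd
import pytest

import ecogrowth as eg
from ecogrowth.growth import (GrowthCurve, aggregate_replicates, detect_lag,
                              max_growth_rate, quality_flags, saturated_density)


def make_curve(od, dt=0.5, cid="c", rep=0):
    od = np.asarray(od, float)
    return GrowthCurve(np.arange(len(od)) * dt, od, combination_id=cid,
                       replicate_id=rep)


class TestDetectLag:
    def test_immediate_growth_starts_at_first_read(self):
        curve = make_curve(np.linspace(0.1, 1.0, 12))
        assert detect_lag(curve) == curve.times[0]

    def test_plateau_then_growth_starts_at_last_flat_read(self):
        od = [0.1] * 10 + list(np.linspace(0.11, 0.5, 8))
        assert detect_lag(make_curve(od)) == make_curve(od).times[9]

    def test_no_growth_returns_sentinel(self):
        od = [0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        assert math.isnan(detect_lag(make_curve(od)))

    def test_matches_exhaustive_scan_on_random_curves(self):
        """The lag rule must agree with a literal scan over all start reads."""
        rng = np.random.default_rng(11)
        run = eg.growth.GROWTH_RUN_LENGTH
        for _ in range(200):
            n = rng.integers(10, 60)
            od = np.maximum(rng.normal(0.3, 0.15, n), 0.0)
            curve = make_curve(od)
            expected = math.nan
            for i in range(n - run):
                if all(od[i + k] > od[i + k - 1] for k in range(1, run + 1)):
                    expected = curve.times[i]
                    break
            got = detect_lag(curve)
            assert (math.isnan(got) and math.isnan(expected)) or got == expected

    def test_prepending_plateau_never_shortens_lag(self):
        base = np.linspace(0.1, 1.0, 14)
        tau0 = detect_lag(make_curve(base))
        padded = np.concatenate([np.full(6, base[0]), base])
        assert detect_lag(make_curve(padded)) >= tau0


class TestMaxGrowthRate:
    def test_exact_on_pure_exponential(self):
        t = np.arange(0, 10, 0.5)
        curve = GrowthCurve(t, 0.01 * np.exp(0.6 * t))
        assert max_growth_rate(curve) == pytest.approx(0.6, abs=1e-9)

    def test_constant_curve_has_zero_rate(self):
        curve = make_curve([0.2] * 10)
        assert max_growth_rate(curve, tau=0.0) == 0.0

    def test_matches_exhaustive_window_enumeration(self):
        """Max 3-slope mean must equal a literal enumeration of windows."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            tau = rng.uniform(0, 4)
            r = rng.uniform(0.3, 1.5)
            k = rng.uniform(0.3, 1.0)
            t = np.arange(0, 24, 0.5)
            curve = GrowthCurve(t, eg.lag_logistic(t, tau, r, k, 0.001))
            tau_hat = detect_lag(curve)
            start = int(np.searchsorted(t, tau_hat))
            stop = len(curve.od) - 1 - int(np.argmax(curve.od[::-1]))
            tw, odw = t[start:stop + 1], curve.od[start:stop + 1]
            ln = np.log(odw)
            slopes = np.empty(len(ln))
            slopes[0] = (ln[1] - ln[0]) / (tw[1] - tw[0])
            slopes[-1] = (ln[-1] - ln[-2]) / (tw[-1] - tw[-2])
            for i in range(1, len(ln) - 1):
                slopes[i] = (ln[i + 1] - ln[i - 1]) / (tw[i + 1] - tw[i - 1])
            expected = max(np.mean(slopes[i:i + 3]) for i in range(len(slopes) - 2))
            assert max_growth_rate(curve) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_positive_od_scaling(self):
        t = np.arange(0, 24, 0.5)
        od = eg.lag_logistic(t, 2.0, 0.8, 1.0, 0.001)
        r1 = max_growth_rate(GrowthCurve(t, od))
        r2 = max_growth_rate(GrowthCurve(t, 7.3 * od))
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestSaturatedDensity:
    def test_maximum_at_last_read_uses_last_three(self):
        od = [0.1, 0.2, 0.3, 0.5, 0.8, 0.9, 1.0]
        assert saturated_density(make_curve(od)) == pytest.approx((0.8 + 0.9 + 1.0) / 3)

    def test_interior_maximum_uses_centred_window(self):
        assert saturated_density(np.array([0.1, 0.5, 1.0, 0.5, 0.1])) == pytest.approx(2 / 3)

    def test_matches_windowing_rule_on_random_curves(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            od = rng.uniform(0, 1, rng.integers(6, 40))
            m, n = int(np.argmax(od)), len(od)
            if m == 0:
                expected = od[:3].mean()
            elif m == n - 1:
                expected = od[-3:].mean()
            else:
                expected = od[m - 1:m + 2].mean()
            assert saturated_density(make_curve(od)) == pytest.approx(expected)

    def test_scales_linearly_with_od(self):
        od = np.array([0.1, 0.2, 0.4, 0.8, 0.9, 1.0, 0.95])
        assert saturated_density(3.0 * od) == pytest.approx(3.0 * saturated_density(od))


class TestAggregateReplicates:
    def _replicates(self, taus, rates, caps):
        t = np.arange(0, 30, 0.5)
        return [GrowthCurve(t, eg.lag_logistic(t, tau, r, k, 0.001),
                            combination_id="x", replicate_id=i)
                for i, (tau, r, k) in enumerate(zip(taus, rates, caps))]

    def test_identical_replicates_have_zero_cv(self):
        curves = self._replicates([2, 2, 2], [0.8, 0.8, 0.8], [1, 1, 1])
        gp = aggregate_replicates(curves)
        assert gp.cv["capacity"] == 0.0
        assert not any(gp.unreliable.values())

    def test_cv_is_sd_over_mean(self):
        curves = self._replicates([2, 2, 2], [0.8, 0.8, 0.8], [0.9, 1.0, 1.1])
        gp = aggregate_replicates(curves)
        assert gp.capacity == pytest.approx(1.0, rel=0.02)
        vals = np.array([saturated_density(c) for c in curves])
        assert gp.cv["capacity"] == pytest.approx(vals.std(ddof=1) / vals.mean())

    def test_no_growth_replicate_flags_lag_and_rate(self):
        curves = self._replicates([2, 2], [0.8, 0.8], [1, 1])
        t = curves[0].times
        curves.append(GrowthCurve(t, np.full(len(t), 0.001), combination_id="x",
                                  replicate_id=2))
        gp = aggregate_replicates(curves)
        assert gp.unreliable["tau"] and gp.unreliable["rate"]
        # capacity is judged only by its replicate CV (here inflated too)
        assert gp.unreliable["capacity"] == (gp.cv["capacity"] > 0.12)

    def test_planted_sensor_saturated_curves_are_flagged(self):
        """Exactly the clipped curves must carry the sensor flag."""
        design = eg.generate_design(n_components=3, levels_per_gradient=4,
                                    n_backgrounds=1, seed=3)
        model = eg.ResponseModel(determinant_map={"capacity": "alanine"})
        truth = eg.ground_truth_parameters(design, model)
        good = eg.simulate_curves(truth, n_replicates=1, seed=4)
        bad = eg.simulate_faulty_curves(5, "sensor_saturated", seed=5)
        flagged = {c.combination_id for c in good + bad
                   if "sensor_saturated" in quality_flags(c)}
        assert flagged == {c.combination_id for c in bad}

    def test_planted_no_growth_curves_are_flagged(self):
        bad = eg.simulate_faulty_curves(5, "no_growth", seed=6)
        assert all("no_growth" in quality_flags(c) for c in bad)


class TestIO:
    def test_long_csv_roundtrip(self, tmp_path):
        t = np.arange(0, 12, 0.5)
        curves = [GrowthCurve(t, eg.lag_logistic(t, 1, 0.8, 1, 0.001),
                              combination_id="a", replicate_id=i) for i in range(2)]
        path = tmp_path / "curves.csv"
        eg.growth.write_curves_long(curves, path)
        back = eg.growth.read_curves_long(path)
        assert len(back) == 2
        np.testing.assert_allclose(back[0].od, curves[0].od)

    def test_wide_csv_with_well_map(self, tmp_path):
        t = np.arange(0, 6, 0.5)
        df = pd.DataFrame({"time_hr": t, "A1": np.linspace(0.1, 1, len(t)),
                           "A2": np.linspace(0.1, 0.9, len(t))})
        path = tmp_path / "plate.csv"
        df.to_csv(path, index=False)
        curves = eg.growth.read_curves_wide(path, {"A1": "m1", "A2": "m1"})
        assert [c.replicate_id for c in curves] == [0, 1]
        assert {c.combination_id for c in curves} == {"m1"}

    def test_parameters_table_columns(self, tmp_path):
        t = np.arange(0, 24, 0.5)
        curves = [GrowthCurve(t, eg.lag_logistic(t, 2, 0.8, 1, 0.001),
                              combination_id="m", replicate_id=i) for i in range(3)]
        table = eg.parameters_table(curves)
        assert set(table.columns) >= {"tau", "rate", "capacity", "flag_tau",
                                      "flag_rate", "flag_capacity"}
        assert table.loc["m", "tau"] == pytest.approx(2.0, abs=0.5)


def test_curve_validation_rejects_bad_inputs():
    t = np.arange(0, 5, 0.5)
    with pytest.raises(ValueError):
        GrowthCurve(t, -np.ones(len(t)))
    with pytest.raises(ValueError):
        GrowthCurve(np.array([0, 1, 2, 3, 4, 5.5, 6]), np.ones(7))
    with pytest.raises(ValueError):
        GrowthCurve(np.array([0, 0.5, 1.0]), np.ones(3))
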