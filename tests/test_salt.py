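"""Cross-condition comparisons: window averages, predictions, mass folds."""

import numpy as np
import pytest

import vimflow as vf
from vimflow.salt import (
    condition_ratio,
    mass_per_cross_section,
    predict_elongation_only,
)


class TestConditionRatio:
    def test_identical_sets_give_unity(self):
        cfg = vf.TraceConfig(noise_sd=0.0, sample_rate=200.0, seed=0)
        trace = vf.generate_trace(cfg)
        series = condition_ratio([trace], [trace], 405.0, n_bootstrap=0)
        sel = series.time_s > 0.01
        assert np.nanmax(np.abs(series.ratio[sel] - 1)) < 1e-9

    def test_lateral_fold_recovered_early(self, salt_condition_set):
        for lam in (405.0, 594.0):
            series = condition_ratio(
                salt_condition_set["high"], salt_condition_set["low"], lam, n_bootstrap=0
            )
            assert series.window_averages["early"] == pytest.approx(1.48, rel=0.05)

    def test_moderate_lateral_fold(self):
        base = vf.TraceConfig(sample_rate=1000.0, duration=120.0)
        levels = [dict(lateral_factor=1.0), dict(lateral_factor=1.3)]
        traces = vf.generate_condition_set(base, levels, n_replicates=3, seed=9)
        low = [t for t in traces if t.meta["is_reference"]]
        high = [t for t in traces if not t.meta["is_reference"]]
        series = condition_ratio(high, low, 405.0, n_bootstrap=0,
                                 plateau_window_s=(100.0, 120.0))
        assert series.window_averages["early"] == pytest.approx(1.3, rel=0.05)

    def test_early_window_agrees_across_wavelengths(self, salt_condition_set):
        vals = [
            condition_ratio(
                salt_condition_set["high"], salt_condition_set["low"], lam, n_bootstrap=0
            ).window_averages["early"]
            for lam in (405.0, 594.0)
        ]
        assert abs(vals[0] / vals[1] - 1) < 0.02

    def test_peak_exceeds_plateau_with_overshoot(self, salt_condition_set):
        series = condition_ratio(
            salt_condition_set["high"], salt_condition_set["low"], 405.0, n_bootstrap=0
        )
        assert series.window_averages["peak"] > series.window_averages["plateau"]

    def test_bootstrap_se_reported(self, salt_condition_set):
        series = condition_ratio(
            salt_condition_set["high"], salt_condition_set["low"], 405.0,
            n_bootstrap=50, seed=1,
        )
        assert all(np.isfinite(v) and v >= 0 for v in series.window_se.values())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            condition_ratio([], [], 405.0)

    def test_normalized_traces_rejected(self, salt_condition_set):
        from vimflow.pipeline import normalize_channels

        bad = [normalize_channels(salt_condition_set["high"][0])]
        with pytest.raises(ValueError, match="calibrated"):
            condition_ratio(bad, salt_condition_set["low"], 405.0)

    def test_grid_mismatch_interpolated(self):
        cfg_a = vf.TraceConfig(noise_sd=0.0, sample_rate=200.0, duration=600.0, seed=0)
        cfg_b = vf.TraceConfig(noise_sd=0.0, sample_rate=125.0, duration=600.0, seed=0)
        a, b = vf.generate_trace(cfg_a), vf.generate_trace(cfg_b)
        series = condition_ratio([a], [b], 405.0, n_bootstrap=0)
        sel = series.time_s > 1.0
        assert np.nanmax(np.abs(series.ratio[sel] - 1)) < 0.01


class TestElongationOnlyPrediction:
    def test_equal_rates_flat(self):
        pred = predict_elongation_only(2.0, 2.0, 405.0, np.logspace(-1, 2.5, 60))
        assert np.allclose(pred.ratio, 1.0, atol=1e-12)
        assert pred.peak_value == 1.0

    def test_faster_numerator_peaks_then_relaxes(self):
        times = np.logspace(-1, np.log10(600), 120)
        pred = predict_elongation_only(2.0, 1.0, 405.0, times)
        assert pred.peak_value > 1.05
        assert 5.0 < pred.peak_time_s < 120.0
        # both saturate: relative excess decays toward 1 at long times
        assert pred.ratio[-1] - 1 < 0.3 * (pred.peak_value - 1)

    def test_doubling_rates_halves_peak_time(self):
        times = np.logspace(-1, np.log10(600), 200)
        slow = predict_elongation_only(2.0, 1.0, 405.0, times)
        fast = predict_elongation_only(4.0, 2.0, 405.0, times / 2.0)
        # exact time rescaling on matched grids
        assert np.allclose(slow.ratio, fast.ratio, rtol=1e-12)
        assert fast.peak_time_s == pytest.approx(slow.peak_time_s / 2.0, rel=1e-9)
        assert fast.peak_value == pytest.approx(slow.peak_value, rel=1e-9)

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            predict_elongation_only(0.0, 1.0, 405.0, [1.0])


class TestMassPerCrossSection:
    def test_peak_decomposition_arithmetic(self, salt_condition_set):
        series = condition_ratio(
            salt_condition_set["high"], salt_condition_set["low"], 405.0, n_bootstrap=0
        )
        series.window_averages["peak"] = 1.5  # worked example
        out = mass_per_cross_section(series, predicted_ratio=1.15, window="peak")
        assert out.fold_factor == pytest.approx(1.5 / 1.15, rel=1e-12)

    def test_plateau_with_unit_prediction(self, salt_condition_set):
        series = condition_ratio(
            salt_condition_set["high"], salt_condition_set["low"], 405.0, n_bootstrap=0
        )
        series.window_averages["plateau"] = 1.6
        out = mass_per_cross_section(series, window="plateau")
        assert out.fold_factor == pytest.approx(1.6)

    def test_known_mass_fold_recovered_from_plateau(self):
        # equal elongation rates isolate the mass fold exactly
        base = vf.TraceConfig(sample_rate=200.0)
        levels = [dict(mass_per_cs_factor=1.0), dict(mass_per_cs_factor=1.3)]
        traces = vf.generate_condition_set(base, levels, n_replicates=3, seed=21)
        low = [t for t in traces if t.meta["is_reference"]]
        high = [t for t in traces if not t.meta["is_reference"]]
        series = condition_ratio(high, low, 405.0, n_bootstrap=0)
        out = mass_per_cross_section(series, window="plateau")
        assert out.fold_factor == pytest.approx(1.3, rel=0.05)

    def test_gain_invariance(self, salt_condition_set):
        series_a = condition_ratio(
            salt_condition_set["high"], salt_condition_set["low"], 405.0, n_bootstrap=0
        )
        gained_high = [t.with_channels(t.i405 * 5.5, t.i594 * 5.5)
                       for t in salt_condition_set["high"]]
        gained_low = [t.with_channels(t.i405 * 5.5, t.i594 * 5.5)
                      for t in salt_condition_set["low"]]
        series_b = condition_ratio(gained_high, gained_low, 405.0, n_bootstrap=0)
        for k in ("early", "peak", "plateau"):
            assert series_a.window_averages[k] == pytest.approx(
                series_b.window_averages[k], rel=1e-9
            )

    def test_invalid_inputs(self, salt_condition_set):
        series = condition_ratio(
            salt_condition_set["high"], salt_condition_set["low"], 405.0, n_bootstrap=0
        )
        with pytest.raises(ValueError):
            mass_per_cross_section(series, predicted_ratio=0.0)
        with pytest.raises(ValueError):
            mass_per_cross_section(series, window="early")
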