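"""Ensemble scattering of log-normal populations and the rate calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vimflow.optics import single_length_ratio, ulf_to_length
from vimflow.population import (
    PUBLISHED_RATE_FACTOR,
    GrowthModel,
    LengthDistribution,
    calibrate_rate_factor,
    ensemble_intensity,
    ensemble_ratio,
    fit_ratio_exponential,
    ratio_curve,
    sample_lengths,
    sigma_from_mean,
)

WAVELENGTH_RATIO = 594.0 / 405.0


class TestSigmaLengthLaw:
    @pytest.mark.parametrize("l_fil,expected", [(1.0, 0.168), (0.0, 0.115), (4.0, 0.327)])
    def test_values(self, l_fil, expected):
        assert sigma_from_mean(l_fil) == pytest.approx(expected, abs=1e-12)

    def test_custom_coefficients(self):
        model = GrowthModel(rate=1.0, sigma_slope=0.1, sigma_intercept=0.2)
        assert sigma_from_mean(3.0, model) == pytest.approx(0.5)


class TestSampleLengths:
    def test_monodisperse(self):
        out = sample_lengths(LengthDistribution(3.0, 0.0), 100, seed=0)
        assert np.allclose(out, 3.0)

    def test_geometric_mean_large_n(self):
        out = sample_lengths(LengthDistribution(3.0, 0.274), 100_000, seed=42)
        geo = 10 ** np.mean(np.log10(out))
        assert geo == pytest.approx(3.0, rel=0.01)
        assert np.std(np.log10(out)) == pytest.approx(0.274, rel=0.02)

    def test_seed_reproducibility(self):
        a = sample_lengths(LengthDistribution(2.0, 0.3), 1000, seed=7)
        b = sample_lengths(LengthDistribution(2.0, 0.3), 1000, seed=7)
        assert np.array_equal(a, b)

    def test_bad_n(self):
        with pytest.raises(ValueError):
            sample_lengths(LengthDistribution(2.0, 0.3), 0)


class TestEnsembleIntensity:
    def test_monodisperse_reduces_to_single_length(self):
        dist = LengthDistribution(4.0, 0.0)
        ratio = ensemble_intensity(dist, 594) / ensemble_intensity(dist, 405)
        assert ratio == pytest.approx(single_length_ratio(ulf_to_length(4.0)), rel=1e-10)

    def test_rayleigh_limit(self):
        dist = LengthDistribution(0.05, 0.05)
        ratio = ensemble_intensity(dist, 594) / ensemble_intensity(dist, 405)
        assert ratio == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("l_fil,sigma", [(1.0, 0.168), (4.0, 0.327), (10.0, 0.6)])
    def test_quadrature_vs_monte_carlo(self, l_fil, sigma):
        dist = LengthDistribution(l_fil, sigma)
        for lam in (405.0, 594.0):
            quad = ensemble_intensity(dist, lam, method="quadrature")
            mc = ensemble_intensity(dist, lam, method="mc", n_mc=100_000, seed=11)
            assert abs(quad / mc - 1) < 0.01

    def test_overly_broad_sigma_rejected(self):
        with pytest.raises(ValueError, match="too broad"):
            ensemble_intensity(LengthDistribution(5.0, 3.5), 405)

    @given(
        st.floats(min_value=0.2, max_value=50.0),
        st.floats(min_value=0.0, max_value=1.5),
        st.sampled_from(["filament", "intensity"]),
    )
    def test_ratio_bounded_by_wavelength_ratio(self, l_fil, sigma, average):
        r = ensemble_ratio(LengthDistribution(l_fil, sigma), average=average)
        assert 1.0 - 1e-9 <= r <= WAVELENGTH_RATIO + 1e-9


class TestRatioCurve:
    def test_zero_rate_constant(self):
        curve = ratio_curve(GrowthModel(rate=0.0), np.linspace(0, 10, 7))
        assert np.allclose(curve, curve[0])

    def test_start_value_matches_direct_evaluation(self):
        growth = GrowthModel(rate=1.0)
        start = ratio_curve(growth, [0.0])[0]
        direct = ensemble_ratio(LengthDistribution(1.0, sigma_from_mean(1.0)))
        assert start == pytest.approx(direct, rel=1e-12)

    @pytest.mark.parametrize("rate", [0.5, 1.0, 2.0, 5.0])
    def test_exponential_describes_curve(self, rate):
        # uniformly sampled, as an instrument would record it
        t = np.linspace(1 / 60, 10, 400)
        curve = ratio_curve(GrowthModel(rate=rate), t, average="intensity")
        _, _, rms = fit_ratio_exponential(t, curve)
        assert rms < 0.01

    def test_nondecreasing_before_plateau(self):
        t = np.logspace(-2, 1, 120)
        curve = ratio_curve(GrowthModel(rate=1.0), t)
        assert np.all(np.diff(curve) > -1e-9)
        assert curve[-1] < WAVELENGTH_RATIO

    def test_time_rescaling(self):
        t = np.logspace(-2, 1, 40)
        slow = ratio_curve(GrowthModel(rate=1.0), t)
        fast = ratio_curve(GrowthModel(rate=2.0), t / 2)
        assert np.allclose(slow, fast, rtol=1e-12)

    def test_mc_matches_quadrature(self):
        t = np.logspace(-1, 1, 25)
        quad = ratio_curve(GrowthModel(rate=1.0), t)
        mc = ratio_curve(GrowthModel(rate=1.0), t, method="mc", n_mc=50_000, seed=3)
        assert np.max(np.abs(mc / quad - 1)) < 0.01


class TestCalibration:
    def test_default_grid_reproduces_published_factor(self):
        result = calibrate_rate_factor(seed=1)
        assert result.factor == pytest.approx(PUBLISHED_RATE_FACTOR, abs=0.2)
        assert result.r_squared > 0.99
        assert result.rates == [0.5, 1.0, 2.0, 3.0, 4.0, 5.0]

    def test_monodisperse_changes_factor(self):
        mono = GrowthModel(rate=1.0, sigma_slope=0.0, sigma_intercept=0.0)
        result = calibrate_rate_factor(seed=1, method="quadrature", growth_template=mono)
        assert abs(result.factor - PUBLISHED_RATE_FACTOR) > 0.5

    def test_doubled_intercept_still_linear(self):
        wide = GrowthModel(rate=1.0, sigma_intercept=0.23)
        default = calibrate_rate_factor(seed=1, method="quadrature")
        doubled = calibrate_rate_factor(seed=1, method="quadrature", growth_template=wide)
        assert doubled.r_squared > 0.99
        assert doubled.factor < default.factor  # broader start blurs faster

    def test_too_few_rates_rejected(self):
        with pytest.raises(ValueError):
            calibrate_rate_factor(rates=[1.0, 2.0], seed=0)

    def test_parameter_recovery_across_rates(self):
        """Fitting the exponential and applying the calibrated reciprocal
        rule recovers the generating rate within 10% for 0.5-5 ULFs/min."""
        factor = calibrate_rate_factor(seed=1, method="quadrature").factor
        for rate in (0.5, 1.0, 2.0, 3.0, 5.0):
            # observation window scaled to the rate, covering the same growth
            t_min = np.logspace(np.log10(1 / 60), 1, 150) / rate
            curve = ratio_curve(GrowthModel(rate=rate), t_min)
            _, tau, _ = fit_ratio_exponential(t_min, curve)
            assert factor / tau == pytest.approx(rate, rel=0.10)


class TestValidation:
    def test_distribution_invariants(self):
        with pytest.raises(ValueError):
            LengthDistribution(-1.0, 0.1)
        with pytest.raises(ValueError):
            LengthDistribution(1.0, -0.1)

    def test_growth_invariants(self):
        with pytest.raises(ValueError):
            GrowthModel(rate=-1.0)
        with pytest.raises(ValueError):
            GrowthModel(rate=1.0, start_length=0.5)
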