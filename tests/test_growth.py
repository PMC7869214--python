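"""Growth-variable extraction and CFU survival arithmetic."""

from __future__ import annotations

import math

import numpy as np
import pytest

from acidtol.growth import (
    GrowthCurve,
    SurvivalSeries,
    compare_growth,
    death_rate,
    growth_variables,
    survival_rate,
)
from acidtol.synthdata import simulate_growth, simulate_survival


def exp_curve(od0=0.05, rate=0.4, hours=12, dt=1.0):
    t = np.arange(0, hours, dt)
    return GrowthCurve(times=t, od=od0 * np.exp(rate * t), label="exp")


class TestGrowthVariables:
    def test_noiseless_exponential_rate_to_machine_precision(self):
        gv = growth_variables(exp_curve())
        assert gv.rate == pytest.approx(0.4, abs=1e-9)

    def test_noiseless_exponential_lag_zero_from_first_reading(self):
        """With od_initial taken as the t=0 reading the max-slope tangent
        passes through the initial density at t=0 exactly."""
        gv = growth_variables(exp_curve(), n_initial=1)
        assert gv.lag == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_exponential_default_lag_is_small(self):
        # default od_initial averages the first 2 readings of a curve already
        # growing, so the tangent crosses it within the first interval
        gv = growth_variables(exp_curve())
        assert 0 <= gv.lag <= 1.0

    def test_lag_exponential_curve_recovers_planted_lag_and_rate(self):
        curve, truth = simulate_growth(lag=10.0, rate=0.3, noise_sd=0.0, seed=0)
        gv = growth_variables(curve)
        assert gv.lag == pytest.approx(10.0, abs=0.5)
        assert gv.rate == pytest.approx(0.3, abs=0.01)

    def test_flat_curve_reports_rate_zero_lag_missing(self):
        t = np.arange(0, 10.0)
        gv = growth_variables(GrowthCurve(t, np.full_like(t, 0.3)))
        assert gv.rate == 0.0
        assert math.isnan(gv.lag)
        assert gv.efficiency == 0.0

    def test_decreasing_curve_rate_zero_efficiency_nonnegative(self):
        t = np.arange(0, 10.0)
        gv = growth_variables(GrowthCurve(t, 1.0 * np.exp(-0.2 * t)))
        assert gv.rate == 0.0
        assert gv.efficiency >= 0.0

    def test_too_few_points_or_bad_window_rejected(self):
        t = np.arange(0, 4.0)
        with pytest.raises(ValueError, match=">= 5"):
            growth_variables(GrowthCurve(t, np.exp(t)))
        with pytest.raises(ValueError, match="window_size"):
            growth_variables(exp_curve(), window_size=2)

    def test_time_shift_invariance(self):
        """Adding Δ to all times shifts the lag by exactly Δ and leaves rate
        and efficiency unchanged."""
        curve, _ = simulate_growth(lag=5.0, rate=0.3, noise_sd=0.02, seed=3)
        gv = growth_variables(curve)
        shifted = GrowthCurve(curve.times + 7.25, curve.od, "shifted")
        gs = growth_variables(shifted)
        assert gs.lag == pytest.approx(gv.lag + 7.25, abs=1e-9)
        assert gs.rate == pytest.approx(gv.rate, abs=1e-12)
        assert gs.efficiency == pytest.approx(gv.efficiency, abs=1e-12)

    def test_od_scale_invariance(self):
        """Multiplying all OD by c leaves rate and lag unchanged; efficiency
        scales by c."""
        curve, _ = simulate_growth(lag=5.0, rate=0.3, noise_sd=0.02, seed=4)
        gv = growth_variables(curve)
        scaled = GrowthCurve(curve.times, curve.od * 3.0, "scaled")
        gs = growth_variables(scaled)
        assert gs.rate == pytest.approx(gv.rate, abs=1e-12)
        assert gs.lag == pytest.approx(gv.lag, abs=1e-9)
        assert gs.efficiency == pytest.approx(gv.efficiency * 3.0, rel=1e-12)

    def test_noisy_monte_carlo_recovery(self):
        """500 noisy curves (5% multiplicative noise): median absolute
        relative error < 10% for rate and lag."""
        rng = np.random.default_rng(11)
        rate_errs, lag_errs = [], []
        for i in range(500):
            lag = float(rng.uniform(2.0, 20.0))
            rate = float(rng.uniform(0.15, 0.5))
            curve, _ = simulate_growth(
                lag=lag, rate=rate, noise_sd=0.05,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            gv = growth_variables(curve)
            rate_errs.append(abs(gv.rate - rate) / rate)
            lag_errs.append(abs(gv.lag - lag) / lag)
        assert np.median(rate_errs) < 0.10
        assert np.median(lag_errs) < 0.10

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            GrowthCurve(np.array([0.0, 1.0, 1.0]), np.ones(3))


class TestCompareGrowth:
    def test_identical_inputs(self):
        gv = growth_variables(exp_curve())
        cmp = compare_growth(gv, gv)
        assert cmp.rate_ratio == 1.0
        assert cmp.efficiency_ratio == 1.0
        assert cmp.lag_difference == 0.0

    def test_stressed_vs_unstressed_pair(self):
        """Acid stress planted at half the rate and +30 h lag is reported as
        rate ratio ~0.5 and lag difference ~30 h."""
        unstressed, _ = simulate_growth(lag=2.0, rate=0.35, noise_sd=0.0, seed=0,
                                        horizon=60.0)
        stressed, _ = simulate_growth(lag=32.0, rate=0.175, noise_sd=0.0, seed=0,
                                      horizon=60.0)
        cmp = compare_growth(growth_variables(stressed), growth_variables(unstressed))
        assert cmp.rate_ratio == pytest.approx(0.5, abs=0.05)
        assert cmp.lag_difference == pytest.approx(30.0, abs=1.0)

    def test_missing_lag_propagates(self):
        t = np.arange(0, 10.0)
        flat = growth_variables(GrowthCurve(t, np.full_like(t, 0.3)))
        grown = growth_variables(exp_curve())
        assert math.isnan(compare_growth(flat, grown).lag_difference)


class TestSurvival:
    def test_time_zero_is_exactly_100(self):
        s = SurvivalSeries(np.array([0.0, 2.0]), np.array([5e5, 5e5]))
        assert survival_rate(s)[0] == (0.0, 100.0)

    def test_halved_cfu_is_50(self):
        s = SurvivalSeries(np.array([0.0, 2.0]), np.array([1e6, 5e5]))
        assert survival_rate(s)[1][1] == pytest.approx(50.0)

    def test_zero_starting_cfu_rejected(self):
        with pytest.raises(ValueError, match="time zero"):
            survival_rate(SurvivalSeries(np.array([0.0, 1.0]), np.array([0.0, 1.0])))

    def test_dilution_invariance(self):
        t = np.array([0.0, 2.0, 4.0])
        c = np.array([1e6, 4e5, 1e5])
        a = survival_rate(SurvivalSeries(t, c))
        b = survival_rate(SurvivalSeries(t, c * 250.0))
        assert [p for _, p in a] == pytest.approx([p for _, p in b])

    def test_exponential_death_rate_recovered_within_5_percent(self):
        series, truth = simulate_survival(
            times=np.linspace(0, 8, 9), death_rate=0.5, noise_sd=0.02, seed=5
        )
        assert death_rate(series) == pytest.approx(0.5, rel=0.05)
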