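"""Three-state kinetics: closed form, fitting, power-law and duration scaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pa2p.kinetics import (
    DurationScalingTable,
    RateParams,
    classify_process_order,
    fit_frame_series,
    fit_power_law,
    fluorescent_population,
    format_measured_relative_rate,
    format_theoretical_relative_rate,
    peak_frame,
    relative_rate_scaling,
    theoretical_duration_scaling,
)

from conftest import rk4_three_state


class TestFluorescentPopulation:
    def test_zero_time_gives_zero(self, rates_default):
        assert fluorescent_population(0.0, rates_default) == 0.0

    def test_no_bleaching_saturates(self):
        rates = RateParams(1.0, 0.0)
        assert fluorescent_population(1.0, rates) == pytest.approx(1 - math.exp(-1))
        assert fluorescent_population(200.0, rates) == pytest.approx(1.0)

    def test_matches_rk4_oracle_at_reference_point(self, rates_default, rk4_oracle):
        # frozen from the RK4 oracle (step 1e-4): N_f(2; 0.5, 0.1) = 0.563564
        assert rk4_oracle(0.5, 0.1, 2.0, dt=1e-4) == pytest.approx(0.5635641, abs=1e-6)
        assert fluorescent_population(2.0, rates_default) == pytest.approx(
            0.5635641, abs=1e-6
        )

    def test_degenerate_rates_use_limit_form(self, rk4_oracle):
        # k_act == k_bl == 0.3 at t=2: limit form k t e^{-kt} = 0.32929
        val = fluorescent_population(2.0, RateParams(0.3, 0.3))
        assert val == pytest.approx(0.3 * 2 * math.exp(-0.6), rel=1e-12)
        assert val == pytest.approx(rk4_oracle(0.3, 0.3, 2.0, dt=1e-4), rel=1e-6)

    def test_closed_form_equals_ode_over_lattice(self, rk4_oracle):
        """Closed form and RK4 agree to <1e-6 relative over a (k,k,t) lattice
        including the near-degenerate ridge."""
        k_acts = [0.05, 0.2, 0.5, 1.0, 2.0]
        k_bls = [0.01, 0.1, 0.5, 0.5 + 1e-12]
        ts = [0.5, 1.0, 2.0, 5.0, 10.0]
        checked = 0
        for ka in k_acts:
            for kb in k_bls:
                for t in ts:
                    ref = rk4_three_state(ka, kb, t, dt=1e-3)
                    got = fluorescent_population(t, RateParams(ka, kb))
                    assert got == pytest.approx(ref, rel=1e-6, abs=1e-8)
                    checked += 1
        assert checked == 100

    def test_negative_time_rejected(self, rates_default):
        with pytest.raises(ValueError):
            fluorescent_population(-1.0, rates_default)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            RateParams(-0.1, 0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ka=st.floats(1e-3, 5.0),
        kb=st.floats(1e-3, 5.0),
        t=st.floats(0.0, 50.0),
    )
    def test_population_is_a_fraction(self, ka, kb, t):
        val = fluorescent_population(t, RateParams(ka, kb))
        assert 0.0 <= val <= 1.0


class TestPeakFrame:
    def test_reference_value(self):
        assert peak_frame(RateParams(0.5, 0.1)) == pytest.approx(
            math.log(5) / 0.4, rel=1e-12
        )

    def test_grid_argmax_oracle(self):
        rates = RateParams(0.5, 0.1)
        t = np.linspace(0, 40, 400001)
        t_star = t[np.argmax(fluorescent_population(t, rates))]
        assert peak_frame(rates) == pytest.approx(t_star, abs=1e-3)

    def test_degenerate_limit(self):
        assert peak_frame(RateParams(0.2, 0.2)) == pytest.approx(5.0)

    def test_monotone_in_bleach_rate(self):
        """Slower bleaching pushes the signal maximum later."""
        k_bls = [0.4, 0.2, 0.1, 0.05, 0.01]
        peaks = [peak_frame(RateParams(0.5, kb)) for kb in k_bls]
        assert all(a < b for a, b in zip(peaks, peaks[1:]))

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            peak_frame(RateParams(0.5, 0.0))


class TestFitFrameSeries:
    def test_noiseless_self_consistency(self):
        t = np.arange(1, 40, dtype=float)
        y = 100.0 * fluorescent_population(t, RateParams(0.5, 0.1))
        fit = fit_frame_series((t, y))
        assert fit.rates.k_act == pytest.approx(0.5, rel=1e-6)
        assert fit.rates.k_bl == pytest.approx(0.1, rel=1e-6)
        assert fit.amplitude == pytest.approx(100.0, rel=1e-6)

    def test_poisson_series_matches_grid_search_oracle(self):
        """On noisy data the solver minimum must agree with a brute-force
        SSE grid search, and recover the truth within 10%/20%."""
        rng = np.random.default_rng(42)
        t = np.arange(1, 40, dtype=float)
        mu = 500.0 * fluorescent_population(t, RateParams(0.5, 0.1))
        y = rng.poisson(mu).astype(float)
        fit = fit_frame_series((t, y))
        assert fit.rates.k_act == pytest.approx(0.5, rel=0.10)
        assert fit.rates.k_bl == pytest.approx(0.1, rel=0.20)

        # brute-force oracle over (k_act, k_bl), amplitude solved linearly
        ka_grid = np.linspace(0.3, 0.7, 81)
        kb_grid = np.linspace(0.05, 0.15, 41)
        best = (None, np.inf)
        for ka in ka_grid:
            for kb in kb_grid:
                shape = fluorescent_population(t, RateParams(ka, kb))
                amp = float(shape @ y / (shape @ shape))
                sse = float(np.sum((y - amp * shape) ** 2))
                if sse < best[1]:
                    best = ((ka, kb), sse)
        (ka_o, kb_o), _ = best
        assert fit.rates.k_act == pytest.approx(ka_o, abs=0.02)
        assert fit.rates.k_bl == pytest.approx(kb_o, abs=0.01)

    def test_pure_rise_has_bleach_consistent_with_zero(self):
        t = np.arange(1, 40, dtype=float)
        y = 80.0 * (1 - np.exp(-0.3 * t))
        fit = fit_frame_series((t, y))
        assert fit.rates.k_bl <= max(fit.stderr_k_bl, 1e-6)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            fit_frame_series(([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))


class TestFitPowerLaw:
    def test_exact_square_law(self):
        fit = fit_power_law([1, 2, 4], [3.0, 12.0, 48.0])
        assert fit.exponent_n == pytest.approx(2.0, abs=1e-12)
        assert fit.prefactor_c == pytest.approx(3.0, rel=1e-12)

    def test_lognormal_noise_recovers_exponent(self):
        """Multiplicative noise sigma=0.1 around a square law; the weighted
        fit must agree with the closed-form OLS slope oracle."""
        rng = np.random.default_rng(7)
        P = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0])
        k = 0.03 * P**2 * rng.lognormal(0.0, 0.1, size=P.size)
        fit = fit_power_law(P, k)
        # closed-form OLS slope on (log P, log k)
        x, y = np.log(P), np.log(k)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fit.exponent_n == pytest.approx(slope, rel=1e-12)
        assert 1.8 <= fit.exponent_n <= 2.2

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0, 3.0], [1.0, -1.0, 1.0])


class TestDurationScaling:
    @pytest.mark.parametrize(
        "n, expected",
        [
            (1, ("1", "1", "1")),
            (2, ("1", "0.5", "0.17")),
            (3, ("1", "0.25", "0.028")),
        ],
    )
    def test_theoretical_scaling_printed_values(self, n, expected):
        """Ideal n-photon duration scalings at 200/400/1200 fs, at the
        rounding of the reference tables."""
        table = theoretical_duration_scaling(n, [200.0, 400.0, 1200.0])
        got = tuple(format_theoretical_relative_rate(v) for v in table.relative_rates)
        assert got == expected

    def test_theoretical_monotone_nonincreasing(self):
        for n in (1.0, 1.5, 2.0, 3.0):
            rel = theoretical_duration_scaling(n, [200, 300, 400, 800, 1200]).relative_rates
            assert all(a >= b for a, b in zip(rel, rel[1:]))

    @pytest.mark.parametrize(
        "rates, stderrs, expected",
        [
            ((1.24, 0.62, 0.12), (0.16, 0.01, 0.01), ("1.00", "0.50", "0.097")),
            ((1.33, 0.72, 0.23), (0.08, 0.02, 0.02), ("1.00", "0.54", "0.173")),
        ],
    )
    def test_measured_relative_scaling_printed_values(self, rates, stderrs, expected):
        """Normalising the measured 200/400/1200 fs activation rates for the
        two caged dyes reproduces the published relative scalings."""
        table = relative_rate_scaling(rates, stderrs, durations=(200, 400, 1200))
        got = tuple(format_measured_relative_rate(v) for v in table.relative_rates)
        assert got == expected
        assert table.relative_rates[0] == 1.0
        assert table.stderr[0] == 0.0

    def test_single_entry_self_normalises(self):
        table = relative_rate_scaling([5.0])
        assert table.relative_rates == (1.0,)

    def test_error_propagation_in_quadrature(self):
        table = relative_rate_scaling([2.0, 1.0], [0.2, 0.1], durations=(1, 2))
        expected = 0.5 * math.sqrt((0.1 / 1.0) ** 2 + (0.2 / 2.0) ** 2)
        assert table.stderr[1] == pytest.approx(expected, rel=1e-12)

    def test_zero_first_rate_rejected(self):
        with pytest.raises(ValueError):
            relative_rate_scaling([0.0, 1.0])


class TestClassifyProcessOrder:
    @pytest.mark.parametrize(
        "measured",
        [(1.0, 0.50, 0.097), (1.0, 0.54, 0.173)],
        ids=["HCage620", "ONB-2SiR"],
    )
    def test_measured_dyes_classified_two_photon(self, measured):
        """Both caged dyes' duration scalings are closest to the ideal
        two-photon tau^-1 law."""
        table = DurationScalingTable((200.0, 400.0, 1200.0), measured)
        order, scores = classify_process_order(table, [1, 2, 3])
        assert order == 2
        assert scores[2] < scores[1] and scores[2] < scores[3]

    def test_ideal_three_photon_input(self):
        table = DurationScalingTable((200.0, 400.0, 1200.0), (1.0, 0.25, 0.028))
        order, _ = classify_process_order(table, [1, 2, 3])
        assert order == 3

    @pytest.mark.parametrize("n", [1, 2, 3])
    @pytest.mark.parametrize("durations", [(200.0, 400.0), (200.0, 400.0, 1200.0, 2400.0)])
    def test_round_trip_with_theoretical_tables(self, n, durations):
        table = theoretical_duration_scaling(n, durations)
        order, _ = classify_process_order(table, [1, 2, 3])
        assert order == n

    def test_zero_relative_rate_rejected(self):
        table = DurationScalingTable.__new__(DurationScalingTable)
        object.__setattr__(table, "durations", (200.0, 400.0))
        object.__setattr__(table, "relative_rates", (1.0, 0.0))
        object.__setattr__(table, "stderr", (0.0, 0.0))
        with pytest.raises(ValueError):
            classify_process_order(table, [1, 2])
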