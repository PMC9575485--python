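"""Structural model: allometric scaling, variability sampling, exact profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from pippk import (
    ConcentrationProfile,
    PopulationParameters,
    allometric_scale,
    fraction_time_above,
    sample_individual,
    simulate_profile,
    steady_state_css,
)
from pippk.pk_model import simulate_profiles, time_above_threshold
from pippk.regimens import InfusionEvent, Regimen, build_regimen


def ode_oracle(ind, events, times):
    """Independent adaptive-ODE reference solution (per-segment LSODA)."""
    k10 = ind.cl / ind.vc
    k12, k21 = ind.q1 / ind.vc, ind.q1 / ind.vp1
    k13, k31 = ind.q2 / ind.vc, ind.q2 / ind.vp2
    K = np.array(
        [[-(k10 + k12 + k13), k21, k31], [k12, -k21, 0.0], [k13, 0.0, -k31]]
    )
    t_max = float(np.max(times))
    edges = sorted(
        {0.0, t_max}
        | {e.start for e in events if e.start < t_max}
        | {e.start + e.duration for e in events if e.start + e.duration < t_max}
    )
    A = np.zeros(3)
    out = {}
    for t0, t1 in zip(edges[:-1], edges[1:]):
        rate = sum(
            ev.amount / ev.duration
            for ev in events
            if ev.start <= t0 + 1e-12 < ev.start + ev.duration
        )
        tsel = np.asarray(times)[(np.asarray(times) >= t0 - 1e-12) & (np.asarray(times) <= t1 + 1e-12)]
        sol = solve_ivp(
            lambda t, y: K @ y + np.array([rate, 0.0, 0.0]),
            (t0, t1),
            A,
            t_eval=np.unique(np.concatenate([tsel, [t1]])),
            method="LSODA",
            rtol=1e-11,
            atol=1e-13,
        )
        for t, y in zip(sol.t, sol.y.T):
            out[round(float(t), 9)] = y[0] / ind.vc
        A = sol.y[:, -1]
    return np.array([out[round(float(t), 9)] for t in times])


class TestAllometricScaling:
    def test_identity_at_reference_weight(self, pop):
        ind = allometric_scale(pop, 70.0)
        assert ind.cl == pytest.approx(14.24)
        assert ind.vc == pytest.approx(5.953)
        assert ind.q1 == pytest.approx(0.1943)
        assert ind.vp1 == pytest.approx(3.537)
        assert ind.q2 == pytest.approx(27.45)
        assert ind.vp2 == pytest.approx(7.329)
        assert ind.eta_cl == 0.0

    def test_power_law_at_half_weight(self, pop):
        ind = allometric_scale(pop, 35.0)
        assert ind.cl == pytest.approx(14.24 * 0.5**0.75, rel=1e-12)
        assert ind.cl == pytest.approx(8.4672, rel=1e-4)
        assert ind.vc == pytest.approx(2.9765, rel=1e-12)

    @pytest.mark.parametrize("weight", [0.0, -5.0])
    def test_invalid_weight_rejected(self, pop, weight):
        with pytest.raises(ValueError):
            allometric_scale(pop, weight)

    def test_invalid_population_parameters_rejected(self):
        with pytest.raises(ValueError):
            PopulationParameters(cl_70=-1.0)
        with pytest.raises(ValueError):
            PopulationParameters(exp_cl=2.5)


class TestSampleIndividual:
    def test_zero_omega_equals_typical(self, pop):
        assert sample_individual(pop, 27.4, 0.0, rng=3) == allometric_scale(pop, 27.4)

    def test_negative_omega_rejected(self, pop):
        with pytest.raises(ValueError):
            sample_individual(pop, 27.4, -0.1)

    def test_lognormal_median_and_quantile(self, pop):
        # 1e5 draws at omega = 0.481: ratio median ~ 1, 5th percentile
        # ~ exp(-1.645 * 0.481) = 0.4533 (log-normal quantile identity)
        rng = np.random.default_rng(99)
        typical = allometric_scale(pop, 27.4).cl
        draws = np.array(
            [sample_individual(pop, 27.4, 0.481, rng).cl for _ in range(100_000)]
        )
        assert np.median(draws) / typical == pytest.approx(1.0, abs=0.01)
        assert np.percentile(draws / typical, 5) == pytest.approx(0.4533, abs=0.01)

    def test_reproducible_under_seed(self, pop):
        a = sample_individual(pop, 40.0, 0.481, rng=7)
        b = sample_individual(pop, 40.0, 0.481, rng=7)
        assert a == b


class TestSimulateProfile:
    def test_one_compartment_closed_form(self, pop):
        # disable peripheral exchange: bolus decays as (D/vc) exp(-cl/vc t)
        ind = allometric_scale(pop, 70.0)
        ind = type(ind)(weight=70, cl=ind.cl, vc=ind.vc, q1=1e-12, vp1=ind.vp1,
                        q2=1e-12, vp2=ind.vp2)
        D = 2000.0
        reg = Regimen("CI", 300, 70, (InfusionEvent(0.0, 1e-7, D),))
        times = np.linspace(0.1, 6, 30)
        prof = simulate_profile(ind, reg, times)
        expect = (D / ind.vc) * np.exp(-(ind.cl / ind.vc) * times)
        np.testing.assert_allclose(prof.concentrations, expect, rtol=1e-6)

    def test_constant_infusion_reaches_rate_over_cl(self, pop):
        ind = allometric_scale(pop, 70.0)
        reg = build_regimen("CI", 300, 70.0, n_days=10)
        prof = simulate_profile(ind, reg, np.array([220.0, 239.0]))
        assert prof.concentrations[-1] == pytest.approx(
            steady_state_css(ind, reg.daily_maintenance_mg / 24.0), rel=1e-4
        )

    def test_matches_ode_oracle_for_ci_regimen(self, pop):
        ind = allometric_scale(pop, 70.0)
        reg = build_regimen("CI", 300, 70.0, n_days=2, loading_mg_per_kg=100)
        times = np.linspace(0.05, 48.0, 50)
        prof = simulate_profile(ind, reg, times)
        oracle = ode_oracle(ind, reg.events, times)
        np.testing.assert_allclose(prof.concentrations, oracle, rtol=1e-6)

    def test_matches_ode_oracle_on_random_parameters(self):
        # randomized positive parameter sets, intermittent schedule
        rng = np.random.default_rng(42)
        for _ in range(20):
            ind_kwargs = dict(
                weight=rng.uniform(10, 90),
                cl=rng.uniform(1, 30),
                vc=rng.uniform(1, 20),
                q1=rng.uniform(0.05, 5),
                vp1=rng.uniform(0.5, 20),
                q2=rng.uniform(1, 40),
                vp2=rng.uniform(1, 20),
            )
            from pippk import IndividualParameters

            ind = IndividualParameters(**ind_kwargs)
            events = (
                InfusionEvent(0.0, 0.5, 1500.0),
                InfusionEvent(8.0, 0.5, 1500.0),
            )
            reg = Regimen("IA_q8h", 300, ind.weight, events)
            times = np.linspace(0.1, 16.0, 25)
            prof = simulate_profile(ind, reg, times)
            oracle = ode_oracle(ind, events, times)
            np.testing.assert_allclose(prof.concentrations, oracle, rtol=1e-6)

    def test_superposition_linearity(self, pop):
        ind = allometric_scale(pop, 40.0)
        times = np.linspace(0.0, 24.0, 97)
        a = (InfusionEvent(0.0, 0.5, 1000.0),)
        b = (InfusionEvent(6.0, 2.0, 3000.0),)
        pa = simulate_profile(ind, Regimen("CI", 1, 40, a), times).concentrations
        pb = simulate_profile(ind, Regimen("CI", 1, 40, b), times).concentrations
        pab = simulate_profile(ind, Regimen("CI", 1, 40, a + b), times).concentrations
        np.testing.assert_allclose(pab, pa + pb, rtol=1e-9, atol=1e-12)

    def test_mass_balance_without_elimination(self):
        # cl ~ 0: amounts in the three compartments sum to the infused amount
        from pippk import IndividualParameters

        ind = IndividualParameters(weight=40, cl=1e-12, vc=4.0, q1=0.2, vp1=2.0,
                                   q2=15.0, vp2=4.0)
        amounts = simulate_profiles(
            ind.cl, ind.vc, ind.q1, ind.vp1, ind.q2, ind.vp2,
            np.array([0.0]), np.array([2.0]), np.array([5000.0]),
            np.array([0.5, 1.0, 2.0, 6.0]),
            return_amounts=True,
        )[0]
        infused = np.array([0.5, 1.0, 2.0, 2.0]) / 2.0 * 5000.0
        np.testing.assert_allclose(amounts.sum(axis=1), infused, rtol=1e-9)

    def test_css_matches_profile_at_ten_half_lives(self, pop):
        ind = allometric_scale(pop, 27.4)
        from pippk.pk_model import _eigensystem

        lam, _, _ = _eigensystem(ind.cl, ind.vc, ind.q1, ind.vp1, ind.q2, ind.vp2)
        t_half = np.log(2) / np.abs(lam[0]).min()
        t_eval = 10.0 * t_half
        rate = 342.5
        n_days = int(np.ceil(t_eval / 24.0)) + 1
        reg = Regimen("CI", 300, 27.4, (InfusionEvent(0.0, 24.0 * n_days, rate * 24 * n_days),))
        prof = simulate_profile(ind, reg, np.array([t_eval]))
        assert prof.concentrations[0] == pytest.approx(
            steady_state_css(ind, rate), rel=1e-3
        )

    def test_negative_inputs_rejected(self, pop):
        ind = allometric_scale(pop, 40.0)
        reg = build_regimen("CI", 300, 40.0)
        with pytest.raises(ValueError):
            simulate_profile(ind, reg, np.array([-1.0, 2.0]))
        with pytest.raises(ValueError):
            InfusionEvent(0.0, 1.0, -10.0)

    def test_steady_state_css_trivial(self, pop):
        ind = allometric_scale(pop, 70.0)
        assert steady_state_css(ind, 0.0) == 0.0
        assert steady_state_css(ind, 16000 / 24) == pytest.approx(46.816, abs=5e-3)
        with pytest.raises(ValueError):
            steady_state_css(ind, -1.0)

    def test_css_after_allometric_scaling(self, pop):
        ind = allometric_scale(pop, 27.4)
        assert ind.cl == pytest.approx(7.0469, abs=1e-3)
        assert steady_state_css(ind, 342.5) == pytest.approx(48.60, abs=0.02)


class TestFractionTimeAbove:
    def _const(self, level):
        t = np.linspace(0.0, 8.0, 9)
        return ConcentrationProfile(t, np.full(9, float(level)))

    def test_constant_above(self):
        assert fraction_time_above(self._const(47.9), 16.0, (0, 8)) == 1.0

    def test_constant_below(self):
        assert fraction_time_above(self._const(10.0), 16.0, (0, 8)) == 0.0

    def test_constant_exactly_at_threshold_not_above(self):
        assert fraction_time_above(self._const(16.0), 16.0, (0, 8)) == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            fraction_time_above(self._const(1.0), 16.0, (3.0, 3.0))

    def test_window_outside_span_rejected(self):
        with pytest.raises(ValueError):
            fraction_time_above(self._const(1.0), 16.0, (0.0, 9.0))

    def test_sawtooth_against_dense_grid_oracle(self):
        # piecewise-linear sawtooth crossing the threshold once per period
        t = np.linspace(0.0, 10.0, 21)
        c = np.where(np.arange(21) % 2 == 0, 2.0, 30.0)
        prof = ConcentrationProfile(t, c)
        got = fraction_time_above(prof, 16.0, (0.0, 10.0))
        td = np.linspace(0.0, 10.0, 2_000_001)
        cd = np.interp(td, t, c)
        oracle = np.mean(cd > 16.0)
        assert got == pytest.approx(oracle, abs=1e-3)

    @given(thr=st.floats(0.5, 40.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fraction_bounded_and_monotone_in_threshold(self, thr):
        t = np.linspace(0.0, 6.0, 40)
        c = 20.0 * np.exp(-0.3 * t) + 5.0 * np.sin(t)
        prof = ConcentrationProfile(t, np.maximum(c, 0))
        f = fraction_time_above(prof, thr, (0.0, 6.0))
        f_higher = fraction_time_above(prof, thr + 1.0, (0.0, 6.0))
        assert 0.0 <= f <= 1.0
        assert f_higher <= f + 1e-12


def test_population_parameters_roundtrip(tmp_path, pop):
    path = tmp_path / "params.yaml"
    pop.to_file(path)
    assert PopulationParameters.from_file(path) == pop
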