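"""Trafficking ODE core: closed-form solutions, steady states, observables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rtktraffic.model_core import (CompartmentState, NoSteadyStateError,
                                   RateParams, Trajectory,
                                   derived_observables, simulate_full,
                                   simulate_pulse_chase, steady_state,
                                   steady_surface_fraction)

from conftest import ivp_oracle, random_rates, random_state

EXAMPLE = RateParams(P_syn=100.0, k_deg=0.01, k_end=0.01, k_rec=0.01,
                     k_shed=0.001)


class TestSimulateFull:
    def test_no_fluxes_constant_trajectory(self):
        p = RateParams(P_syn=0, k_deg=0, k_end=0, k_rec=0, k_shed=0)
        tr = simulate_full(p, CompartmentState(r_s=10, r_i=5, r_f=0),
                           [1, 10, 100])
        assert np.allclose(tr.r_s, 10) and np.allclose(tr.r_i, 5)
        assert np.allclose(tr.r_f, 0)

    def test_fixed_point_stays_fixed_and_sheds_linearly(self):
        ss = steady_state(EXAMPLE)
        tr = simulate_full(EXAMPLE, CompartmentState(r_s=ss.r_s, r_i=ss.r_i),
                           [10, 720, 1440])
        assert np.allclose(tr.r_s, ss.r_s, rtol=1e-10)
        assert np.allclose(tr.r_i, ss.r_i, rtol=1e-10)
        # dr_f/dt = k_shed * r_s* = 16.667 molecules/cell/min
        assert np.allclose(tr.r_f, 16.666667 * tr.times, rtol=1e-5)

    def test_matches_brute_force_integrator(self, rng):
        for _ in range(25):
            p = random_rates(rng)
            init = random_state(rng)
            times = np.sort(rng.uniform(1, 2000, 6))
            times = np.unique(times)
            tr = simulate_full(p, init, times)
            rs, ri, rf = ivp_oracle(p, init, times)
            got = np.vstack([tr.r_s, tr.r_i, tr.r_f])
            exp = np.vstack([rs, ri, rf])
            floor = 1e-4 * np.max(np.abs(exp))
            assert np.max(np.abs(got - exp) /
                          np.maximum(np.abs(exp), floor)) < 1e-6

    def test_long_horizon_converges_to_steady_state(self, rng):
        p = random_rates(rng)
        ss = steady_state(p)
        tr = simulate_full(p, CompartmentState(r_s=1.0, r_i=1.0), [1e6])
        assert tr.r_s[0] == pytest.approx(ss.r_s, rel=1e-6)
        assert tr.r_i[0] == pytest.approx(ss.r_i, rel=1e-6)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            RateParams(P_syn=-1, k_deg=0, k_end=0, k_rec=0, k_shed=0)
        with pytest.raises(ValueError):
            RateParams(P_syn=float("nan"), k_deg=0, k_end=0, k_rec=0, k_shed=0)
        with pytest.raises(ValueError):
            CompartmentState(r_s=-1, r_i=0, r_f=0)
        with pytest.raises(ValueError):
            simulate_full(EXAMPLE, CompartmentState(r_s=1, r_i=1), [5, 5, 10])
        with pytest.raises(ValueError):
            simulate_full(EXAMPLE, CompartmentState(r_s=1, r_i=1), [-1, 5])

    def test_mass_balance_along_random_trajectories(self, rng):
        """d(r_t + r_f)/dt = P_syn - k_deg * r_i (central finite diff)."""
        h = 1e-3
        for _ in range(100):
            p = random_rates(rng)
            init = random_state(rng)
            for t in (10.0, 500.0, 1500.0):
                lo = simulate_full(p, init, [t - h])
                hi = simulate_full(p, init, [t + h])
                mid = simulate_full(p, init, [t])
                lhs = ((hi.r_t[0] + hi.r_f[0]) - (lo.r_t[0] + lo.r_f[0])) / (2 * h)
                rhs = p.P_syn - p.k_deg * mid.r_i[0]
                scale = max(abs(rhs), abs(p.P_syn), 1e-6)
                assert abs(lhs - rhs) / scale < 1e-6


class TestPulseChase:
    def test_no_rates_label_conserved(self):
        p = RateParams(P_syn=100, k_deg=0, k_end=0, k_rec=0, k_shed=0)
        tr = simulate_pulse_chase(p, CompartmentState(r_s=1, r_i=0),
                                  [5, 20, 90])
        assert np.allclose(tr.r_t, 1.0) and np.allclose(tr.r_i, 0.0)

    def test_pure_endocytosis_scalar_exponential(self):
        p = RateParams(P_syn=0, k_deg=0, k_end=0.05, k_rec=0, k_shed=0)
        tr = simulate_pulse_chase(p, CompartmentState(r_s=1, r_i=0), [20])
        assert tr.r_i[0] == pytest.approx(1 - np.exp(-1), abs=1e-12)
        assert tr.r_t[0] == pytest.approx(1.0, abs=1e-12)

    def test_synthesis_term_is_ignored(self, rng):
        p = random_rates(rng)
        init = random_state(rng)
        a = simulate_pulse_chase(p, init, [5, 45, 90])
        b = simulate_pulse_chase(p.replace(P_syn=0.0), init, [5, 45, 90])
        assert np.allclose(a.r_t, b.r_t) and np.allclose(a.r_i, b.r_i)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_linearity_in_initial_label(self, scale):
        p = RateParams(P_syn=50, k_deg=0.01, k_end=0.02, k_rec=0.005,
                       k_shed=0.001)
        base = simulate_pulse_chase(p, CompartmentState(r_s=2, r_i=1),
                                    [5, 20, 45, 75, 90])
        scaled = simulate_pulse_chase(
            p, CompartmentState(r_s=2 * scale, r_i=1 * scale),
            [5, 20, 45, 75, 90])
        for attr in ("r_s", "r_i", "r_f", "r_t"):
            assert np.allclose(getattr(scaled, attr),
                               scale * getattr(base, attr), rtol=1e-9)

    def test_total_label_monotone_nonincreasing_and_nonnegative(self, rng):
        for _ in range(25):
            p = random_rates(rng)
            init = random_state(rng)
            tr = simulate_pulse_chase(p, init, np.arange(1.0, 200.0, 3.0))
            assert np.all(np.diff(tr.r_t) <= 1e-9 * tr.r_t[0])
            assert np.all(tr.r_s >= -1e-12) and np.all(tr.r_i >= -1e-12)

    def test_matches_brute_force_integrator(self, rng):
        for _ in range(10):
            p = random_rates(rng)
            init = random_state(rng)
            times = np.array([5.0, 20.0, 45.0, 75.0, 90.0])
            tr = simulate_pulse_chase(p, init, times)
            rs, ri, rf = ivp_oracle(p, init, times, synthesis=False)
            assert np.allclose(tr.r_s, rs, rtol=1e-6, atol=1e-9)
            assert np.allclose(tr.r_i, ri, rtol=1e-6, atol=1e-9)


class TestSteadyState:
    def test_worked_example(self):
        ss = steady_state(EXAMPLE)
        assert ss.r_s == pytest.approx(16666.67, abs=0.01)
        assert ss.r_i == pytest.approx(8333.33, abs=0.01)

    def test_two_step_chain_limit(self):
        p = RateParams(P_syn=120, k_deg=0.02, k_end=0.004, k_rec=0.0,
                       k_shed=0.0)
        ss = steady_state(p)
        assert ss.r_s == pytest.approx(p.P_syn / p.k_end, rel=1e-12)
        assert ss.r_i == pytest.approx(p.P_syn / p.k_deg, rel=1e-12)

    def test_degenerate_drain_raises(self):
        p = RateParams(P_syn=10, k_deg=0.0, k_end=0.01, k_rec=0.01,
                       k_shed=0.0)
        with pytest.raises(NoSteadyStateError):
            steady_state(p)
        with pytest.raises(NoSteadyStateError):
            steady_state(EXAMPLE.replace(P_syn=0.0))

    def test_surface_fraction_consistent_with_fixed_point(self):
        ss = steady_state(EXAMPLE)
        assert steady_surface_fraction(EXAMPLE) == pytest.approx(
            ss.r_s / (ss.r_s + ss.r_i), rel=1e-12)


class TestDerivedObservables:
    def test_arithmetic(self):
        tr = Trajectory(times=np.array([0.0]), r_s=np.array([75.0]),
                        r_i=np.array([25.0]), r_f=np.array([10.0]))
        df = derived_observables(tr)
        assert df["percent_shed"].iloc[0] == pytest.approx(0.10)
        assert df["surface_fraction"].iloc[0] == pytest.approx(0.75)

    def test_zero_supernatant(self):
        tr = Trajectory(times=np.array([0.0]), r_s=np.array([5.0]),
                        r_i=np.array([5.0]), r_f=np.array([0.0]))
        assert derived_observables(tr)["percent_shed"].iloc[0] == 0.0

    def test_day_long_shedding_fraction(self):
        ss = steady_state(EXAMPLE)
        tr = simulate_full(EXAMPLE, CompartmentState(r_s=ss.r_s, r_i=ss.r_i),
                           [1440])
        df = derived_observables(tr)
        # r_f = 0.001 * 16666.67 * 1440 = 24000 over r_t = 25000
        assert df["percent_shed"].iloc[0] == pytest.approx(0.96, abs=1e-6)

    def test_zero_total_rejected(self):
        tr = Trajectory(times=np.array([0.0]), r_s=np.array([0.0]),
                        r_i=np.array([0.0]), r_f=np.array([1.0]))
        with pytest.raises(ValueError):
            derived_observables(tr)

    def test_tidy_export_schema(self):
        tr = simulate_full(EXAMPLE, CompartmentState(r_s=100, r_i=10),
                           [5, 10])
        df = tr.to_frame()
        assert list(df.columns) == ["time_min", "r_s", "r_i", "r_f", "r_t"]
        assert np.allclose(df["r_t"], df["r_s"] + df["r_i"])
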