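"""Forward five-compartment model: right-hand sides, solver, oracle, metrics."""

import dataclasses

import numpy as np
import pytest
from scipy.linalg import expm

from nanodox import (ConfigurationError, ForwardState, InputError,
                     forward_rhs, load_defaults, peak_metrics,
                     simulate_forward, two_compartment_closed_form)
from nanodox.forward import ForwardTrajectory, default_grid


def zeroed_rates(p):
    f = dataclasses.replace(p.forward, k12=0, k21=0, k10=0, ps=0,
                            k1wi=0, k2wi=0, k3wi=0, k5wi=0, Fpv_t=0.0)
    return f


class TestForwardRhs:
    def test_zero_rates_give_zero_derivative(self, defaults):
        f = zeroed_rates(defaults)
        state = ForwardState(w1=1.0, w3=0.5, w2=0.3, w4=0.2, w5=0.1)
        assert np.allclose(forward_rhs(state, f), 0.0)

    @pytest.mark.parametrize("mode", ["mass_consistent", "as_printed"])
    def test_zero_state_is_stationary(self, defaults, mode):
        assert np.allclose(
            forward_rhs(np.zeros(5), defaults.forward, mode), 0.0)

    def test_fresh_bolus_feeds_tumor_plasma_only(self, defaults):
        # w1 = 0.007, all others zero: only perfusion into w2 is active
        f = defaults.forward
        d = forward_rhs([0.007, 0, 0, 0, 0], f, "mass_consistent")
        dw1, dw3, dw2, dw4, dw5 = d
        assert dw2 == pytest.approx(f.Fpv_t * 0.007)
        assert dw4 == 0.0 and dw5 == 0.0
        assert dw1 == pytest.approx(-(f.k12 + f.k10) * 0.007)
        assert dw3 == pytest.approx(f.k12 * 0.007)

    def test_unknown_mode_rejected(self, defaults):
        with pytest.raises(ConfigurationError):
            forward_rhs(np.zeros(5), defaults.forward, "upwind")

    def test_as_printed_ees_influx_sign_is_negative(self, defaults):
        """The published EES equation drains even when only w2 is loaded.

        This is the documented sign inconsistency: in ``as_printed`` the
        transvascular term enters the EES negatively, so w4 cannot rise
        from zero; ``mass_consistent`` flips it into an influx.
        """
        f = defaults.forward
        state = [0, 0, 1.0, 0, 0]  # only tumor plasma loaded
        printed = forward_rhs(state, f, "as_printed")
        fixed = forward_rhs(state, f, "mass_consistent")
        i_w4 = 3
        assert printed[i_w4] == pytest.approx(-(f.ps / f.Ve_t) * 1.0 * f.UDOX)
        assert fixed[i_w4] == pytest.approx(+(f.ps / f.Ve_t) * 1.0 * f.UDOX)

    def test_as_printed_reproduces_published_coefficients(self, defaults):
        """Verbatim check of each printed term at a generic state."""
        f = defaults.forward
        w1, w3, w2, w4, w5 = 0.1, 0.2, 0.3, 0.05, 0.02
        d = forward_rhs([w1, w3, w2, w4, w5], f, "as_printed")
        w4e = w4 * f.UDOXe
        exp_dw2 = (-(f.ps / f.Vp_t) * w2 * f.UDOX
                   + (f.ps / f.Vp_t) * w4e
                   - f.Fpv_t * w2 + f.Fpv_t * w1)
        exp_dw4 = (-(f.ps / f.Ve_t) * w2 * f.UDOX
                   - (f.ps / f.Ve_t) * w4e
                   - f.k3wi * ((f.k1wi * w4e + f.k2wi * w4e) / (f.kiwi + w4e)
                               - f.k5wi * w5))
        exp_dw5 = f.k3wi * (f.k1wi * w4 + f.k2wi * w4 / (f.kiwi + w4)
                            - f.k5wi * w5)
        assert d[2] == pytest.approx(exp_dw2, rel=1e-14)
        assert d[3] == pytest.approx(exp_dw4, rel=1e-14)
        assert d[4] == pytest.approx(exp_dw5, rel=1e-14)


class TestClosedForm:
    def test_initial_condition(self):
        w1, w3 = two_compartment_closed_form(9.4e-3, 7.052e-5, 2.1e-3,
                                             0.007, 0.0)
        assert w1 == pytest.approx(0.007)
        assert w3 == pytest.approx(0.0, abs=1e-18)

    def test_all_zero_rates_are_static(self):
        w1, w3 = two_compartment_closed_form(0, 0, 0, 0.5, 123.0)
        assert (w1, w3) == (0.5, 0.0)

    def test_matches_independent_matrix_exponential(self, rng):
        for _ in range(30):
            k12, k21, k10 = rng.uniform(1e-5, 0.5, size=3)
            w0 = rng.uniform(0.01, 1.0)
            t = rng.uniform(0.0, 2000.0)
            w1, w3 = two_compartment_closed_form(k12, k21, k10, w0, t)
            A = np.array([[-(k12 + k10), k21], [k12, -k21]])
            ref = expm(A * t) @ [w0, 0.0]
            assert w1 == pytest.approx(ref[0], rel=1e-9, abs=1e-15)
            assert w3 == pytest.approx(ref[1], rel=1e-9, abs=1e-15)

    def test_default_constants_at_t100(self):
        k12, k21, k10, w0 = 9.4e-3, 7.052e-5, 2.1e-3, 0.007
        A = np.array([[-(k12 + k10), k21], [k12, -k21]])
        ref = expm(A * 100.0) @ [w0, 0.0]
        w1, w3 = two_compartment_closed_form(k12, k21, k10, w0, 100.0)
        assert (w1, w3) == pytest.approx(tuple(ref), rel=1e-10)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InputError):
            two_compartment_closed_form(-1e-3, 0, 0, 0.1, 1.0)


class TestSimulateForward:
    def test_systemic_subsystem_tracks_closed_form(self, defaults,
                                                   forward_traj):
        f = defaults.forward
        w1, w3 = two_compartment_closed_form(f.k12, f.k21, f.k10, f.w1_init,
                                             forward_traj.time)
        scale = f.w1_init
        assert np.max(np.abs(forward_traj.column("w1") - w1)) < 1e-6 * scale
        assert np.max(np.abs(forward_traj.column("w3") - w3)) < 1e-6 * scale

    def test_conservation_without_elimination_or_perfusion(self, defaults):
        f = dataclasses.replace(defaults.forward, k10=0.0, Fpv_t=0.0)
        traj = simulate_forward(f)
        total = traj.states.sum(axis=1)  # w2,w4,w5 stay 0; w1+w3 conserved
        assert np.max(np.abs(total - f.w1_init)) < 1e-8

    def test_concentrations_stay_nonnegative(self, forward_traj):
        assert forward_traj.states.min() >= -1e-12

    def test_interior_maxima_in_tumor_compartments(self, forward_traj):
        t_end = forward_traj.time[-1]
        for name in ("w4", "w5"):
            series = forward_traj.column(name)
            t_peak = forward_traj.time[np.argmax(series)]
            assert 0.0 < t_peak < t_end
            assert series[-1] < series.max()

    def test_doubling_permeability_raises_intracellular_peak(self, defaults):
        base = simulate_forward(defaults)
        doubled = simulate_forward(
            defaults.with_value("ps", defaults.forward.ps * 2))
        assert doubled.column("w5").max() > base.column("w5").max()

    def test_deterministic_given_identical_inputs(self, defaults):
        a = simulate_forward(defaults)
        b = simulate_forward(defaults)
        assert np.array_equal(a.states, b.states)

    def test_first_state_equals_initial_condition(self, defaults):
        init = ForwardState(w1=0.01, w2=0.001)
        traj = simulate_forward(defaults.forward, init=init,
                                grid=default_grid(100.0, 11))
        assert np.allclose(traj.states[0], init.as_vector())

    def test_invalid_inputs_rejected(self, defaults):
        with pytest.raises(InputError):
            simulate_forward(defaults, grid=np.array([0.0, 2.0, 1.0]))
        with pytest.raises(InputError):
            simulate_forward(defaults.forward, init=[-1, 0, 0, 0, 0])
        with pytest.raises(ConfigurationError):
            simulate_forward(defaults, mode="unknown")


class TestPeakMetrics:
    def test_constant_trajectory(self):
        t = np.linspace(0, 10, 11)
        states = np.full((11, 5), 2.0)
        pm = peak_metrics(ForwardTrajectory(t, states))
        assert pm["w1"]["peak"] == 2.0
        assert pm["w1"]["auc"] == pytest.approx(20.0)

    def test_monotone_decreasing_series_peaks_at_zero(self, forward_traj):
        assert peak_metrics(forward_traj)["w1"]["peak_time"] == 0.0

    def test_downstream_compartments_peak_later(self, forward_traj):
        pm = peak_metrics(forward_traj)
        assert pm["w5"]["peak_time"] > pm["w2"]["peak_time"]
        assert pm["w4"]["peak_time"] > pm["w2"]["peak_time"]
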