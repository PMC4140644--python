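"""Point-membrane model: resting state, quasi-active admittance, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from dres.membrane import (ImpedanceSpectrum, KLTKinetics, MembraneSpec,
                           MembraneError, impedance_spectrum, nonlinear_rhs,
                           resonance_metrics, resonance_of, resting_state)

from oracles import state_space_admittance


# ---------------------------------------------------------------------------
# resting state
# ---------------------------------------------------------------------------

class TestRestingState:
    def test_passive_rest_equals_leak_reversal(self):
        m = MembraneSpec(g_l=0.5, e_l=-68.0, g_h=0.0,
                         klt=KLTKinetics(gbar=0.0))
        assert resting_state(m).v_rest == pytest.approx(-68.0, abs=1e-9)

    def test_two_leaks_rest_at_conductance_weighted_mean(self):
        m = MembraneSpec(g_l=0.7, e_l=-80.0, g_h=0.7, e_h=-43.0,
                         klt=KLTKinetics(gbar=0.0))
        assert resting_state(m).v_rest == pytest.approx((-80.0 - 43.0) / 2, abs=1e-9)

    def test_rest_is_root_of_current_balance(self, ref_membrane):
        op = resting_state(ref_membrane)
        assert abs(ref_membrane.steady_current(op.v_rest)) < 1e-10

    def test_rest_matches_time_domain_settling(self, ref_membrane):
        """A 500 ms nonlinear simulation settles onto the analytic rest."""
        m = ref_membrane
        y0 = [-60.0, float(m.klt.w_inf(-60.0)), float(m.klt.z_inf(-60.0))]
        sol = solve_ivp(lambda t, y: nonlinear_rhs(m, *y), (0, 500.0), y0,
                        rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(resting_state(m).v_rest, abs=0.01)

    def test_no_root_raises(self):
        m = MembraneSpec(g_l=0.5, e_l=-20.0, g_h=0.0, klt=KLTKinetics(gbar=0.0))
        with pytest.raises(MembraneError, match="bracket"):
            resting_state(m, bracket=(-120.0, -30.0))


# ---------------------------------------------------------------------------
# linearized admittance
# ---------------------------------------------------------------------------

class TestAdmittance:
    def test_dc_admittance_equals_numeric_current_slope(self, ref_membrane):
        op = resting_state(ref_membrane)
        h = 1e-4
        slope = (ref_membrane.steady_current(op.v_rest + h)
                 - ref_membrane.steady_current(op.v_rest - h)) / (2 * h)
        assert complex(op.admittance(0.0)).real == pytest.approx(slope, rel=1e-6)
        assert abs(complex(op.admittance(0.0)).imag) < 1e-12

    def test_passive_membrane_is_rc(self, passive_membrane):
        op = resting_state(passive_membrane)
        f = np.array([0.0, 50.0, 400.0])
        y = op.admittance(f)
        expected = (passive_membrane.g_l + passive_membrane.g_h
                    + 2j * np.pi * f * 1e-3 * passive_membrane.c_m)
        np.testing.assert_allclose(y, expected, rtol=1e-12)

    @pytest.mark.parametrize("f", [10.0, 100.0, 300.0, 1000.0])
    def test_matches_state_space_oracle(self, ref_membrane, f):
        """Full-mode Y(f) equals the resolvent of the linearized 3-state ODE."""
        op = resting_state(ref_membrane)
        y_pkg = complex(op.admittance(f, mode="full"))
        y_ora = complex(state_space_admittance(ref_membrane, f)[0])
        assert abs(y_pkg - y_ora) / abs(y_ora) < 1e-6

    def test_negative_frequency_conjugate_symmetry(self, ref_membrane):
        op = resting_state(ref_membrane)
        for f in (25.0, 310.0):
            assert complex(op.admittance(-f)) == pytest.approx(
                np.conj(complex(op.admittance(f))))

    def test_full_vs_simplified_peak_within_2pct(self, ref_membrane):
        """Dropping slow inactivation barely moves the resonance (12.5 Hz
        corner is far below f_R)."""
        op = resting_state(ref_membrane)
        full = resonance_of(lambda f: op.impedance(f, mode="full"))
        simp = resonance_of(lambda f: op.impedance(f, mode="simplified"))
        assert abs(simp.f_r - full.f_r) / full.f_r < 0.02


# ---------------------------------------------------------------------------
# spectra and resonance metrics
# ---------------------------------------------------------------------------

class TestResonance:
    def test_passive_magnitude_strictly_decreasing(self, passive_membrane,
                                                   coarse_grid):
        spec = impedance_spectrum(passive_membrane, coarse_grid)
        mag = np.abs(spec.z)
        assert np.all(np.diff(mag) < 0)
        met = resonance_metrics(spec)
        assert not met.is_resonant and met.f_r == 0.0

    def test_reference_has_single_interior_peak_above_cutoff(self, ref_membrane):
        op = resting_state(ref_membrane)
        spec = impedance_spectrum(ref_membrane, op=op)
        mag = np.abs(spec.z)
        # exactly one interior maximum (slow inactivation may add a small
        # low-frequency shoulder, i.e. one interior minimum)
        d = np.sign(np.diff(mag))
        maxima = np.sum((d[:-1] > 0) & (d[1:] < 0))
        assert maxima == 1
        met = resonance_metrics(spec)
        assert met.is_resonant
        assert met.f_r > op.f_eff

    def test_piecewise_linear_peak_and_q(self):
        """Synthetic magnitude with known half-power points at 60/160 Hz."""
        f = np.linspace(10.0, 400.0, 1954)
        lvl = 1.0 / np.sqrt(2.0)
        left = 1.0 + (f - 100.0) * (1.0 - lvl) / 40.0
        right = 1.0 - (f - 100.0) * (1.0 - lvl) / 60.0
        mag = np.clip(np.minimum(left, right), 0.05, None)
        met = resonance_metrics(ImpedanceSpectrum(f_hz=f, z=mag.astype(complex)))
        assert met.f_r == pytest.approx(100.0, abs=0.5)
        assert met.f_minus == pytest.approx(60.0, abs=0.5)
        assert met.f_plus == pytest.approx(160.0, abs=0.5)
        assert met.q == pytest.approx(1.0, abs=0.02)

    def test_resonance_monotone_in_gbar_and_leak_reversal(self, ref_membrane):
        def f_r(mem):
            op = resting_state(mem)
            return resonance_of(lambda f: op.impedance(f)).f_r

        by_gbar = [f_r(ref_membrane.with_updates(klt_gbar=g))
                   for g in (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)]
        assert np.all(np.diff(by_gbar) > 0)
        by_el = [f_r(ref_membrane.with_updates(g_l=1.0, e_l=e))
                 for e in (-75.0, -70.0, -65.0, -60.0, -55.0)]
        assert np.all(np.diff(by_el) > 0)

    def test_parameter_plane_spans_threefold_frequency_range(self, ref_membrane):
        """Across a plausible leak-reversal x KLT-density plane the patch
        resonance spans roughly a threefold range."""
        frs = []
        for e_l in np.linspace(-78.0, -56.0, 5):
            for gbar in np.geomspace(2.0, 30.0, 5):
                op = resting_state(ref_membrane.with_updates(g_l=1.0, e_l=e_l,
                                                             klt_gbar=gbar))
                met = resonance_of(lambda f: op.impedance(f))
                if met.is_resonant:
                    frs.append(met.f_r)
        assert len(frs) >= 8
        assert max(frs) / min(frs) > 2.5

    def test_f_r_above_f_eff_across_resonant_sample(self, ref_membrane):
        for gbar in (8.0, 15.0, 25.0):
            for g_h in (0.2, 0.5, 1.0):
                m = ref_membrane.with_updates(g_h=g_h, klt_gbar=gbar)
                op = resting_state(m)
                met = resonance_of(lambda f: op.impedance(f))
                if met.is_resonant:
                    assert met.f_r > op.f_eff


# ---------------------------------------------------------------------------
# nonlinear dynamics
# ---------------------------------------------------------------------------

class TestNonlinearRhs:
    def test_rest_is_fixed_point(self, ref_membrane):
        op = resting_state(ref_membrane)
        d = nonlinear_rhs(ref_membrane, op.v_rest, op.w_inf, op.z_inf, 0.0)
        assert max(abs(x) for x in d) < 1e-10

    def test_small_perturbation_decays_at_linear_rate(self, ref_membrane):
        """The slowest relaxation mode matches the linearized Jacobian."""
        m = ref_membrane
        op = resting_state(m)
        eps = 1e-4
        jac = np.empty((3, 3))
        x0 = np.array([op.v_rest, op.w_inf, op.z_inf])
        for j in range(3):
            dx = np.zeros(3)
            dx[j] = eps
            jac[:, j] = (np.array(nonlinear_rhs(m, *(x0 + dx)))
                         - np.array(nonlinear_rhs(m, *(x0 - dx)))) / (2 * eps)
        lam = np.linalg.eigvals(jac)
        slowest = max(lam.real)
        assert slowest < 0                       # rest is stable
        sol = solve_ivp(lambda t, y: nonlinear_rhs(m, *y), (0.0, 40.0),
                        x0 + [0.01, 0.0, 0.0], rtol=1e-10, atol=1e-12,
                        t_eval=[20.0, 40.0])
        dv = sol.y[0] - op.v_rest
        rate = np.log(abs(dv[1] / dv[0])) / 20.0
        assert rate == pytest.approx(slowest, rel=0.05)

    def test_step_current_settles_on_shifted_root(self, ref_membrane):
        m = ref_membrane
        i_inj = 0.5   # uA/cm^2
        sol = solve_ivp(lambda t, y: nonlinear_rhs(m, *y, i_inj=i_inj),
                        (0, 500.0),
                        [resting_state(m).v_rest,
                         resting_state(m).w_inf, resting_state(m).z_inf],
                        rtol=1e-10, atol=1e-12)
        from scipy.optimize import brentq
        v_new = brentq(lambda v: m.steady_current(v) - i_inj, -120, -30,
                       xtol=1e-12)
        assert sol.y[0, -1] == pytest.approx(v_new, abs=1e-3)


# ---------------------------------------------------------------------------
# kinetics invariants (property-based)
# ---------------------------------------------------------------------------

@settings(max_examples=30, deadline=None, derandomize=True)
@given(w_half=st.floats(-80, -30), w_slope=st.floats(2, 15),
       z_half=st.floats(-90, -50), z_slope=st.floats(4, 20),
       z_floor=st.floats(0.0, 0.9))
def test_gating_curves_are_bounded_and_monotone(w_half, w_slope, z_half,
                                                z_slope, z_floor):
    k = KLTKinetics(w_half=w_half, w_slope=w_slope, z_half=z_half,
                    z_slope=z_slope, z_floor=z_floor)
    v = np.linspace(-120.0, 20.0, 200)
    w, z = k.w_inf(v), k.z_inf(v)
    # open-interval bounds saturate in floating point at extreme voltages
    assert np.all((w >= 0) & (w <= 1)) and np.all((z >= 0) & (z <= 1))
    assert np.all(np.diff(w) >= 0) and np.all(np.diff(z) <= 0)
    assert np.all(k.tau_w(v) > 0) and np.all(k.tau_z(v) > 0)
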