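"""Forward dynamics against closed-form oracles and physical invariants."""

import numpy as np
import pytest

from neckdyn import dynamics
from neckdyn.dynamics import (
    bushing_wrench,
    compile_model,
    extract_joint_series,
    mechanical_energy,
    simulate,
    state_derivative,
    static_equilibrium,
)
from neckdyn.model import State, default_bushing_init
from neckdyn.signals import ForceTrace

from conftest import make_oscillator


def zero_load(duration=0.04, fs=1e6):
    return ForceTrace(np.zeros(int(fs * duration) + 1), fs=fs)


class TestBushingWrench:
    def test_zero_deflection_zero_wrench(self):
        w_cr, w_ca = bushing_wrench(default_bushing_init(), np.zeros(6),
                                    np.zeros(6))
        np.testing.assert_allclose(w_cr, 0.0)
        np.testing.assert_allclose(w_ca, 0.0)

    def test_axial_stiffness_restoring_force(self):
        # 1 mm compression against k_y = 25.2 MN/m -> +25.2 kN restoring
        b = default_bushing_init()
        b.k_trans[1] = 25.2e6
        d = np.zeros(6)
        d[1] = -1.0e-3
        w_cr, w_ca = bushing_wrench(b, d, np.zeros(6))
        assert w_cr[1] == pytest.approx(25_200.0)
        np.testing.assert_allclose(w_ca, -w_cr)

    def test_axial_damping_force(self):
        b = default_bushing_init()
        b.b_trans[1] = 6.1e3
        rate = np.zeros(6)
        rate[1] = -0.5
        w_cr, _ = bushing_wrench(b, np.zeros(6), rate)
        assert w_cr[1] == pytest.approx(3_050.0)

    def test_component_formula(self):
        b = default_bushing_init()
        d = np.array([1e-3, -2e-3, 0.5e-3, 0.01, -0.02, 0.005])
        rate = np.array([0.1, -0.2, 0.05, 1.0, -2.0, 0.5])
        w_cr, _ = bushing_wrench(b, d, rate)
        k = np.concatenate([b.k_trans, b.k_rot])
        c = np.concatenate([b.b_trans, b.b_rot])
        np.testing.assert_allclose(w_cr, -k * d - c * rate)


class TestOscillatorOracle:
    def test_half_period_returns_mirrored_position(self):
        # undamped: x(T/2) = -x0 with omega = 100 rad/s
        model = make_oscillator(mass=1.0, k=1e4, b=0.0)
        t_half = np.pi / 100.0
        res = simulate(model, zero_load(), window_s=t_half,
                       initial_state=State([1e-3], [0.0]),
                       output_times=np.array([0.0, t_half]))
        assert res.body_q[-1, 1] == pytest.approx(-1e-3, abs=1e-6)

    def test_underdamped_matches_closed_form(self):
        m, k, b = 1.0, 1e4, 50.0
        model = make_oscillator(mass=m, k=k, b=b)
        w0 = np.sqrt(k / m)
        zeta = b / (2 * np.sqrt(k * m))
        wd = w0 * np.sqrt(1 - zeta**2)
        x0 = 1e-3
        times = np.linspace(0, 0.005, 51)
        res = simulate(model, zero_load(), window_s=0.005,
                       initial_state=State([x0], [0.0]), output_times=times)
        exact = x0 * np.exp(-zeta * w0 * times) * (
            np.cos(wd * times) + zeta * w0 / wd * np.sin(wd * times))
        # relative error against the closed-form damped oscillator
        assert np.max(np.abs(res.body_q[:, 1] - exact)) <= 1e-6 * x0

    def test_critical_damping_no_zero_crossing(self):
        m, k = 1.0, 1e4
        model = make_oscillator(mass=m, k=k, b=2 * np.sqrt(k * m))
        times = np.linspace(0, 0.1, 401)
        res = simulate(model, zero_load(duration=0.11), window_s=0.1,
                       initial_state=State([1e-3], [0.0]), output_times=times)
        assert np.all(res.body_q[:, 1] > 0.0)

    def test_static_deflection_limit(self):
        # constant compressive load F -> displacement -F/k as t -> inf
        m, k = 1.0, 1e4
        model = make_oscillator(mass=m, k=k, b=2 * np.sqrt(k * m))
        F = 10.0
        load = ForceTrace(np.full(120_001, F), fs=1e6)
        res = simulate(model, load, window_s=0.12,
                       initial_state=State([0.0], [0.0]),
                       output_times=np.array([0.0, 0.12]))
        disp = extract_joint_series(res, "MASS-BASE", "axial_displacement")
        assert disp[-1] == pytest.approx(-F / k, rel=1e-4)


class TestStateDerivative:
    def test_equilibrium_has_zero_acceleration(self, clean_compiled):
        eq = static_equilibrium(clean_compiled)
        rate = state_derivative(clean_compiled, eq)
        np.testing.assert_allclose(rate.u, 0.0, atol=1e-5)
        np.testing.assert_allclose(rate.q, 0.0, atol=1e-12)

    def test_single_mass_newton_law(self):
        # a = (-F_ext - k q - b u)/m - g - preload/m for the 1-DoF chain
        m, k, b, pre = 2.0, 1e4, 30.0, 10.0
        model = make_oscillator(mass=m, k=k, b=b, gravity=True, preload_N=pre)
        q, u, fext = 2e-3, -0.1, 5.0
        rate = state_derivative(model, State([q], [u]), external_force_N=fext)
        expected = (-fext - k * q - b * u - pre) / m - 9.81
        assert rate.u[0] == pytest.approx(expected, rel=1e-12)
        assert rate.q[0] == pytest.approx(u)

    def test_doubling_mass_halves_acceleration(self):
        q = State([1e-3], [0.0])
        a1 = state_derivative(make_oscillator(mass=1.0), q).u[0]
        a2 = state_derivative(make_oscillator(mass=2.0), q).u[0]
        assert a2 == pytest.approx(a1 / 2.0, rel=1e-12)


class TestSimulate:
    def test_equilibrium_is_fixed_point(self, clean_compiled):
        res = simulate(clean_compiled, zero_load(duration=0.006),
                       window_s=0.005)
        drift = np.abs(res.markers.positions - res.markers.positions[0])
        assert drift.max() < 1e-9

    def test_energy_non_increasing_without_drive(self, clean_compiled):
        eq = static_equilibrium(clean_compiled)
        q = eq.q.copy()
        q[0] -= 2e-4   # axial push of the cranial segment
        n_out = 101
        times = np.linspace(0, 0.005, n_out)
        res = simulate(clean_compiled, zero_load(duration=0.006),
                       window_s=0.005, initial_state=State(q, np.zeros_like(q)),
                       output_times=times)
        E = np.array([mechanical_energy(clean_compiled, res.body_q[i],
                                        res.body_u[i]) for i in range(n_out)])
        scale = np.abs(E - E[-1]).max() + 1e-12
        assert np.all(np.diff(E) <= 1e-6 * scale)

    def test_step_halving_convergence(self, clean_bundle, clean_window):
        c = compile_model(clean_bundle.model)
        fw, _ = clean_window
        r1 = simulate(c, fw, window_s=0.005, dt=1e-6)
        r2 = simulate(c, fw, window_s=0.005, dt=5e-7)
        diff = np.abs(r1.markers.positions[-1] - r2.markers.positions[-1])
        assert diff.max() < 1e-8

    def test_load_shorter_than_window_raises(self, clean_compiled):
        with pytest.raises(ValueError, match="shorter"):
            simulate(clean_compiled, zero_load(duration=0.002), window_s=0.005)

    def test_divergence_raises_with_flag(self):
        # overdamped beyond the explicit scheme's stability limit
        model = make_oscillator(mass=1e-3, k=1e4, b=1e5)
        with pytest.raises(FloatingPointError, match="diverged"):
            simulate(model, zero_load(duration=0.006), window_s=0.005,
                     initial_state=State([1e-3], [0.0]))


class TestJointSeries:
    def test_displacement_zero_at_equilibrium_reference(self, clean_compiled,
                                                        clean_bundle):
        res = simulate(clean_compiled, zero_load(duration=0.006),
                       window_s=0.005)
        for j in res.joint_names:
            for ch in ("axial_displacement", "shear_displacement"):
                assert abs(extract_joint_series(res, j, ch)[0]) < 1e-12

    def test_equilibrium_force_equals_preload_share(self, clean_bundle,
                                                    clean_compiled):
        # at static equilibrium the world-frame bushing force on the cranial
        # side of each joint balances the preload plus the weight above it
        model = clean_bundle.model
        c = clean_compiled
        eq = static_equilibrium(c)
        Q = c.full_from_free(eq.q)
        _, _, w = dynamics.joint_state(c, Q, np.zeros_like(Q))
        P, R = dynamics._poses_from_full(c, Q)
        g = 9.81
        for idx, jf in enumerate(model.joints):
            above = sum(model.segments[k].mass for k in range(idx + 1))
            total = model.preload.total_N + g * above
            RJ = R[c.jca[idx]] @ c.jRjc[idx]
            f_world = RJ @ w[idx, :3]
            # x/z components balance the C2 slider's rig reaction; the
            # vertical component carries exactly the preload plus weight
            assert f_world[1] == pytest.approx(total, rel=1e-9)
            # the joint-frame axial channel carries nearly all of it
            axial = extract_joint_series(
                simulate(c, zero_load(duration=0.006), window_s=0.005),
                jf.name, "axial_force")[0]
            assert axial == pytest.approx(total, rel=0.02)

    def test_unknown_channel_and_joint_raise(self, clean_compiled):
        res = simulate(clean_compiled, zero_load(duration=0.006),
                       window_s=0.005)
        with pytest.raises(KeyError):
            extract_joint_series(res, res.joint_names[0], "bogus")
        with pytest.raises(KeyError):
            extract_joint_series(res, "C9-C10", "axial_force")

    def test_joint_state_matches_bushing_wrench(self, clean_bundle,
                                                clean_compiled):
        rng = np.random.default_rng(4)
        nfull = 6 * clean_compiled.n_bodies
        Q = rng.uniform(-5e-3, 5e-3, nfull)
        U = rng.uniform(-0.5, 0.5, nfull)
        d, rate, w = dynamics.joint_state(clean_compiled, Q, U)
        for j, bu in enumerate(clean_bundle.model.bushings):
            w_cr, _ = bushing_wrench(bu, d[j], rate[j])
            np.testing.assert_allclose(w[j], w_cr, rtol=1e-12, atol=1e-12)
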