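"""Perturbation analyses: set sweeps, Monte Carlo, surfaces, frame shifts."""

import numpy as np
import pytest

from neckdyn.sensitivity import (
    SET_PAIRS,
    PerturbationSample,
    fit_pair_surface,
    perturb_sets,
    run_monte_carlo,
    shift_joint_frames,
    sweep_individual_set,
    sweep_joint_frame_positions,
)
from neckdyn.validate import SET_NAMES


class TestPerturbSets:
    def test_zero_perturbation_identity(self):
        p = np.arange(1.0, 17.0)
        np.testing.assert_array_equal(perturb_sets(p, np.zeros(4)), p)

    def test_lower_bound_halves_everything(self):
        p = np.arange(1.0, 17.0)
        np.testing.assert_allclose(perturb_sets(p, np.full(4, -0.5)), p / 2)

    def test_set_isolation(self):
        p = np.ones(16)
        out = perturb_sets(p, np.array([0.5, 0.0, 0.0, 0.0]))
        np.testing.assert_allclose(out[0:4], 1.5)
        np.testing.assert_allclose(out[4:], 1.0)

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="0.5"):
            perturb_sets(np.ones(16), np.array([0.6, 0, 0, 0]))


class TestIndividualSweep:
    def test_unit_scale_recovers_optimum(self, clean_bundle, clean_compiled,
                                         clean_window):
        df = sweep_individual_set(clean_compiled, clean_window,
                                  clean_bundle.truth, "axial_stiffness",
                                  grid=3)
        assert len(df) == 3
        mid = df[np.isclose(df["scale"], 1.0)]["rmse_mm"].iloc[0]
        assert mid < 1e-6
        # away from the optimum the tracking error strictly increases
        assert (df[~np.isclose(df["scale"], 1.0)]["rmse_mm"] > mid).all()

    def test_grid_size(self, clean_bundle, clean_compiled, clean_window):
        df = sweep_individual_set(clean_compiled, clean_window,
                                  clean_bundle.truth, "shear_damping", grid=5)
        assert len(df) == 5
        np.testing.assert_allclose(df["scale"].iloc[[0, -1]], [0.5, 1.5])

    def test_unknown_set_raises(self, clean_compiled, clean_window):
        with pytest.raises(KeyError):
            sweep_individual_set(clean_compiled, clean_window, np.ones(16),
                                 "bogus")


class TestMonteCarlo:
    def test_determinism_and_bounds(self, clean_bundle, clean_compiled,
                                    clean_window):
        kw = dict(n=8, seed=11)
        a = run_monte_carlo(clean_compiled, clean_window, clean_bundle.truth,
                            **kw)
        b = run_monte_carlo(clean_compiled, clean_window, clean_bundle.truth,
                            **kw)
        assert len(a) == 8
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.r, sb.r)
            assert sa.rmse_per_mm == sb.rmse_per_mm
            assert np.all(np.abs(sa.r) <= 0.5)

    def test_delta_rmse_nonnegative_at_truth(self, clean_bundle,
                                             clean_compiled, clean_window):
        # the generating parameters are the global optimum of the
        # noise-free objective, so every perturbation can only hurt
        samples = run_monte_carlo(clean_compiled, clean_window,
                                  clean_bundle.truth, n=25, seed=5)
        assert all(s.delta_rmse_mm >= 0.0 for s in samples)

    def test_invalid_count_raises(self, clean_compiled, clean_window):
        with pytest.raises(ValueError):
            run_monte_carlo(clean_compiled, clean_window, np.ones(16), n=0)


def _cubic_samples(coeffs, powers, pts):
    samples = []
    for ra, rb in pts:
        val = sum(c * ra**i * rb**j for c, (i, j) in zip(coeffs, powers))
        r = np.array([ra, rb, 0.0, 0.0])
        samples.append(PerturbationSample(r=r, p_i=np.ones(16),
                                          rmse_per_mm=val, delta_rmse_mm=val))
    return samples


class TestSurfaceFit:
    POWERS = tuple((i, j) for d in range(4) for i in range(d + 1)
                   for j in [d - i])

    def test_exact_cubic_recovery(self):
        rng = np.random.default_rng(2)
        coeffs = rng.normal(size=10)
        pts = rng.uniform(-0.5, 0.5, (40, 2))
        samples = _cubic_samples(coeffs, self.POWERS, pts)
        fit = fit_pair_surface(samples, (SET_NAMES[0], SET_NAMES[1]))
        np.testing.assert_allclose(fit.coefficients, coeffs, atol=1e-8)
        assert fit.residual_norm < 1e-8

    def test_constant_samples_give_intercept_only(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-0.5, 0.5, (30, 2))
        samples = _cubic_samples([4.2] + [0.0] * 9, self.POWERS, pts)
        fit = fit_pair_surface(samples, (SET_NAMES[0], SET_NAMES[1]))
        assert fit.coefficients[0] == pytest.approx(4.2, abs=1e-10)
        np.testing.assert_allclose(fit.coefficients[1:], 0.0, atol=1e-9)

    def test_too_few_samples_raise(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-0.5, 0.5, (9, 2))
        samples = _cubic_samples(np.ones(10), self.POWERS, pts)
        with pytest.raises(ValueError):
            fit_pair_surface(samples, (SET_NAMES[0], SET_NAMES[1]))

    def test_there_are_six_pairs(self):
        assert len(SET_PAIRS) == 6
        assert len({frozenset(p) for p in SET_PAIRS}) == 6

    def test_surfaces_vanish_at_origin_within_residual(self, clean_bundle,
                                                       clean_compiled,
                                                       clean_window):
        samples = run_monte_carlo(clean_compiled, clean_window,
                                  clean_bundle.truth, n=40, seed=9)
        for pair in SET_PAIRS[:2]:
            fit = fit_pair_surface(samples, pair)
            assert abs(fit(0.0, 0.0)) <= max(fit.residual_norm, 1e-9)


class TestJointFrameSweep:
    def test_zero_shift_recovers_optimum(self, clean_bundle, clean_window):
        df = sweep_joint_frame_positions(clean_bundle.model, clean_window,
                                         clean_bundle.truth, grid=3)
        assert len(df) == 3
        np.testing.assert_allclose(df["d_x_m"].iloc[[0, -1]], [-0.02, 0.02])
        mid = df[np.isclose(df["d_x_m"], 0.0)]["rmse_mm"].iloc[0]
        assert mid < 1e-6
        assert (df["rmse_mm"] >= mid - 1e-12).all()

    def test_shift_preserves_rest_coincidence(self, clean_bundle):
        # shifting a joint frame moves both attachment points identically,
        # so the rest configuration stays undeflected
        from neckdyn.dynamics import compile_model, joint_state
        shifted = compile_model(shift_joint_frames(clean_bundle.model, 0.015))
        Q = np.zeros(6 * shifted.n_bodies)
        d, _, _ = joint_state(shifted, Q, Q.copy())
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
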