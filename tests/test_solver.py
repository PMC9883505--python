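"""Energy evaluation, proximal blocks, and the primal-dual solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shvrestore as sr
from shvrestore import DegradationParams, RegularizationParams, SolverConfig

from oracles import dense_shv_value, smoothed_energy_minimizer


class TestShvValue:
    def test_rho_zero_is_intensity_sum(self, rng):
        u = rng.random((7, 7))
        assert sr.shv_value(u, 0.0) == pytest.approx(u.sum(), rel=1e-12)

    def test_constant_image_closed_form(self):
        u = np.full((6, 5), 0.8)
        assert sr.shv_value(u, 0.3) == pytest.approx(0.7 * 0.8 * 30, rel=1e-12)

    def test_impulse_matches_dense_oracle(self):
        u = np.zeros((3, 3))
        u[1, 1] = 1.0
        assert sr.shv_value(u, 0.5) == pytest.approx(dense_shv_value(u, 0.5), rel=1e-12)

    @pytest.mark.parametrize("shape,rho", [((5, 5), 0.6), ((4, 4, 3), 0.2)])
    def test_random_images_match_dense_oracle(self, rng, shape, rho):
        u = rng.random(shape)
        assert sr.shv_value(u, rho) == pytest.approx(dense_shv_value(u, rho), rel=1e-10)


class TestEnergy:
    def test_dirac_with_u_equal_f(self, rng):
        f = rng.random((6, 6))
        params = RegularizationParams(rho=0.6, lam=0.37)
        b = sr.energy(f, f, sr.dirac_psf((1, 1)), params)
        assert b.fidelity < 1e-20
        assert b.total == pytest.approx(0.37 * sr.shv_value(f, 0.6), rel=1e-12)

    def test_negative_pixel_flags_infinite_total(self, rng):
        f = rng.random((5, 5))
        u = f.copy()
        u[2, 3] = -1e-6
        b = sr.energy(u, f, sr.dirac_psf((1, 1)), RegularizationParams(0.5, 1.0))
        assert b.constraint_violation == 1
        assert b.total == np.inf
        assert np.isfinite(b.fidelity) and np.isfinite(b.regularizer)

    def test_lam_prime_consistency(self):
        p = RegularizationParams(rho=0.1, lam=4.0)
        assert p.lam_prime == pytest.approx(0.2, abs=1e-12)
        q = RegularizationParams.from_lam_prime(0.1, 0.2)
        assert q.lam == pytest.approx(4.0, rel=1e-12)

    def test_preset_map(self):
        from shvrestore.solver import resolve_sparsity

        assert resolve_sparsity("high") == 0.1
        assert resolve_sparsity("moderate") == 0.6
        assert resolve_sparsity("weak") == 0.9


class TestProxAndProjection:
    def test_small_field_unchanged_large_scaled(self):
        w = np.zeros((5, 4, 4))
        w[0] = 0.5
        out = sr.prox_dual_ball(w, radius=1.0)
        assert np.allclose(out, w)
        w[0] = 2.0  # per-pixel norm 2 > radius 1
        out = sr.prox_dual_ball(w, radius=1.0)
        assert np.allclose(out[0], 1.0)

    def test_norms_bounded_and_directions_preserved(self, rng):
        w = rng.standard_normal((5, 8, 8))
        lam = 0.7
        out = sr.prox_dual_ball(w, lam)
        norms = np.sqrt(np.sum(out**2, axis=0))
        assert np.all(norms <= lam + 1e-12)
        inner = np.sum(out * w, axis=0)
        assert np.all(inner >= -1e-12)  # no direction flips

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), radius=st.floats(0.05, 5.0))
    def test_prox_ball_is_a_projection(self, seed, radius):
        """Idempotent, nonexpansive, and never increases any pixel norm."""
        w = np.random.default_rng(seed).standard_normal((5, 6, 6))
        out = sr.prox_dual_ball(w, radius)
        twice = sr.prox_dual_ball(out, radius)
        assert np.allclose(out, twice, atol=1e-12)
        assert np.linalg.norm(out) <= np.linalg.norm(w) + 1e-12
        norms_in = np.sqrt(np.sum(w**2, axis=0))
        norms_out = np.sqrt(np.sum(out**2, axis=0))
        assert np.all(norms_out <= np.minimum(norms_in, radius) + 1e-12)

    def test_project_nonneg(self, rng):
        u = rng.standard_normal((6, 6))
        p = sr.project_nonneg(u)
        assert np.all(p >= 0)
        assert np.array_equal(sr.project_nonneg(p), p)
        assert np.all(sr.project_nonneg(-np.ones((3, 3))) == 0)


class TestRestore:
    def test_vanishing_regularization_returns_input(self, rng):
        f = rng.random((16, 16))
        u, _ = sr.restore(f, sr.dirac_psf((1, 1)), RegularizationParams(0.6, 1e-6))
        assert np.max(np.abs(u - f)) < 1e-3

    def test_dominant_regularizer_drives_to_zero(self, rng):
        f = rng.random((16, 16))
        cfg = SolverConfig(n_iterations=5000, record_energy_every=1000)
        u, _ = sr.restore(f, sr.dirac_psf((1, 1)), RegularizationParams(0.6, 1e3), cfg)
        assert u.mean() < 1e-3

    def test_iterates_feasible_and_energy_decreases(self, degraded_64):
        psf = sr.gaussian_psf(sigma_xy=1.0)
        u, trace = sr.restore(degraded_64, psf, RegularizationParams(0.1, 0.01))
        assert np.all(u >= 0)
        totals = trace.totals
        assert totals[-1] <= totals[0]
        # settled tail: last stretch of the 200 iterations varies slowly
        tail = totals[-10:]
        assert (max(tail) - min(tail)) / max(tail) < 1e-3

    def test_deterministic(self, degraded_64):
        psf = sr.gaussian_psf(sigma_xy=1.0)
        params = RegularizationParams(0.6, 0.05)
        u1, _ = sr.restore(degraded_64, psf, params)
        u2, _ = sr.restore(degraded_64, psf, params)
        assert np.array_equal(u1, u2)

    def test_invalid_user_steps_rejected_before_iterating(self, rng):
        f = rng.random((8, 8))
        cfg = SolverConfig(primal_step=10.0, dual_step=10.0)
        with pytest.raises(ValueError, match="convergence"):
            sr.restore(f, sr.dirac_psf((1, 1)), RegularizationParams(0.6, 0.1), cfg)

    def test_translation_equivariance_for_interior_content(self):
        """Periodic blur + interior support: restoring a shifted image shifts
        the restoration (boundary handling only sees zeros)."""
        u = np.zeros((32, 32))
        u[14:18, 14:18] = 0.8
        psf = sr.gaussian_psf((7, 7), sigma_xy=1.0)
        f = sr.convolve(u, psf)
        params = RegularizationParams(0.6, 0.05)
        r1, _ = sr.restore(f, psf, params)
        r2, _ = sr.restore(np.roll(f, (2, 3), (0, 1)), psf, params)
        assert np.max(np.abs(np.roll(r1, (2, 3), (0, 1)) - r2)) < 1e-8

    def test_matches_convex_oracle_energy(self, rng):
        """Final energy within 0.1% of a brute-force convex minimizer's."""
        spec = sr.PhantomSpec(kind="spots", shape=(8, 8), n_objects=1, object_scale=0.8, seed=3)
        u_true = sr.make_phantom(spec)
        psf = sr.gaussian_psf((7, 7), sigma_xy=1.0)
        f = sr.degrade(u_true, psf, DegradationParams(alpha=None, tau=0.01, seed=5))
        params = RegularizationParams(0.6, 0.05)
        u_pd, _ = sr.restore(f, psf, params, SolverConfig(3000, record_energy_every=3000))
        u_oracle = smoothed_energy_minimizer(f, psf.values, lam=0.05, rho=0.6)
        e_pd = sr.energy(u_pd, f, psf, params).total
        e_oracle = sr.energy(u_oracle, f, psf, params).total
        assert abs(e_pd - e_oracle) <= 1e-3 * e_oracle

    def test_energy_convex_along_chords(self, rng, small_gaussian_psf):
        f = rng.random((8, 8))
        params = RegularizationParams(0.4, 0.3)
        u1, u2 = rng.random((8, 8)), rng.random((8, 8))
        for theta in (0.25, 0.5, 0.75):
            mid = sr.energy(theta * u1 + (1 - theta) * u2, f, small_gaussian_psf, params).total
            ends = (
                theta * sr.energy(u1, f, small_gaussian_psf, params).total
                + (1 - theta) * sr.energy(u2, f, small_gaussian_psf, params).total
            )
            assert mid <= ends + 1e-10

    def test_trace_csv_export(self, tmp_path, rng):
        f = rng.random((8, 8))
        _, trace = sr.restore(f, sr.dirac_psf((1, 1)), RegularizationParams(0.6, 0.1))
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "iteration,fidelity,regularizer,total"
        assert len(lines) == len(trace.iterations) + 1
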