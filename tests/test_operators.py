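"""Convolution and second-order operators: oracles, adjoints, norms."""

import numpy as np
import pytest

import shvrestore as sr
from shvrestore.operators import hessian_norm_bound, n_hessian_components

from oracles import dense_hessian_matrix, direct_circular_convolve


class TestConvolve:
    def test_dirac_is_identity(self, rng):
        u = rng.random((8, 8))
        assert np.allclose(sr.convolve(u, sr.dirac_psf((1, 1))), u, atol=1e-13)

    def test_unit_dc_gain_on_constant(self, small_gaussian_psf):
        u = np.full((10, 10), 3.7)
        assert np.allclose(sr.convolve(u, small_gaussian_psf), 3.7, atol=1e-12)

    def test_matches_direct_sum_oracle(self, rng, small_gaussian_psf):
        u = rng.random((7, 7))
        expected = direct_circular_convolve(u, small_gaussian_psf.values)
        assert np.allclose(sr.convolve(u, small_gaussian_psf), expected, atol=1e-10)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            sr.convolve(np.zeros((5, 5)), sr.gaussian_psf((7, 7), sigma_xy=1.0))

    def test_symmetric_kernel_self_adjoint(self, rng, small_gaussian_psf):
        u = rng.random((8, 8))
        assert np.allclose(
            sr.convolve(u, small_gaussian_psf),
            sr.convolve_adjoint(u, small_gaussian_psf),
            atol=1e-12,
        )

    def test_adjoint_inner_product_identity(self, rng, small_gaussian_psf):
        u, w = rng.random((8, 8)), rng.random((8, 8))
        lhs = np.vdot(sr.convolve(u, small_gaussian_psf), w)
        rhs = np.vdot(u, sr.convolve_adjoint(w, small_gaussian_psf))
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_linearity(self, rng, small_gaussian_psf):
        u, v = rng.random((8, 8)), rng.random((8, 8))
        lhs = sr.convolve(2.0 * u - 3.0 * v, small_gaussian_psf)
        rhs = 2.0 * sr.convolve(u, small_gaussian_psf) - 3.0 * sr.convolve(v, small_gaussian_psf)
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestHessianOperator:
    def test_constant_image_keeps_only_intensity(self):
        u = np.full((6, 6), 2.5)
        field = sr.hessian_operator(u, rho=0.4)
        assert np.allclose(field.components[0], 0.6 * 2.5)
        assert np.allclose(field.components[1:], 0.0, atol=1e-14)

    def test_ramp_has_zero_pure_second_difference_inside(self):
        x = np.arange(8, dtype=float)
        u = np.tile(x, (8, 1))  # varies along axis 1
        field = sr.hessian_operator(u, rho=1.0)
        # component 2 is the pure second difference along axis 1
        d_xx = field.components[2]
        assert np.allclose(d_xx[:, 1:-1], 0.0, atol=1e-14)
        # rows at the axis-0 boundary are zero too: u does not vary along axis 0
        d_yy = field.components[1]
        assert np.allclose(d_yy, 0.0, atol=1e-14)

    @pytest.mark.parametrize("shape", [(5, 5), (4, 4, 3)])
    @pytest.mark.parametrize("rho", [0.0, 0.5, 1.0])
    def test_matches_dense_matrix_oracle(self, rng, shape, rho):
        u = rng.random(shape)
        field = sr.hessian_operator(u, rho)
        dense = dense_hessian_matrix(shape, rho)
        expected = (dense @ u.ravel()).reshape(field.components.shape)
        assert np.max(np.abs(field.components - expected)) < 1e-12

    def test_component_count_and_mixed_symmetry(self, rng):
        for ndim, shape in [(2, (5, 6)), (3, (4, 5, 3)), (4, (3, 3, 4, 4))]:
            u = rng.random(shape)
            field = sr.hessian_operator(u, 0.7)
            assert field.components.shape[0] == 1 + ndim * ndim
            # paired mixed components are equal (symmetric stencil)
            n_upper = ndim * (ndim - 1) // 2
            upper = field.components[1 + ndim : 1 + ndim + n_upper]
            lower = field.components[1 + ndim + n_upper :]
            assert np.array_equal(upper, lower)

    def test_rho_extremes(self, rng):
        u = rng.random((6, 6))
        f0 = sr.hessian_operator(u, 0.0)
        assert np.array_equal(f0.components[0], u)
        assert np.all(f0.components[1:] == 0)
        f1 = sr.hessian_operator(u, 1.0)
        assert np.all(f1.components[0] == 0)

    def test_invalid_rho(self):
        with pytest.raises(ValueError, match="rho"):
            sr.hessian_operator(np.zeros((4, 4)), 1.5)


class TestHessianAdjoint:
    @pytest.mark.parametrize("rho", [0.0, 0.5, 1.0])
    def test_inner_product_identity(self, rng, rho):
        u = rng.random((6, 6))
        field = sr.hessian_operator(u, rho)
        w = rng.standard_normal(field.components.shape)
        lhs = np.vdot(field.components, w)
        rhs = np.vdot(u, sr.hessian_adjoint(w, rho))
        assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), 1.0)

    def test_zero_field_and_intensity_only(self, rng):
        shape = (5, 5)
        w = np.zeros((n_hessian_components(2),) + shape)
        assert np.all(sr.hessian_adjoint(w, 0.3) == 0)
        img = rng.random(shape)
        w[0] = img
        assert np.allclose(sr.hessian_adjoint(w, 0.3), 0.7 * img, atol=1e-14)

    def test_component_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="components"):
            sr.hessian_adjoint(np.zeros((4, 5, 5)), 0.5)

    def test_time_weight_consistent_adjoint(self, rng):
        u = rng.random((3, 4, 4))  # TYX
        field = sr.hessian_operator(u, 0.6, time_axis=0, time_weight=0.5)
        w = rng.standard_normal(field.components.shape)
        lhs = np.vdot(field.components, w)
        rhs = np.vdot(u, sr.hessian_adjoint(w, 0.6, time_axis=0, time_weight=0.5))
        assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), 1.0)


class TestOperatorNorm:
    def test_unit_sum_kernels_have_unit_norm(self):
        assert sr.operator_norm("convolution", (8, 8), psf=sr.dirac_psf((1, 1))) == 1.0
        g = sr.gaussian_psf((7, 7), sigma_xy=1.2)
        assert sr.operator_norm("convolution", (16, 16), psf=g) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("rho", [0.3, 0.6])
    def test_hessian_norm_matches_dense_svd(self, rho):
        estimate = sr.operator_norm("hessian", (6, 6), rho=rho, tol=1e-10, max_iter=5000)
        dense = dense_hessian_matrix((6, 6), rho)
        top = np.linalg.svd(dense, compute_uv=False)[0]
        assert estimate == pytest.approx(top, rel=1e-4)

    def test_norm_bound_dominates_dense_norm(self):
        for shape, rho in [((6, 6), 0.1), ((6, 6), 0.9), ((4, 4, 3), 0.6)]:
            top = np.linalg.svd(dense_hessian_matrix(shape, rho), compute_uv=False)[0]
            assert hessian_norm_bound(len(shape), rho) >= top - 1e-12
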