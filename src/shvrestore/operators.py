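"""Linear operators of the restoration energy.

Two operator families are provided:

* the blur operator ``H`` — circular (periodic) convolution with a PSF
  kernel, evaluated by FFT, with the kernel centered at the origin by an
  index shift so a symmetric kernel introduces no translation;
* the sparsity/second-order operator ``D2_rho`` mapping an image ``u`` to
  the per-pixel vector ``((1-rho) u, rho uxx, rho uyy, ..., rho uxy, ...)``
  containing the intensity and all d^2 second finite differences (both
  mixed orders are listed, so each mixed derivative effectively carries a
  sqrt(2) weight inside the per-pixel norm).  Boundaries are Neumann:
  out-of-range neighbours replicate the edge value.

Exact adjoints of both operators are provided — the primal-dual solver
needs them — together with a power-iteration spectral-norm estimate used
by the automatic step-size rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

__all__ = [
    "HessianField",
    "convolve",
    "convolve_adjoint",
    "hessian_operator",
    "hessian_adjoint",
    "operator_norm",
    "psf_transfer",
    "n_hessian_components",
]


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

def _kernel_array(psf) -> np.ndarray:
    values = getattr(psf, "values", psf)
    return np.asarray(values, dtype=np.float64)


def psf_transfer(psf, shape: tuple[int, ...]) -> np.ndarray:
    """Full complex transfer function of the kernel on an image grid.

    The kernel's center pixel (``shape // 2`` along each axis) is rolled to
    index 0 before the FFT, so convolution is translation-free for
    symmetric kernels.
    """
    k = _kernel_array(psf)
    if k.ndim != len(shape):
        raise ValueError(
            f"PSF dimensionality {k.ndim} does not match image dimensionality {len(shape)}"
        )
    if any(ks > s for ks, s in zip(k.shape, shape)):
        raise ValueError(f"kernel shape {k.shape} larger than image shape {shape}")
    big = np.zeros(shape, dtype=np.float64)
    big[tuple(slice(0, s) for s in k.shape)] = k
    center = tuple(s // 2 for s in k.shape)
    big = np.roll(big, tuple(-c for c in center), axis=tuple(range(len(shape))))
    return scipy.fft.fftn(big)


def _apply_transfer(u: np.ndarray, transfer: np.ndarray) -> np.ndarray:
    return np.real(scipy.fft.ifftn(scipy.fft.fftn(u) * transfer))


def convolve(u: np.ndarray, psf, transfer: np.ndarray | None = None) -> np.ndarray:
    """Circular convolution ``h * u`` via FFT; output shape = input shape."""
    u = np.asarray(u, dtype=np.float64)
    if transfer is None:
        transfer = psf_transfer(psf, u.shape)
    return _apply_transfer(u, transfer)


def convolve_adjoint(r: np.ndarray, psf, transfer: np.ndarray | None = None) -> np.ndarray:
    """Adjoint ``H^T r``: circular correlation with the kernel."""
    r = np.asarray(r, dtype=np.float64)
    if transfer is None:
        transfer = psf_transfer(psf, r.shape)
    return _apply_transfer(r, np.conj(transfer))


# ---------------------------------------------------------------------------
# Finite differences with replicate (Neumann) boundaries
# ---------------------------------------------------------------------------

def _take(u: np.ndarray, ax: int, sl: slice) -> np.ndarray:
    key = [slice(None)] * u.ndim
    key[ax] = sl
    return u[tuple(key)]


def _shift_fwd(u: np.ndarray, ax: int) -> np.ndarray:
    """out(x) = u(x + e_ax), edge value replicated at the far boundary."""
    return np.concatenate([_take(u, ax, slice(1, None)), _take(u, ax, slice(-1, None))], axis=ax)


def _shift_bwd(u: np.ndarray, ax: int) -> np.ndarray:
    """out(x) = u(x - e_ax), edge value replicated at the near boundary."""
    return np.concatenate([_take(u, ax, slice(0, 1)), _take(u, ax, slice(0, -1))], axis=ax)


def _shift_fwd_T(w: np.ndarray, ax: int) -> np.ndarray:
    zeros = np.zeros_like(_take(w, ax, slice(0, 1)))
    out = np.concatenate([zeros, _take(w, ax, slice(0, -1))], axis=ax)
    key = [slice(None)] * w.ndim
    key[ax] = slice(-1, None)
    out[tuple(key)] += _take(w, ax, slice(-1, None))
    return out


def _shift_bwd_T(w: np.ndarray, ax: int) -> np.ndarray:
    zeros = np.zeros_like(_take(w, ax, slice(0, 1)))
    out = np.concatenate([_take(w, ax, slice(1, None)), zeros], axis=ax)
    key = [slice(None)] * w.ndim
    key[ax] = slice(0, 1)
    out[tuple(key)] += _take(w, ax, slice(0, 1))
    return out


def _second_diff(u: np.ndarray, ax: int) -> np.ndarray:
    return _shift_fwd(u, ax) + _shift_bwd(u, ax) - 2.0 * u


def _second_diff_T(w: np.ndarray, ax: int) -> np.ndarray:
    return _shift_fwd_T(w, ax) + _shift_bwd_T(w, ax) - 2.0 * w


def _fwd_diff(u: np.ndarray, ax: int) -> np.ndarray:
    return _shift_fwd(u, ax) - u


def _fwd_diff_T(w: np.ndarray, ax: int) -> np.ndarray:
    return _shift_fwd_T(w, ax) - w


def _mixed_diff(u: np.ndarray, ax_i: int, ax_j: int) -> np.ndarray:
    # forward-forward stencil u(x+ei+ej) - u(x+ei) - u(x+ej) + u(x)
    return _fwd_diff(_fwd_diff(u, ax_j), ax_i)


def _mixed_diff_T(w: np.ndarray, ax_i: int, ax_j: int) -> np.ndarray:
    return _fwd_diff_T(_fwd_diff_T(w, ax_i), ax_j)


# ---------------------------------------------------------------------------
# The composite operator D2_rho
# ---------------------------------------------------------------------------

def n_hessian_components(ndim: int) -> int:
    """Component count of the per-pixel vector: 1 + d^2."""
    return 1 + ndim * ndim


def _component_axes(ndim: int) -> list[tuple[int, ...]]:
    """Axis labels of the derivative components, in storage order.

    Pure second differences per axis, then the mixed upper triangle
    (i < j), then the mixed lower triangle (j, i) — duplicates of the
    symmetric stencil, listed so the per-pixel norm weights mixed terms
    by sqrt(2).
    """
    pure = [(i, i) for i in range(ndim)]
    upper = [(i, j) for i in range(ndim) for j in range(i + 1, ndim)]
    lower = [(j, i) for (i, j) in upper]
    return pure + upper + lower


def _axis_scale(axes: tuple[int, ...], time_axis: int | None, time_weight: float) -> float:
    if time_axis is not None and time_axis in axes:
        return time_weight
    return 1.0


@dataclass
class HessianField:
    """Per-pixel vector field ``D2_rho u``.

    ``components`` has shape ``(1 + d^2, *grid)``: slot 0 is the intensity
    term ``(1 - rho) u``; the remaining d^2 slots hold ``rho`` times the
    second differences in the order returned by ``_component_axes``.
    """

    components: np.ndarray
    rho: float

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.components.shape[1:]

    @property
    def ndim_image(self) -> int:
        return self.components.ndim - 1

    def pixel_norms(self) -> np.ndarray:
        """Euclidean norm of the per-pixel vector, one value per pixel."""
        return np.sqrt(np.sum(self.components**2, axis=0))


def _check_rho(rho: float) -> float:
    rho = float(rho)
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    return rho


def hessian_operator(
    u: np.ndarray,
    rho: float,
    time_axis: int | None = None,
    time_weight: float = 1.0,
) -> HessianField:
    """Apply ``D2_rho`` to an image (2D, 3D or 4D).

    Parameters
    ----------
    u
        Image array, ``2 <= u.ndim <= 4``.
    rho
        Sparsity weight in [0, 1]: 0 keeps only the intensity component,
        1 keeps only the second differences.
    time_axis, time_weight
        If the image has a time axis, all components involving it are
        additionally scaled by ``time_weight`` (default 1, i.e. time is
        regularized like a spatial axis with unit grid spacing).
    """
    rho = _check_rho(rho)
    u = np.asarray(u, dtype=np.float64)
    if not 2 <= u.ndim <= 4:
        raise ValueError(f"image dimension must be 2, 3 or 4, got {u.ndim}")
    d = u.ndim
    comps = np.empty((n_hessian_components(d),) + u.shape, dtype=np.float64)
    comps[0] = (1.0 - rho) * u
    for slot, axes in enumerate(_component_axes(d), start=1):
        scale = rho * _axis_scale(axes, time_axis, time_weight)
        i, j = axes
        if i == j:
            comps[slot] = scale * _second_diff(u, i)
        else:
            comps[slot] = scale * _mixed_diff(u, i, j)
    return HessianField(components=comps, rho=rho)


def hessian_adjoint(
    field: HessianField | np.ndarray,
    rho: float,
    time_axis: int | None = None,
    time_weight: float = 1.0,
) -> np.ndarray:
    """Exact adjoint ``D2_rho^T w`` (including the replication transpose)."""
    rho = _check_rho(rho)
    comps = field.components if isinstance(field, HessianField) else np.asarray(field, dtype=np.float64)
    d = comps.ndim - 1
    if not 2 <= d <= 4:
        raise ValueError(f"field grid dimension must be 2, 3 or 4, got {d}")
    if comps.shape[0] != n_hessian_components(d):
        raise ValueError(
            f"expected {n_hessian_components(d)} components for a {d}D grid, got {comps.shape[0]}"
        )
    out = (1.0 - rho) * comps[0]
    for slot, axes in enumerate(_component_axes(d), start=1):
        scale = rho * _axis_scale(axes, time_axis, time_weight)
        if scale == 0.0:
            continue
        i, j = axes
        if i == j:
            out += scale * _second_diff_T(comps[slot], i)
        else:
            out += scale * _mixed_diff_T(comps[slot], i, j)
    return out


# ---------------------------------------------------------------------------
# Operator norms
# ---------------------------------------------------------------------------

def hessian_norm_bound(
    ndim: int,
    rho: float,
    time_axis: int | None = None,
    time_weight: float = 1.0,
) -> float:
    """Sharp closed-form upper bound on ``||D2_rho||``.

    Each second-difference component has operator norm at most 4 (attained
    by the highest-frequency mode), so stacking gives
    ``||D||^2 <= (1-rho)^2 + 16 rho^2 sum_c scale_c^2`` with one unit scale
    per derivative slot (d^2 of them, time-involving slots scaled by the
    temporal weight).  Used by the solver's step-size rule, where any upper
    bound keeps the scheme convergent.
    """
    rho = _check_rho(rho)
    total = 0.0
    for axes in _component_axes(ndim):
        total += (4.0 * _axis_scale(axes, time_axis, time_weight)) ** 2
    return float(np.sqrt((1.0 - rho) ** 2 + rho * rho * total))


def operator_norm(
    which: str,
    shape: tuple[int, ...],
    psf=None,
    rho: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    time_axis: int | None = None,
    time_weight: float = 1.0,
) -> float:
    """Spectral norm of ``H``, ``D2_rho`` or their vertical concatenation.

    ``which`` is one of ``"convolution"``, ``"hessian"``, ``"composite"``.
    The convolution norm is read off the transfer function (the operator
    is diagonal in the Fourier basis; for a unit-sum nonnegative kernel it
    is the DC gain, 1).  The others use power iteration on the
    self-adjoint composition ``A^T A`` to relative tolerance ``tol``.
    """
    if which == "convolution":
        if psf is None:
            raise ValueError("psf required for the convolution norm")
        return float(np.max(np.abs(psf_transfer(psf, shape))))

    if rho is None:
        raise ValueError("rho required for the hessian/composite norm")
    transfer = psf_transfer(psf, shape) if which == "composite" else None

    def normal_op(u: np.ndarray) -> np.ndarray:
        w = hessian_operator(u, rho, time_axis, time_weight)
        out = hessian_adjoint(w, rho, time_axis, time_weight)
        if transfer is not None:
            out = out + convolve_adjoint(convolve(u, None, transfer), None, transfer)
        return out

    if which not in ("hessian", "composite"):
        raise ValueError(f"unknown operator {which!r}")

    rng = np.random.Generator(np.random.Philox(seed))
    u = rng.standard_normal(shape)
    u /= np.linalg.norm(u)
    prev = 0.0
    lam = 0.0
    for _ in range(max_iter):
        w = normal_op(u)
        norm_w = float(np.linalg.norm(w))
        if norm_w == 0.0:
            return 0.0
        lam = float(np.vdot(u, w))  # Rayleigh quotient of A^T A
        u = w / norm_w
        if abs(lam - prev) <= tol * abs(lam):
            return float(np.sqrt(lam))
        prev = lam
    raise RuntimeError(
        f"power iteration did not converge in {max_iter} iterations; "
        f"last two eigenvalue estimates: {prev:.9g}, {lam:.9g}"
    )
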