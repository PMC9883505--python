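"""Independent brute-force oracles used by the test suite.

Everything here is built directly from definitions (explicit loops, dense
matrices, scipy.optimize), never from the package's FFT / stencil code
paths, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def direct_circular_convolve(u: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """O(N * K) direct-sum circular convolution with a centered kernel."""
    center = tuple(s // 2 for s in kernel.shape)
    out = np.zeros_like(u, dtype=np.float64)
    for p in np.ndindex(kernel.shape):
        w = kernel[p]
        if w == 0.0:
            continue
        shift = tuple(pi - ci for pi, ci in zip(p, center))
        out += w * np.roll(u, shift, axis=tuple(range(u.ndim)))
    return out


def dense_shift_fwd(n: int) -> np.ndarray:
    """Matrix of x -> x+1 with the far edge value replicated."""
    m = np.zeros((n, n))
    for k in range(n - 1):
        m[k, k + 1] = 1.0
    m[n - 1, n - 1] = 1.0
    return m


def dense_shift_bwd(n: int) -> np.ndarray:
    m = np.zeros((n, n))
    for k in range(1, n):
        m[k, k - 1] = 1.0
    m[0, 0] = 1.0
    return m


def _axis_matrix(op_1d: np.ndarray, axis: int, shape: tuple[int, ...]) -> np.ndarray:
    """Lift a 1D operator to the flattened (row-major) image space."""
    mat = np.eye(1)
    for ax, n in enumerate(shape):
        block = op_1d if ax == axis else np.eye(n)
        mat = np.kron(mat, block)
    return mat


def dense_hessian_matrix(shape: tuple[int, ...], rho: float) -> np.ndarray:
    """Dense matrix of the stacked intensity + second-difference operator.

    Rows are ordered (intensity, pure diffs per axis, mixed upper
    triangle, mixed lower triangle), matching the package's component
    order; boundaries replicate edge values.
    """
    d = len(shape)
    n = int(np.prod(shape))
    eye = np.eye(n)
    blocks = [(1.0 - rho) * eye]
    second = {}
    fwd = {}
    for ax, sz in enumerate(shape):
        sf = _axis_matrix(dense_shift_fwd(sz), ax, shape)
        sb = _axis_matrix(dense_shift_bwd(sz), ax, shape)
        second[ax] = sf + sb - 2.0 * eye
        fwd[ax] = sf - eye
    for ax in range(d):
        blocks.append(rho * second[ax])
    upper = [(i, j) for i in range(d) for j in range(i + 1, d)]
    for i, j in upper:
        blocks.append(rho * (fwd[i] @ fwd[j]))
    for i, j in upper:
        blocks.append(rho * (fwd[j] @ fwd[i]))
    return np.vstack(blocks)


def dense_shv_value(u: np.ndarray, rho: float) -> float:
    """Regularizer value from the dense matrix: sum of per-pixel norms."""
    mat = dense_hessian_matrix(u.shape, rho)
    field = (mat @ u.ravel()).reshape(-1, u.size)
    return float(np.sum(np.sqrt(np.sum(field**2, axis=0))))


def smoothed_energy_minimizer(
    f: np.ndarray, kernel: np.ndarray, lam: float, rho: float, eps: float = 1e-8
) -> np.ndarray:
    """Brute-force convex minimizer of the restoration energy.

    L-BFGS-B with nonnegativity bounds on the smoothed energy where every
    per-pixel norm ||w|| is replaced by sqrt(||w||^2 + eps^2); at
    eps = 1e-8 the smoothing bias is far below the comparison tolerance.
    """
    from scipy.optimize import minimize

    mat = dense_hessian_matrix(f.shape, rho)
    n = f.size

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        u = x.reshape(f.shape)
        r = direct_circular_convolve(u, kernel) - f
        fid = 0.5 * float(np.sum(r * r))
        g_fid = direct_circular_convolve(r, kernel[tuple(slice(None, None, -1) for _ in kernel.shape)])
        field = (mat @ x).reshape(-1, n)
        norms = np.sqrt(np.sum(field**2, axis=0) + eps**2)
        reg = lam * float(np.sum(norms))
        g_reg = lam * (mat.T @ (field / norms).ravel())
        return fid + reg, g_fid.ravel() + g_reg

    x0 = np.clip(f, 0.0, None).ravel()
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * n,
        options={"maxiter": 20000, "maxfun": 50000, "ftol": 1e-16, "gtol": 1e-12},
    )
    return res.x.reshape(f.shape)
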