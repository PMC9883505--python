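"""Mixed Poisson-Gaussian observation model.

A fluorescence micrograph ``f`` is modelled as a blurred true image
``v = h * u`` corrupted by photon shot noise and detector readout noise::

    f(x) = Poisson(alpha * v(x)) / alpha + N(0, tau^2)

where ``alpha > 0`` is the quantization factor of the photodetector
(photons per normalized intensity unit) and ``tau`` the readout standard
deviation on the normalized [0, 1] intensity scale.  The pixelwise variance
of this model is ``v(x) / alpha + tau^2``, which is what justifies using a
plain quadratic fidelity term even for shot-noise-limited data: at the true
image the expected squared residual equals ``||f||_1 / alpha + N * tau^2``,
a constant independent of ``u``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operators import convolve

__all__ = [
    "DegradationParams",
    "simulate_poisson_gaussian",
    "variance_prediction",
    "quadratic_fidelity",
    "fidelity_budget",
]


@dataclass(frozen=True)
class DegradationParams:
    """Parameters of the mixed Poisson-Gaussian degradation.

    Parameters
    ----------
    alpha
        Photodetector quantization factor (> 0).  ``None`` or ``inf``
        selects the pure-Gaussian limit: the Poisson component is skipped
        entirely rather than sampled at a huge rate, so the tau-only
        protocol is exact.
    tau
        Standard deviation of the additive zero-mean Gaussian readout
        noise, on the normalized [0, 1] intensity scale (>= 0).
    seed
        Seed for the counter-based (Philox) generator; identical seed and
        input give a bit-identical noisy image on every platform.
    """

    alpha: float | None = 100.0
    tau: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha is not None and not np.isinf(self.alpha):
            if self.alpha <= 0:
                raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")

    @property
    def gaussian_only(self) -> bool:
        return self.alpha is None or np.isinf(self.alpha)


def _check_nonnegative(v: np.ndarray) -> None:
    if np.any(v < 0):
        idx = tuple(int(i) for i in np.unravel_index(int(np.argmin(v)), v.shape))
        raise ValueError(
            f"noise-free input must be nonnegative; pixel {idx} has value {float(v[idx])}"
        )


def simulate_poisson_gaussian(v: np.ndarray, params: DegradationParams) -> np.ndarray:
    """Draw one noisy realization ``f = Poisson(alpha v)/alpha + N(0, tau^2)``.

    Negative output values (Gaussian tail) are *not* clipped; clipping
    would bias the variance identity.  Draws are made for the whole
    row-major array in one call of a Philox-seeded generator, so results
    are reproducible across platforms.
    """
    v = np.asarray(v, dtype=np.float64)
    _check_nonnegative(v)
    rng = np.random.Generator(np.random.Philox(params.seed))
    if params.gaussian_only:
        f = v.copy()
    else:
        f = rng.poisson(params.alpha * v).astype(np.float64) / params.alpha
    if params.tau > 0:
        f += rng.normal(0.0, params.tau, size=v.shape)
    return f


def variance_prediction(v: np.ndarray, params: DegradationParams) -> np.ndarray:
    """Pixelwise variance ``v / alpha + tau^2`` of the observation model."""
    v = np.asarray(v, dtype=np.float64)
    _check_nonnegative(v)
    if params.gaussian_only:
        shot = np.zeros_like(v)
    else:
        shot = v / params.alpha
    return shot + params.tau**2


def quadratic_fidelity(f: np.ndarray, u: np.ndarray, psf) -> float:
    """Quadratic data-fidelity term ``0.5 * || h*u - f ||_2^2``.

    ``psf`` may be a :class:`~shvrestore.psf.PSFKernel` or a bare kernel
    array; the convolution is circular (FFT-based).
    """
    f = np.asarray(f, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    if f.shape != u.shape:
        raise ValueError(f"shape mismatch: f {f.shape} vs u {u.shape}")
    r = convolve(u, psf) - f
    return 0.5 * float(np.sum(r * r))


def fidelity_budget(f: np.ndarray, params: DegradationParams) -> float:
    """Expected squared residual at the true image.

    Returns ``||f||_1 / alpha + N * tau^2`` where ``N`` is the number of
    pixels.  Under the observation model this is the value around which
    ``||f - h*u||_2^2`` concentrates when ``u`` is the true image, which is
    the quantity a discrepancy-style constraint would pin the residual to.
    """
    f = np.asarray(f, dtype=np.float64)
    n = f.size
    if params.gaussian_only:
        shot = 0.0
    else:
        shot = float(np.sum(np.abs(f))) / params.alpha
    return shot + n * params.tau**2
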