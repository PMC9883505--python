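"""Point-spread-function models.

All kernels are nonnegative, sum to one and have their peak at the central
pixel of an odd-sized support.  Widths are expressed in pixels (the
separable Gaussian and the Lorentzian); only the scalar-diffraction
Gibson-Lanni model takes physical units, because it needs a wavelength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PSFKernel",
    "GibsonLanniParams",
    "gaussian_psf",
    "lorentzian_psf_2d",
    "gibson_lanni_psf",
    "dirac_psf",
    "load_psf",
    "save_psf",
]


@dataclass(frozen=True)
class PSFKernel:
    """A normalized convolution kernel.

    ``values`` is a nonnegative array summing to 1; ``center`` is the index
    of the kernel peak (the coordinate-wise mode for the unimodal models);
    ``pixel_units`` records that widths were given in pixels.
    """

    values: np.ndarray
    center: tuple[int, ...]
    pixel_units: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if np.any(v < 0):
            raise ValueError("kernel values must be nonnegative")
        s = float(v.sum())
        if not math.isclose(s, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"kernel must sum to 1 within 1e-9, sums to {s!r}")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim


def _check_odd(shape: tuple[int, ...]) -> None:
    if any(s % 2 == 0 for s in shape):
        raise ValueError(
            f"kernel shape must be odd along every axis, got {shape}; "
            "pad the support by one pixel"
        )


def _normalize(values: np.ndarray) -> PSFKernel:
    values = np.asarray(values, dtype=np.float64)
    center = tuple(s // 2 for s in values.shape)
    return PSFKernel(values=values / values.sum(), center=center)


def _auto_side(sigma: float) -> int:
    # default support: +-4 sigma keeps truncated mass below 1e-4
    return 2 * int(np.ceil(4.0 * sigma)) + 1


def gaussian_psf(
    shape: tuple[int, ...] | None = None,
    sigma_xy: float = 1.5,
    sigma_z: float | None = None,
) -> PSFKernel:
    """Separable sampled Gaussian kernel, isotropic in XY.

    ``shape`` is ``(ny, nx)`` or ``(nz, ny, nx)``, odd along each axis; if
    omitted, each side defaults to ``2 * ceil(4 sigma) + 1``.  ``sigma_z``
    (pixels) is used only for a 3D kernel.
    """
    if sigma_xy <= 0:
        raise ValueError(f"sigma_xy must be > 0, got {sigma_xy}")
    is_3d = sigma_z is not None if shape is None else len(shape) == 3
    if is_3d and (sigma_z is None or sigma_z <= 0):
        raise ValueError(f"3D kernel needs sigma_z > 0, got {sigma_z}")
    if shape is None:
        side = _auto_side(sigma_xy)
        shape = (_auto_side(sigma_z), side, side) if is_3d else (side, side)
    _check_odd(tuple(shape))
    sigmas = (sigma_z, sigma_xy, sigma_xy) if is_3d else (sigma_xy, sigma_xy)
    marginals = []
    for n, s in zip(shape, sigmas):
        x = np.arange(n, dtype=np.float64) - n // 2
        marginals.append(np.exp(-(x**2) / (2.0 * s**2)))
    values = marginals[0]
    for m in marginals[1:]:
        values = np.multiply.outer(values, m)
    return _normalize(values)


def lorentzian_psf_2d(shape: tuple[int, int] | None = None, gamma: float = 1.0) -> PSFKernel:
    """2D Lorentzian radial profile ``(1 + (r / gamma)^2)^-1``.

    ``gamma`` (pixels) is the half-width: the unnormalized profile at
    radius ``gamma`` is half the center value.  Normalized to unit sum on
    the truncated support.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if shape is None:
        side = 2 * int(np.ceil(8.0 * gamma)) + 1
        shape = (side, side)
    if len(shape) != 2:
        raise ValueError(f"Lorentzian PSF is 2D only, got shape {shape}")
    _check_odd(tuple(shape))
    y = np.arange(shape[0], dtype=np.float64) - shape[0] // 2
    x = np.arange(shape[1], dtype=np.float64) - shape[1] // 2
    r2 = y[:, None] ** 2 + x[None, :] ** 2
    return _normalize(1.0 / (1.0 + r2 / gamma**2))


def dirac_psf(shape: tuple[int, ...] = (1, 1)) -> PSFKernel:
    """Impulse kernel: 1 at the center, 0 elsewhere (denoising blur)."""
    _check_odd(tuple(shape))
    values = np.zeros(shape, dtype=np.float64)
    values[tuple(s // 2 for s in shape)] = 1.0
    return PSFKernel(values=values, center=tuple(s // 2 for s in shape))


@dataclass(frozen=True)
class GibsonLanniParams:
    """Optical parameters of the scalar-diffraction widefield PSF.

    Defaults describe a generic high-NA oil-immersion setup and are
    arbitrary placeholders, not calibrated values: NA 1.4, emission 520 nm,
    all refractive indices matched at 1.515, 100 nm lateral pixels, 250 nm
    axial steps.  ``specimen_depth`` (nm) drives the index-mismatch
    aberration; at 0 with matched indices the model reduces to the
    aberration-free defocus integral, symmetric about the focal plane.
    """

    numerical_aperture: float = 1.4
    emission_wavelength: float = 520.0
    immersion_refractive_index: float = 1.515
    specimen_refractive_index: float = 1.515
    coverslip_refractive_index: float = 1.515
    lateral_pixel_size: float = 100.0
    axial_step: float = 250.0
    n_planes_kept: int = 3
    specimen_depth: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture < self.immersion_refractive_index:
            raise ValueError(
                "numerical aperture must satisfy 0 < NA < immersion index, got "
                f"NA={self.numerical_aperture}, ni={self.immersion_refractive_index}"
            )
        if self.n_planes_kept < 1 or self.n_planes_kept % 2 == 0:
            raise ValueError(f"n_planes_kept must be odd >= 1, got {self.n_planes_kept}")


def _gl_pupil_integral(
    r: np.ndarray, z: float, p: GibsonLanniParams, n_samples: int
) -> np.ndarray:
    """Kirchhoff integral over the pupil radius for one axial plane.

    ``h(r, z) = | int_0^1 exp(i k Phi(s; z)) J0(k r NA s) s ds |^2`` with
    the optical path difference ``Phi`` composed of the defocus term and
    the specimen index-mismatch term.
    """
    from scipy.special import j0

    k = 2.0 * np.pi / p.emission_wavelength
    s = np.linspace(0.0, 1.0, n_samples)
    na_s = p.numerical_aperture * s
    ci = np.sqrt(np.maximum(p.immersion_refractive_index**2 - na_s**2, 0.0))
    phi = z * ci
    if p.specimen_depth != 0.0:
        cs = np.sqrt(
            np.maximum(p.specimen_refractive_index**2 - na_s**2, 0.0).astype(complex)
        )
        phi = phi + p.specimen_depth * (cs - ci)
    integrand = np.exp(1j * k * phi)[None, :] * j0(k * np.outer(r, na_s)) * s[None, :]
    amp = np.trapezoid(integrand, s, axis=1)
    return np.abs(amp) ** 2


def gibson_lanni_psf(
    params: GibsonLanniParams | None = None,
    shape: tuple[int, int, int] = (9, 15, 15),
    quadrature_tol: float = 1e-4,
    max_refinements: int = 12,
) -> PSFKernel:
    """3D scalar-diffraction PSF, truncated axially to ``n_planes_kept``.

    The pupil integral is evaluated per voxel by trapezoid quadrature,
    doubling the pupil sample count until the kernel changes by less than
    ``quadrature_tol`` in relative L1 norm.  The full axial extent given
    by ``shape`` is computed, then only ``n_planes_kept`` planes centered
    on the focal plane are retained and the kernel renormalized.
    """
    p = params if params is not None else GibsonLanniParams()
    if len(shape) != 3:
        raise ValueError(f"Gibson-Lanni PSF is 3D, got shape {shape}")
    _check_odd(tuple(shape))
    nz, ny, nx = shape
    yy = (np.arange(ny) - ny // 2) * p.lateral_pixel_size
    xx = (np.arange(nx) - nx // 2) * p.lateral_pixel_size
    r = np.sqrt(yy[:, None] ** 2 + xx[None, :] ** 2).ravel()
    zs = (np.arange(nz) - nz // 2) * p.axial_step

    def evaluate(n_samples: int) -> np.ndarray:
        planes = [_gl_pupil_integral(r, z, p, n_samples).reshape(ny, nx) for z in zs]
        vol = np.stack(planes)
        return vol / vol.sum()

    n_samples = 64
    vol = evaluate(n_samples)
    for _ in range(max_refinements):
        n_samples *= 2
        vol_fine = evaluate(n_samples)
        change = float(np.sum(np.abs(vol_fine - vol)))
        vol = vol_fine
        if change < quadrature_tol:
            break
    else:
        raise RuntimeError(
            f"pupil quadrature did not converge below {quadrature_tol} "
            f"after {max_refinements} refinements (last change {change:.3g})"
        )

    if p.n_planes_kept > nz:
        raise ValueError(f"n_planes_kept={p.n_planes_kept} exceeds axial extent {nz}")
    lo = nz // 2 - p.n_planes_kept // 2
    kept = vol[lo : lo + p.n_planes_kept]
    return _normalize(kept)


def load_psf(path) -> PSFKernel:
    """Read a kernel from a (single- or multi-page) TIFF and normalize it."""
    import tifffile

    values = np.asarray(tifffile.imread(path), dtype=np.float64)
    if np.any(values < 0):
        raise ValueError(f"PSF file {path} contains negative values")
    if values.sum() <= 0:
        raise ValueError(f"PSF file {path} has zero total mass")
    return _normalize(values)


def save_psf(psf: PSFKernel, path) -> None:
    import tifffile

    tifffile.imwrite(path, psf.values.astype(np.float32), photometric="minisblack")
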