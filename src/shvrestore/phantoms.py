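"""Synthetic phantoms and the degradation protocol.

The generator emulates the two structural regimes fluorescence
restoration is benchmarked on: diffraction-limited *spots* (vesicle-like
bright Gaussian blobs over an exactly zero background — highly sparse)
and *filaments* (smoothed random-walk curves resembling cytoskeletal
structures — weakly sparse), plus a *mixed* class.  Degradation follows
the standard simulation protocol: Gaussian blur of chosen width, then
mixed Poisson-Gaussian (or pure Gaussian) noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .noise import DegradationParams, simulate_poisson_gaussian
from .operators import convolve

__all__ = ["PhantomSpec", "make_phantom", "degrade"]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a reproducible phantom.

    ``object_scale`` is the blob sigma (spots) or filament thickness in
    pixels.  Amplitudes are drawn uniformly from ``amplitude_range``
    (subset of [0, 1]).  Spots are rejection-sampled to be disjoint, so
    the background is exactly zero outside objects.
    """

    kind: str = "spots"
    shape: tuple[int, ...] = (64, 64)
    n_objects: int = 10
    amplitude_range: tuple[float, float] = (0.5, 1.0)
    object_scale: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("spots", "filaments", "mixed"):
            raise ValueError(f"kind must be spots|filaments|mixed, got {self.kind!r}")
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        lo, hi = self.amplitude_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError(f"amplitude_range must be within [0, 1], got {self.amplitude_range}")


def _blob_support_radius(sigma: float) -> int:
    return int(np.ceil(4.0 * sigma))


def _place_spots(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros(spec.shape, dtype=np.float64)
    radius = _blob_support_radius(spec.object_scale)
    # keep blob supports fully inside the grid where the grid allows it
    margins = [min(radius, (s - 1) // 2) for s in spec.shape]
    min_sep = 2 * radius + 1  # disjoint circular truncated supports
    centers: list[np.ndarray] = []
    # sequential rejection with full restarts: dense configurations can
    # paint themselves into a corner
    for _restart in range(30):
        centers = []
        tries = 0
        while len(centers) < spec.n_objects and tries < 200 * spec.n_objects:
            tries += 1
            c = np.array(
                [int(rng.integers(m, s - m)) for m, s in zip(margins, spec.shape)]
            )
            if any(np.linalg.norm(c - p) < min_sep for p in centers):
                continue
            centers.append(c)
        if len(centers) == spec.n_objects:
            break
    else:
        raise ValueError(
            f"could not place {spec.n_objects} non-overlapping spots of scale "
            f"{spec.object_scale} on grid {spec.shape}"
        )
    amplitudes = rng.uniform(*spec.amplitude_range, size=len(centers))
    grids = np.meshgrid(*[np.arange(2 * radius + 1) - radius for _ in spec.shape], indexing="ij")
    r2 = sum(g.astype(np.float64) ** 2 for g in grids)
    blob = np.exp(-r2 / (2.0 * spec.object_scale**2))
    blob[r2 > radius**2] = 0.0  # truncate so background stays exactly zero
    for c, a in zip(centers, amplitudes):
        img_sl = []
        blob_sl = []
        for ci, s in zip(c, spec.shape):
            lo, hi = ci - radius, ci + radius + 1
            img_sl.append(slice(max(lo, 0), min(hi, s)))
            blob_sl.append(slice(max(lo, 0) - lo, (2 * radius + 1) - (hi - min(hi, s))))
        img_sl, blob_sl = tuple(img_sl), tuple(blob_sl)
        img[img_sl] = np.maximum(img[img_sl], a * blob[blob_sl])
    return img


def _draw_filaments(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    img = np.zeros(spec.shape, dtype=np.float64)
    d = len(spec.shape)
    n_steps = 3 * max(spec.shape)
    for _ in range(spec.n_objects):
        pos = np.array([rng.uniform(0, s - 1) for s in spec.shape])
        direction = rng.standard_normal(d)
        direction /= np.linalg.norm(direction)
        amp = rng.uniform(*spec.amplitude_range)
        for _ in range(n_steps):
            idx = tuple(int(round(p)) for p in pos)
            if all(0 <= i < s for i, s in zip(idx, spec.shape)):
                img[idx] = max(img[idx], amp)
            direction += 0.25 * rng.standard_normal(d)
            direction /= np.linalg.norm(direction)
            pos = pos + direction
            if any(p < 0 or p > s - 1 for p, s in zip(pos, spec.shape)):
                break
    img = gaussian_filter(img, sigma=max(spec.object_scale / 2.0, 0.5), mode="constant")
    peak = img.max()
    if peak > 0:
        img *= spec.amplitude_range[1] / peak
    return img


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate a phantom in [0, 1], reproducible from ``spec.seed``."""
    rng = np.random.Generator(np.random.Philox(spec.seed))
    if spec.n_objects == 0:
        return np.zeros(spec.shape, dtype=np.float64)
    if spec.kind == "spots":
        img = _place_spots(spec, rng)
    elif spec.kind == "filaments":
        img = _draw_filaments(spec, rng)
    else:  # mixed
        half = spec.n_objects // 2
        spots = _place_spots(
            PhantomSpec("spots", spec.shape, max(half, 1), spec.amplitude_range,
                        spec.object_scale, spec.seed),
            rng,
        )
        fil = _draw_filaments(
            PhantomSpec("filaments", spec.shape, max(spec.n_objects - half, 1),
                        spec.amplitude_range, spec.object_scale, spec.seed),
            rng,
        )
        img = np.maximum(spots, fil)
    return np.clip(img, 0.0, 1.0)


def degrade(u: np.ndarray, psf, params: DegradationParams) -> np.ndarray:
    """Blur with the PSF, then apply the mixed Poisson-Gaussian noise.

    With ``params.alpha`` set to ``None``/``inf`` the Poisson component is
    skipped (the pure-Gaussian benchmark protocol).  Output values are not
    clipped and may be slightly negative.
    """
    u = np.asarray(u, dtype=np.float64)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("phantom intensities must lie in [0, 1] before degradation")
    v = convolve(u, psf)
    # FFT round-off can leave tiny negatives in the blurred image
    v = np.maximum(v, 0.0)
    return simulate_poisson_gaussian(v, params)
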