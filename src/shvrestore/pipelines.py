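"""Restoration strategies for 2D / 3D / 2D+T / 3D+T images.

The strategy names encode the flowchart a practitioner walks through:
denoise only (Dirac PSF) in 2, 3 or 4 dimensions; direct 2D/3D
deconvolution when the PSF is trusted; *plane-by-plane* (PbyP)
deconvolution of each XY section with a 2D PSF when the 3D PSF is poorly
known; and the chained *denoise-before-deconvolve* variants for
low-photon regimes, including 4D denoising followed by per-frame 3D
deconvolution for light-sheet videos.

Intensities are normalized globally (one maximum per run, preserving
temporal dynamics such as bleaching across a video), restored on the
[0, 1] scale where the noise model lives, and denormalized on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .psf import PSFKernel, dirac_psf
from .select import LambdaGrid, select_lambda
from .solver import RegularizationParams, SolverConfig, EnergyTrace, resolve_sparsity, restore
from .volume import ImageVolume, NormalizationRecord, as_volume

__all__ = [
    "StageParams",
    "RestorationStrategy",
    "normalize",
    "denormalize",
    "run_strategy",
    "STRATEGY_MODES",
]

STRATEGY_MODES = (
    "denoise2d",
    "denoise3d",
    "denoise4d",
    "deconv2d",
    "deconv3d",
    "deconv_pbyp",
    "denoise_then_deconv3d",
    "denoise_then_deconv_pbyp",
    "denoise4d_then_deconv3d_per_frame",
)

#: axes each mode accepts, and whether it has denoise / deconv stages
_MODE_TABLE = {
    "denoise2d": (("YX",), True, None),
    "denoise3d": (("ZYX", "TYX"), True, None),
    "denoise4d": (("TZYX",), True, None),
    "deconv2d": (("YX",), False, "direct"),
    "deconv3d": (("ZYX",), False, "direct"),
    "deconv_pbyp": (None, False, "pbyp"),
    "denoise_then_deconv3d": (("ZYX",), True, "direct"),
    "denoise_then_deconv_pbyp": (None, True, "pbyp"),
    "denoise4d_then_deconv3d_per_frame": (("TZYX",), True, "per_frame"),
}


@dataclass(frozen=True)
class StageParams:
    """Regularization settings for one restoration stage.

    ``sparsity`` is a preset name or rho value; ``lam`` is a positive
    number or ``"auto"`` for minimax selection on a ROI.
    """

    sparsity: float | str = "moderate"
    lam: float | str = "auto"
    config: SolverConfig = field(default_factory=SolverConfig)

    @property
    def rho(self) -> float:
        return resolve_sparsity(self.sparsity)


@dataclass(frozen=True)
class RestorationStrategy:
    """A mode plus per-stage parameters.

    Deconvolution stages require ``psf`` (a non-trivial kernel); denoise
    stages always use the Dirac kernel regardless of ``psf``.  ``roi``
    optionally fixes the 2D (y, x) patch used for automatic lambda
    selection; the default is a centered crop of up to 64 x 64 pixels of
    the middle plane/frame.  ``time_weight`` scales the temporal
    second-difference components in 4D denoising.
    """

    mode: str
    psf: PSFKernel | None = None
    denoise: StageParams = field(default_factory=StageParams)
    deconv: StageParams = field(default_factory=StageParams)
    roi: tuple[slice, slice] | None = None
    time_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in _MODE_TABLE:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {STRATEGY_MODES}")
        _, _, deconv_kind = _MODE_TABLE[self.mode]
        if deconv_kind is not None:
            if self.psf is None:
                raise ValueError(f"mode {self.mode!r} requires a PSF")
            need = 2 if deconv_kind == "pbyp" else 3 if deconv_kind in ("per_frame",) else None
            if need is None:
                need = 2 if self.mode == "deconv2d" else 3
            if self.psf.ndim != need:
                raise ValueError(
                    f"mode {self.mode!r} needs a {need}D PSF, got {self.psf.ndim}D"
                )


def normalize(u: np.ndarray) -> tuple[np.ndarray, NormalizationRecord]:
    """Scale by the global maximum so intensities lie in [0, 1]."""
    u = np.asarray(u, dtype=np.float64)
    peak = float(u.max())
    if peak <= 0:
        raise ValueError("image maximum must be positive to normalize")
    return u / peak, NormalizationRecord(max_value=peak)


def denormalize(u: np.ndarray, record: NormalizationRecord) -> np.ndarray:
    return np.asarray(u, dtype=np.float64) * record.max_value + record.offset


def _default_roi_2d(plane: np.ndarray, size: int = 64) -> tuple[slice, slice]:
    ny, nx = plane.shape
    h, w = min(size, ny), min(size, nx)
    y0, x0 = (ny - h) // 2, (nx - w) // 2
    return (slice(y0, y0 + h), slice(x0, x0 + w))


def _middle_plane(data: np.ndarray) -> np.ndarray:
    """Central 2D (y, x) section of a 2-4D array."""
    plane = data
    while plane.ndim > 2:
        plane = plane[plane.shape[0] // 2]
    return plane


def _psf_2d(psf: PSFKernel) -> PSFKernel:
    """2D reduction of a kernel: axial sum of a 3D PSF, renormalized."""
    if psf.ndim == 2:
        return psf
    flat = psf.values.sum(axis=0)
    center = tuple(s // 2 for s in flat.shape)
    return PSFKernel(values=flat / flat.sum(), center=center)


def _resolve_lam(
    data: np.ndarray,
    psf2d: PSFKernel,
    stage: StageParams,
    roi: tuple[slice, slice] | None,
) -> float:
    if stage.lam != "auto":
        return float(stage.lam)
    plane = _middle_plane(data)
    sl = roi if roi is not None else _default_roi_2d(plane)
    patch = plane[sl]
    result = select_lambda(patch, psf2d, stage.rho, LambdaGrid(), stage.config)
    return result.lam_star


def _restore_nd(
    data: np.ndarray,
    psf,
    stage: StageParams,
    lam: float,
    time_axis: int | None,
    time_weight: float,
) -> tuple[np.ndarray, EnergyTrace]:
    params = RegularizationParams(rho=stage.rho, lam=lam)
    return restore(data, psf, params, stage.config, time_axis=time_axis, time_weight=time_weight)


def _pbyp(
    data: np.ndarray, psf2d: PSFKernel, stage: StageParams, lam: float
) -> tuple[np.ndarray, list[EnergyTrace]]:
    """Deconvolve every XY section independently with the 2D PSF."""
    flat = data.reshape((-1,) + data.shape[-2:])
    out = np.empty_like(flat)
    traces = []
    params = RegularizationParams(rho=stage.rho, lam=lam)
    for i, plane in enumerate(flat):
        out[i], tr = restore(plane, psf2d, params, stage.config)
        traces.append(tr)
    return out.reshape(data.shape), traces


def run_strategy(image, strategy: RestorationStrategy):
    """Apply a restoration strategy to an image.

    Returns ``(restored ImageVolume, traces)`` where ``traces`` maps stage
    names to their energy traces (a list of per-plane/frame traces for
    plane-by-plane and per-frame stages).  Output axes, shape and metadata
    match the input; intensities are returned on the input scale.
    """
    vol = as_volume(image)
    required_axes, has_denoise, deconv_kind = _MODE_TABLE[strategy.mode]
    if required_axes is not None and vol.axes not in required_axes:
        raise ValueError(
            f"mode {strategy.mode!r} expects axes {'/'.join(required_axes)}, "
            f"image has {vol.axes!r}"
        )
    if deconv_kind == "pbyp" and vol.ndim < 3:
        raise ValueError("plane-by-plane deconvolution needs a stack (Z and/or T axis)")

    data, record = normalize(vol.data)
    time_axis = vol.axes.find("T") if vol.has_time else None
    traces: dict[str, object] = {}

    if has_denoise:
        stage = strategy.denoise
        lam = _resolve_lam(data, dirac_psf((1, 1)), stage, strategy.roi)
        data, tr = _restore_nd(
            data, dirac_psf((1,) * data.ndim), stage, lam, time_axis, strategy.time_weight
        )
        traces["denoise"] = tr

    if deconv_kind is not None:
        stage = strategy.deconv
        psf = strategy.psf
        lam = _resolve_lam(data, _psf_2d(psf), stage, strategy.roi)
        if deconv_kind == "direct":
            data, tr = _restore_nd(data, psf, stage, lam, None, 1.0)
            traces["deconv"] = tr
        elif deconv_kind == "pbyp":
            data, trs = _pbyp(data, psf, stage, lam)
            traces["deconv"] = trs
        else:  # per_frame 3D deconvolution of a TZYX video
            params = RegularizationParams(rho=stage.rho, lam=lam)
            frames = []
            trs = []
            for frame in data:
                uf, tr = restore(frame, psf, params, stage.config)
                frames.append(uf)
                trs.append(tr)
            data = np.stack(frames)
            traces["deconv"] = trs

    restored = denormalize(data, record)
    return vol.with_data(restored, normalization=record), traces
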