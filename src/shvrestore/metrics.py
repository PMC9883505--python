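"""Restoration quality metrics: PSNR and ROI-power SNR."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RoiPair", "psnr", "roi_snr"]


@dataclass(frozen=True)
class RoiPair:
    """Disjoint rectangular signal / background regions.

    Each ROI is a tuple of ``slice`` objects (one per image axis) with
    explicit, nonnegative bounds so disjointness can be verified.
    """

    signal_roi: tuple[slice, ...]
    background_roi: tuple[slice, ...]

    def __post_init__(self) -> None:
        for roi in (self.signal_roi, self.background_roi):
            for s in roi:
                if s.start is None or s.stop is None or s.stop <= s.start:
                    raise ValueError(f"ROI slices need explicit start < stop, got {roi}")
        overlap = all(
            a.start < b.stop and b.start < a.stop
            for a, b in zip(self.signal_roi, self.background_roi)
        )
        if overlap:
            raise ValueError("signal and background ROIs must be disjoint")


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB with peak fixed at 1.

    The reference is assumed normalized to [0, 1], so
    ``psnr = 10 log10(1 / MSE)``.  Identical images return ``inf``.  Note
    the roles are not symmetric: normalization (the peak) belongs to the
    reference.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return np.inf
    return float(10.0 * np.log10(1.0 / mse))


def roi_snr(image: np.ndarray, rois: RoiPair) -> float:
    """Mean squared intensity of the signal ROI over that of the background.

    ``SNR = |S|^-1 sum_S I(x)^2  /  |B|^-1 sum_B I(x)^2``; a background
    region with exactly zero power is an error rather than an infinity.
    """
    image = np.asarray(image, dtype=np.float64)
    sig = image[rois.signal_roi]
    bg = image[rois.background_roi]
    if sig.size == 0 or bg.size == 0:
        raise ValueError("ROIs must be nonempty within the image")
    bg_power = float(np.mean(bg**2))
    if bg_power == 0.0:
        raise ValueError("background ROI has zero power; choose a region with samples")
    return float(np.mean(sig**2)) / bg_power
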