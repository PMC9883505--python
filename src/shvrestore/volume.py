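"""In-memory image container with explicit axis bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ImageVolume", "NormalizationRecord", "AXIS_CANONICAL"]

#: Canonical axis order; images carry a subset ending in "YX".
AXIS_CANONICAL = "TZYX"


@dataclass(frozen=True)
class NormalizationRecord:
    """Global intensity scaling applied before restoration.

    ``max_value`` is the original maximum; ``offset`` the subtracted
    minimum (0 unless min-shifting was requested).  ``denormalize``
    inverts ``normalize`` to within 1e-6 relative.
    """

    max_value: float
    offset: float = 0.0


@dataclass(frozen=True)
class ImageVolume:
    """A nonnegative intensity array with named axes.

    ``axes`` is a string over {T, Z, Y, X} matching ``data.ndim``, always
    containing "YX" and ordered canonically (T, Z, Y, X).  ``source_dtype``
    remembers the on-disk dtype for round-trips.
    """

    data: np.ndarray
    axes: str = "YX"
    normalization: NormalizationRecord | None = None
    source_dtype: np.dtype | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        ax = self.axes.upper()
        if len(ax) != data.ndim:
            raise ValueError(f"axes {ax!r} do not match array dimensionality {data.ndim}")
        if len(set(ax)) != len(ax) or any(a not in AXIS_CANONICAL for a in ax):
            raise ValueError(f"axes must be a unique subset of {AXIS_CANONICAL!r}, got {ax!r}")
        if not ax.endswith("YX"):
            raise ValueError(f"axes must be canonical (subset of TZYX ending in YX), got {ax!r}")
        object.__setattr__(self, "axes", ax)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def axis_index(self, name: str) -> int:
        i = self.axes.find(name.upper())
        if i < 0:
            raise KeyError(f"axis {name!r} not present in {self.axes!r}")
        return i

    @property
    def has_time(self) -> bool:
        return "T" in self.axes

    @property
    def has_z(self) -> bool:
        return "Z" in self.axes

    def with_data(self, data: np.ndarray, **changes) -> "ImageVolume":
        if data.shape != self.data.shape:
            raise ValueError(f"replacement data shape {data.shape} differs from {self.data.shape}")
        return replace(self, data=data, **changes)


def as_volume(image, axes: str | None = None) -> ImageVolume:
    """Coerce an array (or pass through a volume), inferring axes by rank.

    Rank 2 -> YX, 3 -> ZYX, 4 -> TZYX unless ``axes`` is given.
    """
    if isinstance(image, ImageVolume):
        return image
    arr = np.asarray(image, dtype=np.float64)
    if axes is None:
        axes = {2: "YX", 3: "ZYX", 4: "TZYX"}.get(arr.ndim)
        if axes is None:
            raise ValueError(f"cannot infer axes for a {arr.ndim}D array")
    return ImageVolume(data=arr, axes=axes)
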