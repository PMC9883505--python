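"""TIFF reading/writing with explicit axis conventions.

Volumes are stored as single- or multi-page grayscale TIFF, one channel
per file.  Axes are canonicalized to a subset of (T, Z, Y, X) on read;
where the file metadata is silent and the rank is ambiguous (3D could be
a Z stack or a time series), an explicit ``axes`` argument is required
rather than guessed.
"""

from __future__ import annotations

import numpy as np
import tifffile

from .volume import AXIS_CANONICAL, ImageVolume, NormalizationRecord
from .pipelines import denormalize

__all__ = ["read_volume", "write_volume"]

_ALLOWED = {"YX", "ZYX", "TYX", "TZYX"}


def _canonicalize(data: np.ndarray, axes: str) -> tuple[np.ndarray, str]:
    axes = axes.upper()
    if len(axes) != data.ndim:
        raise ValueError(f"axes {axes!r} do not match data rank {data.ndim}")
    order = [axes.index(a) for a in AXIS_CANONICAL if a in axes]
    canonical = "".join(a for a in AXIS_CANONICAL if a in axes)
    if canonical not in _ALLOWED:
        raise ValueError(f"unsupported axis set {axes!r}; need Y and X, optional T/Z")
    return np.transpose(data, order), canonical


def read_volume(path, axes: str | None = None) -> ImageVolume:
    """Read a grayscale TIFF as a float volume.

    ``axes`` overrides/provides the interpretation (e.g. ``"ZYX"`` or
    ``"TYX"`` for a 3-page file).  Without it, 2D files are (Y, X), and
    higher ranks use the TIFF series metadata; a metadata-free multi-page
    file is ambiguous and raises.  Integer data is converted to float64
    without rescaling; the original dtype is retained for round-trips.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        meta_axes = series.axes
        # files whose pages were written as independent series: stack them
        if axes is not None and len(axes) == data.ndim + 1 and len(tf.pages) > 1:
            data = np.stack([p.asarray() for p in tf.pages])
            meta_axes = ""
    source_dtype = data.dtype
    data = np.asarray(data, dtype=np.float64)

    if axes is not None:
        declared = axes.upper()
    elif data.ndim == 2:
        declared = "YX"
    else:
        meta = (meta_axes or "").upper()
        if len(meta) == data.ndim and set(meta) <= set("TZYX"):
            declared = meta
        else:
            raise ValueError(
                f"cannot infer axes for {data.ndim}D file {path} "
                f"(metadata says {meta_axes!r}); pass axes='ZYX' or 'TYX'"
            )
    data, canonical = _canonicalize(data, declared)
    return ImageVolume(data=data, axes=canonical, source_dtype=source_dtype)


def write_volume(
    image: ImageVolume | np.ndarray,
    path,
    record: NormalizationRecord | None = None,
    dtype: str | np.dtype = "float32",
) -> int:
    """Write a volume as multi-page TIFF (float32 by default).

    If ``record`` is given the data is denormalized back to the original
    intensity scale first.  When casting to an integer dtype, values are
    clipped to the dtype range; the number of saturated pixels is
    returned (0 for in-range images) so callers can log it.
    """
    if isinstance(image, ImageVolume):
        data, axes = image.data, image.axes
    else:
        data = np.asarray(image, dtype=np.float64)
        axes = {2: "YX", 3: "ZYX", 4: "TZYX"}.get(data.ndim, None)
    if not np.all(np.isfinite(data)):
        raise ValueError("refusing to write non-finite values")
    if record is not None:
        data = denormalize(data, record)

    dtype = np.dtype(dtype)
    saturated = 0
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        saturated = int(np.count_nonzero((data < info.min) | (data > info.max)))
        data = np.clip(np.rint(data), info.min, info.max)
    out = data.astype(dtype)
    metadata = {"axes": axes} if axes else None
    tifffile.imwrite(path, out, metadata=metadata, photometric="minisblack")
    return saturated
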