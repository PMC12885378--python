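"""Image I/O and axis canonicalisation.

Images move through the pipeline as :class:`ImageVolume` objects: a numpy
array with an explicit axis string drawn from ``TCZYX`` and a physical pixel
size.  On disk they are OME-TIFF files (via :mod:`tifffile`) or zarr arrays
carrying an ``axes`` attribute.  All readers promote to the canonical 5D
``TCZYX`` order so downstream code never guesses at layout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
import zarr

CANONICAL_AXES = "TCZYX"


@dataclass
class ImageVolume:
    """A multi-channel intensity array with explicit axis semantics.

    Parameters
    ----------
    data:
        Intensity array whose dimensions match ``axes``.
    axes:
        Axis string, a subsequence of ``"TCZYX"`` (case-insensitive).
    pixel_size_um:
        Lateral pixel size in micrometres.
    """

    data: np.ndarray
    axes: str = "YX"
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.axes = self.axes.upper()
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"data has {self.data.ndim} dimensions but axes is {self.axes!r}"
            )
        bad = set(self.axes) - set(CANONICAL_AXES)
        if bad:
            raise ValueError(f"unknown axes {sorted(bad)}; allowed: {CANONICAL_AXES}")

    def canonical(self) -> "ImageVolume":
        """Return a 5D ``TCZYX`` view with singleton axes inserted."""
        data = self.data
        axes = self.axes
        # bring present axes into canonical relative order
        order = sorted(range(len(axes)), key=lambda i: CANONICAL_AXES.index(axes[i]))
        data = np.transpose(data, order)
        axes = "".join(axes[i] for i in order)
        for pos, ax in enumerate(CANONICAL_AXES):
            if ax not in axes:
                data = np.expand_dims(data, pos)
                axes = axes[:pos] + ax + axes[pos:]
        return ImageVolume(data, axes, self.pixel_size_um)

    def plane(self, t: int = 0, c: int = 0, z: int = 0) -> np.ndarray:
        """Extract a single ``(y, x)`` plane from the canonical volume."""
        return self.canonical().data[t, c, z]

    def max_project(self, axis: str = "Z") -> "ImageVolume":
        axis = axis.upper()
        if axis not in self.axes:
            raise ValueError(f"axis {axis!r} not present in {self.axes!r}")
        i = self.axes.index(axis)
        return ImageVolume(
            self.data.max(axis=i), self.axes.replace(axis, ""), self.pixel_size_um
        )


def max_project(volume, axis: str = "Z"):
    """Per-pixel maximum along one named axis.

    Accepts an :class:`ImageVolume` (returns an :class:`ImageVolume`) or a
    bare array with an integer axis (returns an array).
    """
    if isinstance(volume, ImageVolume):
        return volume.max_project(axis)
    return np.asarray(volume).max(axis=int(axis) if not isinstance(axis, int) else axis)


def _is_zarr(path: str) -> bool:
    return str(path).rstrip("/").endswith(".zarr") or os.path.isdir(path)


def write_image(path, volume: ImageVolume) -> None:
    """Write an :class:`ImageVolume` to OME-TIFF (``.tif``/``.tiff``) or zarr."""
    vol = volume.canonical()
    path = str(path)
    if _is_zarr(path):
        arr = zarr.create_array(
            store=path, shape=vol.data.shape, dtype=vol.data.dtype, overwrite=True
        )
        arr[:] = vol.data
        arr.attrs["axes"] = vol.axes.lower()
        arr.attrs["pixel_size_um"] = float(vol.pixel_size_um)
    else:
        tifffile.imwrite(
            path,
            vol.data,
            ome=True,
            metadata={
                "axes": vol.axes,
                "PhysicalSizeX": float(vol.pixel_size_um),
                "PhysicalSizeY": float(vol.pixel_size_um),
            },
        )


def read_image(path, axes: str | None = None) -> ImageVolume:
    """Read an OME-TIFF or zarr image into canonical ``TCZYX`` order.

    Parameters
    ----------
    path:
        File (TIFF) or directory (zarr) path.
    axes:
        Explicit axis string overriding file metadata.  Required when the
        file carries no usable axis metadata.
    """
    path = str(path)
    if _is_zarr(path):
        arr = zarr.open_array(path, mode="r")
        data = arr[:]
        meta_axes = arr.attrs.get("axes")
        pixel_size = float(arr.attrs.get("pixel_size_um", 1.0))
    else:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            meta_axes = series.axes
            pixel_size = 1.0
            if tf.is_ome and tf.ome_metadata:
                import re

                m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', tf.ome_metadata)
                if m:
                    pixel_size = float(m.group(1))
    use_axes = (axes or meta_axes or "").upper()
    if not use_axes or set(use_axes) - set(CANONICAL_AXES):
        raise ValueError(
            f"no usable axis metadata in {path!r} (got {meta_axes!r}); "
            "pass an explicit axes string such as 'YX' or 'TCZYX'"
        )
    if len(use_axes) != np.ndim(data):
        raise ValueError(
            f"axes {use_axes!r} do not match data with {np.ndim(data)} dimensions"
        )
    return ImageVolume(np.asarray(data), use_axes, pixel_size).canonical()
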