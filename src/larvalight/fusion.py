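"""Dual-illumination fusion, tile stitching, and light-sheet flat-fielding.

A light sheet is thin at its focus and diverges away from it, so the
illumination intensity across the field of view is not uniform.  Along the
sheet propagation direction ``x`` the intensity follows a Lorentzian centred
on the sheet focus, and along the vertical direction ``y`` a Gaussian:

    I(x, y) = I0 / (1 + ((x - xc) / xR)^2) * exp(-(y - yc)^2 / (2 sigma_y^2))

The five parameters are fit to an image of a uniform fluorophore solution and
the fitted field, normalised to its own peak, is divided out of every plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .io import ImageVolume

log = logging.getLogger(__name__)


@dataclass
class SheetFieldParams:
    """Parameters of the separable Lorentzian(x) x Gaussian(y) sheet field.

    I0 : peak intensity (a.u.); xc : sheet focus along propagation axis (px);
    xR : Lorentzian half-width (px); yc : vertical sheet centre (px);
    sigma_y : vertical Gaussian width (px).
    """

    I0: float
    xc: float
    xR: float
    yc: float
    sigma_y: float

    def __post_init__(self) -> None:
        if not (self.I0 > 0 and self.xR > 0 and self.sigma_y > 0):
            raise ValueError(
                f"require I0 > 0, xR > 0, sigma_y > 0; got I0={self.I0}, "
                f"xR={self.xR}, sigma_y={self.sigma_y}"
            )

    def evaluate(self, y, x) -> np.ndarray:
        """Evaluate the field at (y, x); inputs broadcast."""
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        lorentz = 1.0 / (1.0 + ((x - self.xc) / self.xR) ** 2)
        gauss = np.exp(-((y - self.yc) ** 2) / (2.0 * self.sigma_y**2))
        return self.I0 * lorentz * gauss

    def render(self, shape: tuple[int, int]) -> np.ndarray:
        """Evaluate on a full (ny, nx) pixel grid (pixel-centre coordinates)."""
        yy, xx = np.indices(shape)
        return self.evaluate(yy, xx)

    def as_array(self) -> np.ndarray:
        return np.array([self.I0, self.xc, self.xR, self.yc, self.sigma_y])


@dataclass
class SheetFieldFit:
    params: SheetFieldParams
    residual_norm: float
    n_iterations: int


@dataclass
class TileSet:
    """Tiles plus their stage offsets in physical units (same axis order as
    the trailing spatial axes of each tile)."""

    tiles: Sequence[np.ndarray]
    stage_offsets: Sequence[Sequence[float]]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        shapes = {t.shape for t in self.tiles}
        if len(shapes) > 1:
            raise ValueError(f"tiles must share a shape; got {sorted(shapes)}")
        if len(self.stage_offsets) != len(self.tiles):
            raise ValueError("one stage offset required per tile")
        offs = np.asarray(self.stage_offsets, dtype=float)
        if not np.all(np.isfinite(offs)):
            raise ValueError("stage offsets must be finite")
        if self.tiles and offs.shape[1] > self.tiles[0].ndim:
            raise ValueError(
                f"offset dimensionality {offs.shape[1]} exceeds tile rank "
                f"{self.tiles[0].ndim}"
            )


def average_illuminations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Voxelwise arithmetic mean of the two sheet-illumination exposures."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return (a.astype(np.float64) + b.astype(np.float64)) / 2.0


def fuse_tiles(tiles: TileSet, return_counts: bool = False):
    """Paste tiles onto a common canvas at their stage positions.

    Offsets are converted to voxels by dividing by the pixel size and rounding
    to the nearest integer; overlapping voxels are resolved by the arithmetic
    mean of all contributing tiles, uncovered canvas is zero.
    """
    offs = np.asarray(tiles.stage_offsets, dtype=float) / tiles.pixel_size_um
    offs = np.round(offs).astype(int)
    offs -= offs.min(axis=0)  # shift to a nonnegative canvas
    ndim_off = offs.shape[1]
    tile_shape = np.asarray(tiles.tiles[0].shape)
    spatial = tile_shape[-ndim_off:]
    canvas_spatial = offs.max(axis=0) + spatial
    canvas_shape = tuple(tile_shape[:-ndim_off]) + tuple(canvas_spatial)
    acc = np.zeros(canvas_shape, dtype=np.float64)
    cnt = np.zeros(canvas_shape[-ndim_off:], dtype=np.int32)
    for tile, off in zip(tiles.tiles, offs):
        sl = tuple(slice(o, o + s) for o, s in zip(off, spatial))
        acc[(Ellipsis,) + sl] += tile
        cnt[sl] += 1
    with np.errstate(invalid="ignore"):
        fused = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    if return_counts:
        return fused, cnt
    return fused


def _initial_guess(image: np.ndarray) -> SheetFieldParams:
    """Analytic initialisation: peak position/value and half-max widths."""
    iy, ix = np.unravel_index(np.argmax(image), image.shape)
    I0 = float(image[iy, ix])
    if I0 <= 0:
        raise ValueError("image maximum must be positive to initialise the fit")
    row = image[iy, :]
    col = image[:, ix]

    def half_width(profile, center):
        above = np.flatnonzero(profile >= 0.5 * profile[center])
        if above.size < 2:
            return max(len(profile) / 4.0, 1.0)
        return max((above[-1] - above[0]) / 2.0, 1.0)

    xR = half_width(row, ix)
    # Gaussian FWHM = 2.355 sigma
    sigma_y = half_width(col, iy) * 2.0 / 2.355
    return SheetFieldParams(I0, float(ix), float(xR), float(iy), float(sigma_y))


def fit_sheet_field(
    image: np.ndarray,
    init: Optional[SheetFieldParams] = None,
    axes: str = "YX",
    max_nfev: int = 2000,
) -> SheetFieldFit:
    """Least-squares fit of the five sheet-field parameters to a uniform
    fluorophore reference image.

    ``axes`` states the layout of ``image``; pass ``"XY"`` if the propagation
    axis is the first array axis.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("fit_sheet_field expects a single 2D plane")
    axes = axes.upper()
    if axes == "XY":
        image = image.T
    elif axes != "YX":
        raise ValueError(f"axes must be 'YX' or 'XY', got {axes!r}")
    guess = init or _initial_guess(image)
    yy, xx = np.indices(image.shape)

    def residual(p):
        I0, xc, xR, yc, sy = p
        model = I0 / (1.0 + ((xx - xc) / xR) ** 2) * np.exp(
            -((yy - yc) ** 2) / (2.0 * sy**2)
        )
        return (model - image).ravel()

    res = least_squares(
        residual,
        guess.as_array(),
        bounds=([1e-12, -np.inf, 1e-9, -np.inf, 1e-9], np.inf),
        max_nfev=max_nfev,
    )
    if not res.success:
        raise RuntimeError(
            f"sheet-field fit did not converge after {res.nfev} evaluations; "
            f"last iterate {res.x}"
        )
    p = res.x
    return SheetFieldFit(
        SheetFieldParams(*[float(v) for v in p]),
        residual_norm=float(np.linalg.norm(res.fun)),
        n_iterations=int(res.nfev),
    )


def apply_sheet_field(image: np.ndarray, params: SheetFieldParams) -> np.ndarray:
    """Multiply each (y, x) plane by the peak-normalised sheet field.

    This is the forward model the phantom uses; ``correct_sheet_field``
    inverts it exactly away from the division floor.
    """
    image = np.asarray(image, dtype=float)
    field = params.render(image.shape[-2:])
    field = field / field.max()
    return image * field


def correct_sheet_field(
    image, params: SheetFieldParams, eps: float = 0.05, crop_fraction: float = 0.0
):
    """Divide each plane by the fitted field normalised to its own maximum.

    The peak region is therefore unchanged.  Where the normalised model falls
    below ``eps`` the divisor is floored at ``eps`` to avoid noise blow-up at
    the field edges; engaging the floor on more than 10% of pixels logs a
    warning.  ``crop_fraction`` optionally crops that fraction of rows off the
    top and bottom before correction (low-intensity sheet artifacts).
    """
    is_volume = isinstance(image, ImageVolume)
    data = image.canonical().data if is_volume else np.asarray(image, dtype=float)
    if crop_fraction > 0:
        ny = data.shape[-2]
        c = int(round(crop_fraction * ny))
        sl = (Ellipsis, slice(c, ny - c), slice(None))
        data = data[sl]
    field = params.render(data.shape[-2:])
    field = field / field.max()
    floored = field < eps
    frac = floored.mean()
    if frac > 0.10:
        log.warning(
            "sheet-field floor engaged on %.1f%% of pixels (eps=%g)",
            100 * frac,
            eps,
        )
    divisor = np.maximum(field, eps)
    out = data.astype(np.float64) / divisor
    if is_volume:
        return ImageVolume(out, image.canonical().axes, image.pixel_size_um)
    return out
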