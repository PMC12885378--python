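"""Synthetic larva ("phantom") generator with full ground truth.

The phantom emulates the statistical structure the quantification stages
assume: a ~3 mm elongated larva whose fat body occupies a fixed fraction of
the field of view, with bilaterally symmetric rows of cells laid out along
the anterior-posterior (A-P) axis.  Reporter expression follows the measured
"partial response" pattern — high in the anterior and posterior lobes, low in
the middle — with per-larva contrasts configurable.  The default contrasts
encode the observed effect sizes: anterior mean expression 14x the middle,
posterior 5x, a uniform control marker only 1.3x brighter anteriorly, and
per-cell accumulation slopes whose regional medians are 2.0x (anterior) and
1.6x (posterior) the middle median.

Every generated cell and bacterial object is recorded in a truth manifest
(:class:`PhantomTruth`) so downstream stages can be validated by parameter
recovery, with no external data.

Rendering conventions: anterior is at low x; positions are 0-based pixel
indices with pixel-centre coordinates; cells are hard discs (2D) or spheres
(3D) of constant intensity composited with the tissue background by
per-pixel maximum, so a circle-sum of matching radius recovers the deposited
intensity exactly on a noiseless render.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fusion import SheetFieldParams, apply_sheet_field
from .io import ImageVolume

log = logging.getLogger(__name__)

REGIONS = ("anterior", "middle", "posterior")


@dataclass
class BacteriaSpec:
    """Counts and rendering parameters for the planktonic-bacteria phantom.

    Objects are Gaussian spots whose integrated intensity equals
    ``member count x unit_intensity``; singles and doublets stand in for
    planktonic cells, larger clusters for bacteria internalised by host cells.
    """

    n_singles: int = 60
    n_doublets: int = 15
    cluster_sizes: Sequence[int] = (4, 6, 9)
    unit_intensity: float = 2000.0
    intensity_cv: float = 0.0
    spot_sigma_px: float = 2.0
    ap_density: str = "u"  # "u" (mild U-shape along A-P) or "uniform"
    u_strength: float = 0.8
    min_separation_px: float = 14.0


@dataclass
class TranscriptSpec:
    """Generative model for the per-cell transcript table: each cell has a
    Poisson total count and a Binomial count for the gene of interest, whose
    true frequency follows a configurable A-P profile."""

    mean_total_counts: float = 200.0
    kind: str = "anterior_step"  # "flat", "anterior_step", or "u"
    freq_low: float = 0.005
    freq_high: float = 0.02
    step_at: float = 0.3


@dataclass
class PhantomConfig:
    """Full generative parameter set for one synthetic larva.

    All intensities are arbitrary units (a.u.), lengths are pixels, rates
    are a.u. per hour.  Identical ``rng_seed`` + config reproduce identical
    outputs bit for bit.
    """

    rng_seed: int = 0
    image_shape: tuple = (220, 900)  # (y, x) or (z, y, x)
    pixel_size_um: float = 2.0
    larva_length_frac: float = 0.8
    n_cells: int = 180
    cell_radius_px: int = 4
    region_boundaries: tuple = (0.25, 0.65)
    expression_contrast: tuple = (14.0, 5.0)  # anterior:middle, posterior:middle
    marker_contrast: float = 1.3  # anterior:middle for the control channel
    middle_mean: float = 100.0  # middle-region mean reporter pixel value
    intensity_cv: float = 0.35  # per-cell log-normal spread around region mean
    marker_middle_mean: float = 60.0
    marker_cv: float = 0.10
    rate_medians: dict = field(
        default_factory=lambda: {"anterior": 40.0, "middle": 20.0, "posterior": 32.0}
    )
    rate_cv: float = 0.4
    allele_copies: int = 1
    background_level: float = 5.0  # outside-larva background (reporter channel)
    body_level: float = 20.0  # larva-body autofluorescence (reporter channel)
    marker_background: float = 2.0
    noise_sd: float = 5.0  # additive Gaussian, default 5% of middle mean
    sheet_field: Optional[SheetFieldParams] = None
    bacteria_spec: BacteriaSpec = field(default_factory=BacteriaSpec)
    transcripts: TranscriptSpec = field(default_factory=TranscriptSpec)
    n_rows: int = 4
    row_spacing_px: int = 18

    def validate(self) -> None:
        if self.n_cells < 1 or self.cell_radius_px < 1 or self.n_rows < 1:
            raise ValueError("counts and radii must be positive")
        b0, b1 = self.region_boundaries
        if not (0.0 < b0 < b1 < 1.0):
            raise ValueError(
                f"region_boundaries must be strictly increasing within (0,1); "
                f"got {self.region_boundaries}"
            )
        if not (0.0 < self.larva_length_frac <= 1.0):
            raise ValueError("larva_length_frac must be in (0, 1]")
        if min(self.expression_contrast) < 1 or self.marker_contrast < 1:
            raise ValueError("contrasts are ratios to the middle and must be >= 1")
        if self.allele_copies not in (1, 2):
            raise ValueError("allele_copies must be 1 or 2")
        if len(self.image_shape) not in (2, 3):
            raise ValueError("image_shape must be (y, x) or (z, y, x)")
        if set(self.rate_medians) != set(REGIONS):
            raise ValueError(f"rate_medians must have keys {REGIONS}")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sheet_field is not None:
            d["sheet_field"] = asdict(self.sheet_field)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown phantom config keys: {sorted(unknown)}")
        if d.get("sheet_field") is not None and not isinstance(
            d["sheet_field"], SheetFieldParams
        ):
            d["sheet_field"] = SheetFieldParams(**d["sheet_field"])
        if "bacteria_spec" in d and isinstance(d["bacteria_spec"], dict):
            d["bacteria_spec"] = BacteriaSpec(**d["bacteria_spec"])
        if "transcripts" in d and isinstance(d["transcripts"], dict):
            d["transcripts"] = TranscriptSpec(**d["transcripts"])
        for key in ("image_shape", "region_boundaries", "expression_contrast"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground-truth manifest for one phantom: one record per rendered cell
    and bacterial object, the sheet parameters used, and a config echo."""

    cells: Optional[pd.DataFrame]
    bacteria: Optional[pd.DataFrame]
    sheet: Optional[SheetFieldParams]
    config: PhantomConfig
    fatbody_extent: tuple
    times: Optional[np.ndarray] = None

    def write(self, outdir) -> None:
        import os
        import yaml

        os.makedirs(outdir, exist_ok=True)
        if self.cells is not None:
            self.cells.to_csv(os.path.join(outdir, "truth_cells.csv"), index=False)
        if self.bacteria is not None:
            self.bacteria.to_csv(
                os.path.join(outdir, "truth_bacteria.csv"), index=False
            )
        with open(os.path.join(outdir, "phantom_config.yaml"), "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# geometry helpers


def fatbody_extent(config: PhantomConfig) -> tuple:
    """(x0, x1) pixel extent of the fat body along the A-P (x) axis."""
    nx = config.image_shape[-1]
    length = config.larva_length_frac * nx
    x0 = (nx - length) / 2.0
    return (x0, x0 + length)


def assign_region(ap_fraction, boundaries) -> np.ndarray:
    """Map A-P fractions in [0, 1] to anterior/middle/posterior labels."""
    ap = np.asarray(ap_fraction, dtype=float)
    b0, b1 = boundaries
    out = np.where(ap < b0, "anterior", np.where(ap < b1, "middle", "posterior"))
    return out.astype(object)


def ball_offsets(radius: int, ndim: int = 2) -> np.ndarray:
    """Integer offsets of the discrete disc (2D) or ball (3D) of ``radius``."""
    r = int(radius)
    grids = np.meshgrid(*([np.arange(-r, r + 1)] * ndim), indexing="ij")
    dist2 = sum(g**2 for g in grids)
    keep = dist2 <= r * r
    return np.stack([g[keep] for g in grids], axis=1)


def _layout_cells(config: PhantomConfig) -> pd.DataFrame:
    """Deterministic grid layout: ``n_rows`` bilaterally symmetric rows of
    cells evenly spaced along the fat-body extent."""
    x0, x1 = fatbody_extent(config)
    length = x1 - x0
    ny = config.image_shape[-2]
    yc = ny // 2
    n_cols = int(np.ceil(config.n_cells / config.n_rows))
    spacing = length / n_cols
    xs = x0 + (np.arange(n_cols) + 0.5) * spacing
    offsets = (np.arange(config.n_rows) - (config.n_rows - 1) / 2.0) * (
        config.row_spacing_px
    )
    rows = []
    cid = 0
    for j in range(n_cols):
        for off in offsets:
            if cid >= config.n_cells:
                break
            rows.append((cid, float(yc + off), float(xs[j])))
            cid += 1
    df = pd.DataFrame(rows, columns=["cell_id", "y", "x"])
    df["y"] = np.round(df["y"]).astype(int)
    df["x"] = np.round(df["x"]).astype(int)
    df["ap_fraction"] = (df["x"] - x0) / length
    df["region"] = assign_region(df["ap_fraction"], config.region_boundaries)
    r = config.cell_radius_px
    bad = df.index[
        (df["y"] - r < 0)
        | (df["y"] + r >= ny)
        | (df["x"] - r < 0)
        | (df["x"] + r >= config.image_shape[-1])
    ].tolist()
    if bad:
        raise ValueError(
            f"cells fall outside the image (indices {bad}); enlarge image_shape "
            "or reduce n_cells / cell_radius_px"
        )
    if len(config.image_shape) == 3:
        df.insert(1, "z", config.image_shape[0] // 2)  # monolayer sheet
    return df


def _lognormal_with_mean(rng, mean, cv, size):
    """Log-normal draws with the requested arithmetic mean and CV."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if cv <= 0:
        return mean.copy()
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma)


def _lognormal_with_median(rng, median, cv, size):
    """Log-normal draws with the requested median and CV."""
    median = np.broadcast_to(np.asarray(median, dtype=float), size)
    if cv <= 0:
        return median.copy()
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(np.log(median), sigma)


def _body_mask_bounds(config: PhantomConfig):
    """(y slice, x slice) of the larva-body band."""
    x0, x1 = fatbody_extent(config)
    ny = config.image_shape[-2]
    yc = ny // 2
    half = (config.n_rows - 1) / 2.0 * config.row_spacing_px + config.cell_radius_px + 8
    ylo = max(int(yc - half), 0)
    yhi = min(int(yc + half) + 1, ny)
    xlo = max(int(x0) - 10, 0)
    xhi = min(int(x1) + 10, config.image_shape[-1])
    return slice(ylo, yhi), slice(xlo, xhi)


def _deposit(canvas: np.ndarray, centers: np.ndarray, values: np.ndarray, radius: int):
    """Max-composite constant discs/spheres onto ``canvas`` in place."""
    offs = ball_offsets(radius, canvas.ndim)
    for center, val in zip(centers, values):
        idx = tuple((center + offs).T)
        canvas[idx] = np.maximum(canvas[idx], val)


def _render_channels(config, cells, reporter_vals, marker_vals, rng, add_noise=True):
    shape = tuple(config.image_shape)
    ndim = len(shape)
    rep = np.full(shape, float(config.background_level))
    ysl, xsl = _body_mask_bounds(config)
    body_idx = (Ellipsis, ysl, xsl) if ndim == 3 else (ysl, xsl)
    rep[body_idx] = max(config.body_level, config.background_level)
    mark = np.full(shape, float(config.marker_background))
    cols = ["z", "y", "x"] if ndim == 3 else ["y", "x"]
    centers = cells[cols].to_numpy(dtype=int)
    _deposit(rep, centers, reporter_vals, config.cell_radius_px)
    _deposit(mark, centers, marker_vals, config.cell_radius_px)
    stack = np.stack([rep, mark])
    if config.sheet_field is not None:
        stack = apply_sheet_field(stack, config.sheet_field)
    if add_noise and config.noise_sd > 0:
        stack = stack + rng.normal(0.0, config.noise_sd, stack.shape)
    axes = "CZYX" if ndim == 3 else "CYX"
    return ImageVolume(stack, axes, config.pixel_size_um)


# ---------------------------------------------------------------------------
# generators


def generate_snapshot(config: PhantomConfig):
    """Render a two-channel endpoint snapshot (reporter, control marker).

    Returns ``(ImageVolume, PhantomTruth)``.  Per-cell reporter means are
    drawn log-normally around the region mean (middle = ``middle_mean``,
    anterior/posterior scaled by ``expression_contrast``), multiplied by
    ``allele_copies``; the marker channel is uniform up to
    ``marker_contrast`` in the anterior.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    cells = _layout_cells(config)
    ca, cp = config.expression_contrast
    region_mean = {
        "anterior": ca * config.middle_mean,
        "middle": config.middle_mean,
        "posterior": cp * config.middle_mean,
    }
    means = cells["region"].map(region_mean).to_numpy(dtype=float)
    values = _lognormal_with_mean(rng, means, config.intensity_cv, len(cells))
    values = values * config.allele_copies
    marker_mean = np.where(
        cells["region"] == "anterior",
        config.marker_contrast * config.marker_middle_mean,
        config.marker_middle_mean,
    )
    marker_vals = _lognormal_with_mean(rng, marker_mean, config.marker_cv, len(cells))
    image = _render_channels(config, cells, values, marker_vals, rng)
    n_px = len(ball_offsets(config.cell_radius_px, len(config.image_shape)))
    truth_cells = cells.copy()
    truth_cells["mean_intensity"] = values
    truth_cells["deposited_intensity"] = values * n_px
    truth_cells["marker_intensity"] = marker_vals
    truth_cells["marker_deposited"] = marker_vals * n_px
    truth = PhantomTruth(
        cells=truth_cells,
        bacteria=None,
        sheet=config.sheet_field,
        config=config,
        fatbody_extent=fatbody_extent(config),
    )
    return image, truth


def generate_timeseries(config: PhantomConfig, times):
    """Render a reporter time series with deterministic linear accumulation.

    Per-cell intensity at time ``t`` (hours) is ``intercept + slope * t``
    plus noise; slopes are drawn log-normally per region with medians
    ``rate_medians`` and CV ``rate_cv``.  The intercept is the tissue
    background level (cells start dark).  Returns a list of per-timepoint
    :class:`ImageVolume` plus the truth manifest recording every slope.
    """
    config.validate()
    times = np.asarray(times, dtype=float)
    if times.size < 3 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing with >= 3 points")
    rng = np.random.default_rng(config.rng_seed)
    cells = _layout_cells(config)
    medians = cells["region"].map(config.rate_medians).to_numpy(dtype=float)
    slopes = _lognormal_with_median(rng, medians, config.rate_cv, len(cells))
    slopes = slopes * config.allele_copies
    intercept = float(config.body_level)
    marker_vals = np.full(len(cells), 3.0 * config.marker_background)
    frames = []
    for t in times:
        vals = intercept + slopes * t
        frames.append(_render_channels(config, cells, vals, marker_vals, rng))
    truth_cells = cells.copy()
    truth_cells["slope"] = slopes
    truth_cells["intercept"] = intercept
    truth = PhantomTruth(
        cells=truth_cells,
        bacteria=None,
        sheet=config.sheet_field,
        config=config,
        fatbody_extent=fatbody_extent(config),
        times=times,
    )
    return frames, truth


def _sample_ap_positions(rng, n, spec: BacteriaSpec):
    """Inverse-CDF sample of A-P fractions from the configured density."""
    if spec.ap_density == "uniform":
        return rng.random(n)
    if spec.ap_density != "u":
        raise ValueError(f"unknown ap_density {spec.ap_density!r}")
    grid = np.linspace(0.0, 1.0, 1025)
    pdf = 1.0 + spec.u_strength * (2.0 * grid - 1.0) ** 2
    cdf = np.cumsum(pdf)
    cdf = (cdf - cdf[0]) / (cdf[-1] - cdf[0])
    return np.interp(rng.random(n), cdf, grid)


def generate_bacteria_field(config: PhantomConfig):
    """Render a single-channel field of planktonic bacteria and clusters.

    Each object is a Gaussian spot of integrated intensity
    ``count x unit_intensity`` (discretely normalised, so the rendered sum is
    exact); placement along A-P follows the configured density, a mild
    U-shape by default.  Objects are rejection-sampled to keep a minimum
    separation; an overlapping-object fraction above 20% logs a warning.
    """
    config.validate()
    spec = config.bacteria_spec
    counts = (
        [1] * spec.n_singles + [2] * spec.n_doublets + list(spec.cluster_sizes)
    )
    if not counts:
        raise ValueError("bacteria_spec is empty")
    rng = np.random.default_rng(config.rng_seed)
    x0, x1 = fatbody_extent(config)
    ny = config.image_shape[-2]
    nx = config.image_shape[-1]
    ysl, _ = _body_mask_bounds(config)
    ylo, yhi = ysl.start, ysl.stop
    placed = []
    for count in counts:
        for _ in range(200):
            f = float(_sample_ap_positions(rng, 1, spec)[0])
            x = x0 + f * (x1 - x0)
            y = ylo + rng.random() * (yhi - 1 - ylo)
            if all(
                (x - px) ** 2 + (y - py) ** 2 >= spec.min_separation_px**2
                for py, px in ((p[0], p[1]) for p in placed)
            ):
                placed.append((y, x, f))
                break
        else:
            raise RuntimeError(
                "could not place bacteria with the requested minimum separation; "
                "reduce counts or min_separation_px"
            )
    counts = np.asarray(counts)
    ys = np.array([p[0] for p in placed])
    xs = np.array([p[1] for p in placed])
    fracs = np.array([p[2] for p in placed])
    factor = _lognormal_with_mean(rng, 1.0, spec.intensity_cv, len(counts))
    intensities = counts * spec.unit_intensity * factor
    sigmas = spec.spot_sigma_px * counts ** (1.0 / 3.0)
    img = np.full((ny, nx), float(config.background_level))
    for y, x, inten, sig in zip(ys, xs, intensities, sigmas):
        r = int(np.ceil(4 * sig))
        yy, xx = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
        kern = np.exp(-(yy**2 + xx**2) / (2 * sig**2))
        kern = kern / kern.sum() * inten
        iy, ix = int(round(y)), int(round(x))
        ylo_k, yhi_k = max(iy - r, 0), min(iy + r + 1, ny)
        xlo_k, xhi_k = max(ix - r, 0), min(ix + r + 1, nx)
        img[ylo_k:yhi_k, xlo_k:xhi_k] += kern[
            ylo_k - (iy - r) : yhi_k - (iy - r), xlo_k - (ix - r) : xhi_k - (ix - r)
        ]
    # overlap accounting: objects closer than 4 sigma of the larger spot
    n = len(counts)
    if n > 1:
        d2 = (ys[:, None] - ys[None, :]) ** 2 + (xs[:, None] - xs[None, :]) ** 2
        lim = (4 * np.maximum(sigmas[:, None], sigmas[None, :])) ** 2
        overlapping = ((d2 < lim).sum(axis=1) - 1) > 0
        if overlapping.mean() > 0.20:
            log.warning(
                "%.0f%% of bacteria objects overlap a neighbour",
                100 * overlapping.mean(),
            )
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, img.shape)
    bacteria = pd.DataFrame(
        {
            "object_id": np.arange(n),
            "y": ys,
            "x": xs,
            "ap_fraction": fracs,
            "count": counts,
            "true_intensity": intensities,
            "sigma_px": sigmas,
        }
    )
    truth = PhantomTruth(
        cells=None,
        bacteria=bacteria,
        sheet=None,
        config=config,
        fatbody_extent=(x0, x1),
    )
    return ImageVolume(img, "YX", config.pixel_size_um), truth


def _true_frequency(ap, spec: TranscriptSpec) -> np.ndarray:
    ap = np.asarray(ap, dtype=float)
    if spec.kind == "flat":
        return np.full_like(ap, spec.freq_high)
    if spec.kind == "anterior_step":
        return np.where(ap < spec.step_at, spec.freq_high, spec.freq_low)
    if spec.kind == "u":
        return spec.freq_low + (spec.freq_high - spec.freq_low) * (2 * ap - 1) ** 2
    raise ValueError(f"unknown transcript profile kind {spec.kind!r}")


def generate_transcript_table(config: PhantomConfig) -> pd.DataFrame:
    """Per-cell A-P positions and transcript counts for one gene.

    Total counts per cell are Poisson; the gene's count is Binomial with a
    true frequency following the configured A-P profile.  The true frequency
    is echoed per cell so recovery tests need no separate manifest.
    """
    config.validate()
    if config.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    spec = config.transcripts
    rng = np.random.default_rng(config.rng_seed)
    ap = rng.random(config.n_cells)
    freq = _true_frequency(ap, spec)
    total = np.maximum(rng.poisson(spec.mean_total_counts, config.n_cells), 1)
    gene = rng.binomial(total, np.clip(freq, 0.0, 1.0))
    return pd.DataFrame(
        {
            "cell_id": np.arange(config.n_cells),
            "ap_fraction": ap,
            "gene_count": gene,
            "total_count": total,
            "true_frequency": freq,
        }
    )
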