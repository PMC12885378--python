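"""Anterior-posterior expression profiling.

Tissue-scale expression patterns are quantified without a cell marker by
multi-Otsu thresholding of log-transformed maximum-intensity projections:
two thresholds separate three intensity categories (dim background, bright
tissue background, strong reporter signal), the top category is kept as the
signal mask, and masked intensity is summed along the larva's short axis to
give a 1D distribution along the A-P axis.  Profiles are binned over the
fat-body extent (14 bins by default, i.e. a bin width of ~0.07 of the
fat-body length), normalised per larva to their maximum, and averaged across
larvae.  Transcript-table profiles are averaged per bin with bootstrap
errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from skimage.filters import threshold_multiotsu

log = logging.getLogger(__name__)


@dataclass
class APProfile:
    """A binned 1D distribution along the A-P axis.

    ``bin_edges`` are fractions of the fat-body length (length ``n_bins+1``,
    contiguous over [0, 1]); ``values`` are summed intensity or mean
    transcript frequency per bin; ``error`` is the per-bin spread (sd across
    larvae or bootstrap sd); ``n_contributors`` counts larvae or cells per
    bin.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    normalized: bool = False
    error: Optional[np.ndarray] = None
    n_contributors: Optional[np.ndarray] = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.bin_edges) != len(self.values) + 1:
            raise ValueError("bin_edges must have len(values) + 1 entries")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "value": self.values,
            }
        )
        if self.error is not None:
            df["sd"] = self.error
        if self.n_contributors is not None:
            df["n"] = self.n_contributors
        return df


@dataclass
class RegionStats:
    """Mean expression per A-P region and the contrast ratios between them.

    Undefined ratios (zero middle mean) are reported as NaN, never infinity.
    """

    mean_anterior: float
    mean_middle: float
    mean_posterior: float
    anterior_middle: float
    posterior_middle: float
    max_end_middle: float


def extract_signal_mask(projection: np.ndarray, n_classes: int = 3):
    """Top-class mask from multi-Otsu thresholding of the log image.

    The projection is log(1 + I) transformed (admitting zero pixels), the
    multi-Otsu thresholds are computed on a 256-bin histogram, and the mask
    keeps pixels above the highest threshold.  Returns ``(mask, thresholds)``
    with thresholds on the log scale for audit.
    """
    projection = np.asarray(projection, dtype=float)
    if projection.min() < 0:
        raise ValueError("projection must be nonnegative; clip before masking")
    logimg = np.log1p(projection)
    if np.unique(logimg).size < n_classes:
        raise ValueError(
            f"degenerate histogram: fewer than {n_classes} distinct values; "
            f"cannot compute {n_classes - 1} thresholds"
        )
    nbins = 256
    thresholds = threshold_multiotsu(logimg, classes=n_classes, nbins=nbins)
    # thresholds are histogram bin centres and the threshold bin belongs to
    # the lower class; compare bin indices so values sharing the threshold
    # bin are never split
    edges = np.histogram_bin_edges(logimg, bins=nbins)
    pix_bin = np.clip(np.searchsorted(edges, logimg, side="right") - 1, 0, nbins - 1)
    thr_bin = np.clip(np.searchsorted(edges, thresholds[-1], side="right") - 1, 0, nbins - 1)
    mask = pix_bin > thr_bin
    return mask, thresholds


def ap_profile(
    projection: np.ndarray,
    mask: np.ndarray,
    fatbody_extent: tuple,
    n_bins: int = 14,
) -> APProfile:
    """Masked intensity summed along the short axis, binned along A-P.

    Every masked pixel whose column lies within ``fatbody_extent = (x0, x1)``
    is accumulated into exactly one of ``n_bins`` equal-width bins over the
    extent, so the unnormalised profile conserves total masked intensity.
    """
    projection = np.asarray(projection, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    x0, x1 = fatbody_extent
    if not (x0 < x1):
        raise ValueError(f"invalid fatbody extent ({x0}, {x1})")
    if not mask.any():
        log.warning("empty signal mask: profile is all zero")
    column_sum = np.where(mask, projection, 0.0).sum(axis=0)
    xs = np.arange(projection.shape[1]) + 0.5  # pixel centres
    frac = (xs - x0) / (x1 - x0)
    inside = (frac >= 0.0) & (frac < 1.0)
    idx = np.floor(frac[inside] * n_bins).astype(int)
    values = np.zeros(n_bins)
    np.add.at(values, idx, column_sum[inside])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return APProfile(edges, values, normalized=False)


def normalize_and_average(profiles: Sequence[APProfile]) -> APProfile:
    """Normalise each profile to its own maximum, then average across larvae.

    The error band is the per-bin sample standard deviation (ddof=1; zero
    for a single larva).  Profiles with an all-zero maximum are excluded
    with a warning.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    edges = profiles[0].bin_edges
    kept = []
    for i, p in enumerate(profiles):
        if not np.allclose(p.bin_edges, edges):
            raise ValueError("profiles must share binning")
        m = p.values.max()
        if m <= 0:
            log.warning("profile %d has max 0; excluded from the average", i)
            continue
        kept.append(p.values / m)
    if not kept:
        raise ValueError("no profiles with positive maximum")
    arr = np.stack(kept)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros_like(mean)
    return APProfile(
        edges,
        mean,
        normalized=True,
        error=sd,
        n_contributors=np.full(len(mean), arr.shape[0]),
    )


def region_ratios(
    data: Union[APProfile, pd.DataFrame],
    region_boundaries: tuple = (0.25, 0.65),
) -> RegionStats:
    """Per-region mean expression and anterior/middle, posterior/middle and
    max(anterior, posterior)/middle contrast ratios.

    ``data`` is either an :class:`APProfile` (bins assigned to regions by
    bin centre; prefer fine binning so region boundaries fall between bins)
    or a cell measurement table with ``intensity`` and either ``region`` or
    ``ap_fraction`` columns.
    """
    b0, b1 = region_boundaries
    if isinstance(data, APProfile):
        pos = data.bin_centers
        vals = data.values
        labels = np.where(pos < b0, "anterior", np.where(pos < b1, "middle", "posterior"))
    else:
        vals = data["intensity"].to_numpy(dtype=float)
        if "region" in data.columns:
            labels = data["region"].to_numpy()
        elif "ap_fraction" in data.columns:
            ap = data["ap_fraction"].to_numpy(dtype=float)
            labels = np.where(ap < b0, "anterior", np.where(ap < b1, "middle", "posterior"))
        else:
            raise ValueError("cell table needs a 'region' or 'ap_fraction' column")
    means = {}
    for region in ("anterior", "middle", "posterior"):
        sel = labels == region
        if not sel.any():
            raise ValueError(f"region {region!r} is empty")
        means[region] = float(vals[sel].mean())

    def ratio(a, b):
        return a / b if b != 0 else float("nan")

    return RegionStats(
        mean_anterior=means["anterior"],
        mean_middle=means["middle"],
        mean_posterior=means["posterior"],
        anterior_middle=ratio(means["anterior"], means["middle"]),
        posterior_middle=ratio(means["posterior"], means["middle"]),
        max_end_middle=ratio(
            max(means["anterior"], means["posterior"]), means["middle"]
        ),
    )


def plot_profile(profile: APProfile, path, label: str = "expression") -> None:
    """Plot an A-P profile with its error band to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    x = profile.bin_centers
    ax.plot(x, profile.values, color="forestgreen", lw=2)
    if profile.error is not None:
        ax.fill_between(
            x,
            profile.values - profile.error,
            profile.values + profile.error,
            color="forestgreen",
            alpha=0.3,
        )
    ax.set_xlabel("A-P position (fraction of fat-body length)")
    ax.set_ylabel(("normalized " if profile.normalized else "") + label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def bootstrap_ap_transcript_profile(
    cells: pd.DataFrame,
    n_bins: int = 14,
    n_boot: int = 100,
    seed: int = 0,
) -> APProfile:
    """Mean transcript frequency per A-P bin with bootstrap error bars.

    Per-cell frequency is ``gene_count / total_count``; the per-bin value is
    its mean over cells in the bin, and the error is the standard deviation
    of that mean over ``n_boot`` within-bin resamples with replacement.
    Empty bins are reported as NaN.
    """
    rng = np.random.default_rng(seed)
    ap = cells["ap_fraction"].to_numpy(dtype=float)
    total = cells["total_count"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(total > 0, cells["gene_count"].to_numpy(dtype=float) / total, 0.0)
    idx = np.clip(np.floor(ap * n_bins).astype(int), 0, n_bins - 1)
    values = np.full(n_bins, np.nan)
    error = np.full(n_bins, np.nan)
    n_contrib = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        f = freq[idx == b]
        n_contrib[b] = f.size
        if f.size == 0:
            continue
        values[b] = f.mean()
        if f.size == 1:
            error[b] = 0.0  # a single cell resamples to itself
        else:
            resampled = rng.choice(f, size=(n_boot, f.size), replace=True).mean(axis=1)
            error[b] = resampled.std(ddof=0)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return APProfile(edges, values, normalized=False, error=error, n_contributors=n_contrib)
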