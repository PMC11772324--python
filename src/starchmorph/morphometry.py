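"""Per-granule shape statistics and joint size-shape summaries.

Two shape descriptors drive the analysis.  *Circularity* is the mean
distance from the object centroid to its boundary divided by the standard
deviation of that distance — high for round granules, low for irregular
ones, and scale-invariant.  *Aspect ratio* is the minor/major axis ratio of
the mask's second-central-moment ellipse (``major = 4 * sqrt(lambda_1)``),
equal to ``b/a`` for an ideal ellipse and 1 for a circle.  Hila are counted
as sufficiently prominent, well-separated local intensity minima inside the
granule, emulating the initiation points visible under polarized light.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ShapeRecord",
    "DensityGrid",
    "HilumConfig",
    "boundary_radial_profile",
    "circularity",
    "circularity_from_distances",
    "aspect_ratio",
    "axis_lengths",
    "count_hila",
    "measure",
    "size_shape_density",
    "records_frame",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class ShapeRecord:
    """Measured quantities for one granule frame (lengths in um)."""

    frame_id: int
    area: float
    equivalent_diameter: float
    major_axis: float
    minor_axis: float
    aspect_ratio: float
    circularity: float
    n_hila: int
    qc_pass: bool = True


@dataclass
class DensityGrid:
    """Normalized 2-D histogram of (size, aspect ratio) with contour levels
    and the per-size-decile median aspect-ratio curve."""

    size_edges: np.ndarray
    ar_edges: np.ndarray
    cell_masses: np.ndarray  # shape (len(size_edges)-1, len(ar_edges)-1)
    contour_levels: np.ndarray
    decile_medians: np.ndarray  # median aspect ratio per size decile


def _single_component(mask: np.ndarray) -> None:
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2-D array")
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        raise ValueError("empty mask")
    if n > 1:
        raise ValueError(f"mask has {n} components; expected exactly one")


def boundary_radial_profile(mask: np.ndarray, pixel_size: float = 1.0) -> np.ndarray:
    """Distances (um) from the mask centroid to every boundary pixel.

    A boundary pixel is a foreground pixel with at least one background
    4-neighbour (image edges count as background).
    """
    _single_component(mask)
    m = mask.astype(bool)
    padded = np.pad(m, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = m & ~interior
    ys, xs = np.nonzero(m)
    cy, cx = ys.mean(), xs.mean()
    by, bx = np.nonzero(boundary)
    dists = np.hypot(by - cy, bx - cx) * pixel_size
    if dists.size < 8:
        raise ValueError("degenerate mask: fewer than 8 boundary pixels")
    return dists


def circularity_from_distances(distances: np.ndarray, cap: float = 1000.0) -> float:
    """Mean of a boundary-distance profile over its population SD."""
    d = np.asarray(distances, dtype=float)
    mean = float(d.mean())
    sd = float(d.std(ddof=0))
    if sd < 1e-9 * mean:
        return cap
    return mean / sd


def circularity(mask: np.ndarray, pixel_size: float = 1.0, cap: float = 1000.0) -> float:
    """Mean boundary distance divided by its population standard deviation.

    Near-zero variation (a perfect circle of boundary samples) returns the
    configured ``cap``.  Scale-invariant: ``pixel_size`` cancels.
    """
    return circularity_from_distances(boundary_radial_profile(mask, pixel_size), cap)


def _central_moments(mask: np.ndarray) -> tuple[float, float, float, int]:
    ys, xs = np.nonzero(mask)
    n = ys.size
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    mu20 = float((dx * dx).mean())
    mu02 = float((dy * dy).mean())
    mu11 = float((dx * dy).mean())
    return mu20, mu02, mu11, n

def _moment_axes(mask: np.ndarray) -> tuple[float, float]:
    """(major, minor) axis lengths in pixels from second central moments."""
    mu20, mu02, mu11, _ = _central_moments(mask)
    common = math.sqrt(max((mu20 - mu02) ** 2 + 4 * mu11**2, 0.0))
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    return 4.0 * math.sqrt(max(lam1, 0.0)), 4.0 * math.sqrt(max(lam2, 0.0))


def axis_lengths(mask: np.ndarray, pixel_size: float = 1.0) -> tuple[float, float]:
    """Moment-ellipse (major, minor) axis lengths in um."""
    _single_component(mask)
    major, minor = _moment_axes(mask)
    return major * pixel_size, minor * pixel_size


def aspect_ratio(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Minor/major moment-axis ratio in (0, 1]; 1 for a perfect disc."""
    _single_component(mask)
    if int(mask.sum()) < 4:
        raise ValueError("degenerate mask: area < 4 px")
    return aspect_ratio_from_mask(mask)


def aspect_ratio_from_mask(mask: np.ndarray) -> float:
    """Lenient moment aspect ratio (no component-count validation)."""
    major, minor = _moment_axes(mask)
    if major <= 0:
        return 1.0
    return min(minor / major, 1.0)


@dataclass(frozen=True)
class HilumConfig:
    """Hilum (intensity-minimum) detection parameters, lengths in um."""

    sigma_um: float = 0.6  # Gaussian smoothing before minimum detection
    min_prominence: float = 30.0  # required depth below local surround
    min_distance_um: float = 3.0  # minimum separation between hila
    border_um: float = 1.0  # ignore minima this close to the mask edge


def count_hila(
    image,
    mask: np.ndarray,
    cfg: HilumConfig = HilumConfig(),
) -> int:
    """Number of detected hila inside the mask (>= 1 by convention).

    Local minima of the smoothed intensity, at least ``border_um`` from the
    mask edge, of prominence >= ``min_prominence`` relative to the local
    surround, separated pairwise by >= ``min_distance_um``.  A granule with
    no detected minimum counts as one hilum (every granule has one).
    """
    if not mask.any():
        raise ValueError("empty mask")
    px = image.pixel_size
    smooth = ndimage.gaussian_filter(image.data, sigma=cfg.sigma_um / px)
    interior = ndimage.distance_transform_edt(mask) * px >= cfg.border_um
    if not interior.any():
        return 1
    local_min = smooth == ndimage.minimum_filter(smooth, size=3)
    cand = np.argwhere(local_min & interior)
    if cand.size == 0:
        return 1
    rad = max(int(round(cfg.min_distance_um / px)), 1)
    surround_max = ndimage.maximum_filter(smooth, size=2 * rad + 1)
    prom = surround_max[cand[:, 0], cand[:, 1]] - smooth[cand[:, 0], cand[:, 1]]
    cand = cand[prom >= cfg.min_prominence]
    if len(cand) == 0:
        return 1
    depth = smooth[cand[:, 0], cand[:, 1]]
    order = np.argsort(depth)  # deepest minima first
    chosen: list[np.ndarray] = []
    min_d_px = cfg.min_distance_um / px
    for idx in order:
        p = cand[idx]
        if all(np.hypot(*(p - q)) >= min_d_px for q in chosen):
            chosen.append(p)
    return max(1, len(chosen))


def measure(
    image,
    mask: np.ndarray,
    pixel_size: float | None = None,
    frame_id: int = 0,
    hilum_cfg: HilumConfig = HilumConfig(),
) -> ShapeRecord:
    """Populate a full :class:`ShapeRecord` for one QC-passed frame."""
    px = pixel_size if pixel_size is not None else image.pixel_size
    _single_component(mask)
    area = float(mask.sum()) * px**2
    major, minor = axis_lengths(mask, px)
    return ShapeRecord(
        frame_id=frame_id,
        area=area,
        equivalent_diameter=2.0 * math.sqrt(area / math.pi),
        major_axis=major,
        minor_axis=minor,
        aspect_ratio=min(minor / major, 1.0) if major > 0 else 1.0,
        circularity=circularity(mask, px),
        n_hila=count_hila(image, mask, hilum_cfg),
        qc_pass=True,
    )


def records_frame(records: list[ShapeRecord]) -> pd.DataFrame:
    """Tabulate shape records (one row per granule frame)."""
    return pd.DataFrame([r.__dict__ for r in records])


def size_shape_density(
    records,
    size_bins: int = 32,
    ar_bins: int = 32,
    levels: tuple[float, ...] = (0.25, 0.5, 0.75),
    size_column: str = "area",
) -> DensityGrid:
    """Joint (size, aspect ratio) density plus the decile median curve.

    The 2-D histogram is normalized to total mass 1; ``contour_levels`` are
    the cell-mass thresholds enclosing the given mass fractions (regions of
    equal point density).  ``decile_medians`` is the median aspect ratio per
    size decile, the curve used to assess size-shape coupling.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_frame(list(records))
    if len(df) < 10:
        raise ValueError("need at least 10 records for a density summary")
    size = df[size_column].to_numpy(dtype=float)
    ar = df["aspect_ratio"].to_numpy(dtype=float)
    hist, se, ae = np.histogram2d(size, ar, bins=(size_bins, ar_bins))
    mass = hist / hist.sum()
    flat = np.sort(mass.ravel())[::-1]
    cum = np.cumsum(flat)
    thresholds = np.array(
        [flat[min(np.searchsorted(cum, lv), len(flat) - 1)] for lv in levels]
    )
    deciles = np.quantile(size, np.linspace(0, 1, 11))
    medians = []
    for lo, hi in zip(deciles[:-1], deciles[1:]):
        sel = (size >= lo) & (size <= hi if hi == deciles[-1] else size < hi)
        medians.append(float(np.median(ar[sel])) if sel.any() else np.nan)
    return DensityGrid(
        size_edges=se,
        ar_edges=ae,
        cell_masses=mass,
        contour_levels=thresholds,
        decile_medians=np.array(medians),
    )
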