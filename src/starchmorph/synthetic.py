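"""Seeded synthetic starch-granule populations with per-granule ground truth.

Potato tuber starch is modelled as a lognormal mixture of granule sizes with
modes near 4, 11, 23 and 40 um, a wild-type-like negative coupling between
granule size and aspect ratio (large granules are more ellipsoidal), an
optional fraction of fused multi-hilum granules, and frame-level doublet and
debris contamination.  Granules are prolate spheroids (``a >= b = c``) whose
major axis lies in the image plane, so the true aspect ratio ``b/a`` equals
the projected minor/major ratio.

Rendered single-object images follow a fixed intensity convention chosen so
the downstream QC windows are directly meaningful: background near 5,
foreground between ~50 at the boundary and a bright plateau at 613 around
each lobe centre, and the hilum as a localized intensity depression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SizeMode",
    "PopulationSpec",
    "Lobe",
    "GranuleTruth",
    "ObjectImage",
    "IntensityConfig",
    "DEFAULT_MODES",
    "sample_population",
    "render_object",
    "spike_contaminants",
    "simulate_frames",
    "spherized",
    "truth_table",
]

_TWO31 = 2**31


@dataclass(frozen=True)
class SizeMode:
    """One lognormal component of the granule size mixture.

    ``mean_diameter`` (um) is the geometric mean / peak location of the
    component; ``sd_log`` is the lognormal scale; ``weight`` the mixture
    fraction.
    """

    mean_diameter: float
    sd_log: float
    weight: float

    def __post_init__(self) -> None:
        if self.mean_diameter <= 0:
            raise ValueError("mean_diameter must be positive")
        if self.sd_log < 0:
            raise ValueError("sd_log must be non-negative")
        if not 0 <= self.weight <= 1:
            raise ValueError("weight must be in [0, 1]")


#: Default potato-tuber-like size mixture: modes at 4, 11, 23 and 40 um, with
#: the smaller granules more numerous (number-weighted mixture).
DEFAULT_MODES: tuple[SizeMode, ...] = (
    SizeMode(4.0, 0.13, 0.32),
    SizeMode(11.0, 0.13, 0.30),
    SizeMode(23.0, 0.13, 0.24),
    SizeMode(40.0, 0.13, 0.14),
)


@dataclass
class PopulationSpec:
    """Parameters of one simulated granule population.

    ``shape_coupling`` is the slope ``s`` of the aspect-ratio decline with
    log size: singlet i gets ``ar = clip(1 - s*ln(d_i/d0) + eps, ar_min, 1)``
    with ``d0`` the smallest mode mean and ``eps ~ N(0, ar_noise_sd^2)``.
    ``s > 0`` reproduces the wild-type-like pattern (large granules less
    round); ``s = 0`` a decoupled, spherical population.
    """

    n: int
    modes: tuple[SizeMode, ...] = DEFAULT_MODES
    shape_coupling: float = 0.12
    ar_noise_sd: float = 0.04
    fused_fraction: float = 0.0
    boundary_noise: float = 0.02
    doublet_rate: float = 0.0
    debris_rate: float = 0.0
    seed: int = 0
    ar_min: float = 0.2
    fused_min_diameter: float = 18.0
    hilum_min_separation: float = 6.0
    hilum_offset_frac: float = 0.2

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.modes:
            raise ValueError("at least one size mode is required")
        total = sum(m.weight for m in self.modes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode weights must sum to 1 (got {total!r})")
        for name in ("fused_fraction", "doublet_rate", "debris_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.doublet_rate + self.debris_rate > 1.0:
            raise ValueError("doublet_rate + debris_rate must not exceed 1")
        if self.shape_coupling < 0:
            raise ValueError("shape_coupling must be >= 0")
        if self.ar_noise_sd < 0 or self.boundary_noise < 0:
            raise ValueError("noise levels must be >= 0")
        if not 0 < self.ar_min <= 1:
            raise ValueError("ar_min must be in (0, 1]")


@dataclass(frozen=True)
class Lobe:
    """One elliptical lobe of a granule projection (offsets in um)."""

    dx: float
    dy: float
    semi_major: float
    semi_minor: float
    theta: float


@dataclass
class GranuleTruth:
    """Ground truth for one simulated granule (or contaminant object)."""

    id: int
    class_label: str  # singlet | fused | doublet_member | debris
    semi_axes: tuple[float, float, float]  # a >= b = c, um
    orientation: float  # radians
    lobes: tuple[Lobe, ...]
    hilum_positions: tuple[tuple[float, float], ...]  # um offsets from centroid
    true_volume: float  # um^3
    true_aspect_ratio: float  # b / a
    boundary_noise: float = 0.0
    render_seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b > 0 and c > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")
        if self.class_label == "fused" and len(self.hilum_positions) < 2:
            raise ValueError("fused granules need >= 2 hilum positions")
        if self.class_label == "singlet" and len(self.hilum_positions) != 1:
            raise ValueError("singlets have exactly one hilum")


@dataclass
class ObjectImage:
    """Single-object grayscale frame with physical pixel size."""

    data: np.ndarray  # rows x cols, intensity units, >= 0
    pixel_size: float  # um / pixel
    polarity: str = "bright"  # foreground-bright
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.data.size == 0:
            raise ValueError("empty image")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class IntensityConfig:
    """Rendering intensity convention (instrument-unit scale).

    Foreground runs from ``fg_edge`` at the lobe boundary to a plateau at
    ``fg_peak`` inside ``core_frac`` of the lobe radius; the plateau is what
    the stringent QC window keys on.  Hila are Gaussian depressions of depth
    ``hilum_depth`` and width ``hilum_sigma_frac`` of the lobe's semi-minor
    axis (floored at ``hilum_sigma_min`` um).
    """

    background: float = 5.0
    fg_edge: float = 50.0
    fg_peak: float = 613.0
    core_frac: float = 0.5
    hilum_depth: float = 80.0
    hilum_sigma_frac: float = 0.12
    hilum_sigma_min: float = 0.4
    # depression depth scales with lobe semi-minor axis up to this size (um),
    # so small granules show shallow hila, as they do optically
    hilum_full_depth_minor: float = 4.0
    pixel_noise_sd: float = 2.0
    fg_floor: float = 14.0  # foreground never drops below the broad window
    growth_rings: bool = False
    ring_amplitude: float = 8.0
    ring_period_um: float = 1.5


def _draw_mixture(rng: np.random.Generator, modes: tuple[SizeMode, ...], n: int) -> np.ndarray:
    weights = np.array([m.weight for m in modes])
    comp = rng.choice(len(modes), size=n, p=weights / weights.sum())
    mu = np.log([m.mean_diameter for m in modes])
    sd = np.array([m.sd_log for m in modes])
    return np.exp(rng.normal(mu[comp], sd[comp]))


def sample_population(spec: PopulationSpec) -> list[GranuleTruth]:
    """Draw ``spec.n`` granule truths from the configured population.

    Diameters (projected-area-equivalent, um) come from the lognormal
    mixture; singlet aspect ratios follow the size-shape coupling; a
    ``fused_fraction`` of granules are built as two overlapping spherical
    lobes with two hilum positions.  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    d = _draw_mixture(rng, spec.modes, n)
    d0 = min(m.mean_diameter for m in spec.modes)
    eps = rng.normal(0.0, spec.ar_noise_sd, size=n) if spec.ar_noise_sd > 0 else np.zeros(n)
    ar = np.clip(1.0 - spec.shape_coupling * np.log(d / d0) + eps, spec.ar_min, 1.0)
    theta = rng.uniform(0.0, math.pi, size=n)
    fused = rng.random(n) < spec.fused_fraction
    hilum_sign = rng.choice([-1.0, 1.0], size=n)
    hilum_u = rng.uniform(0.5, 1.0, size=n)
    render_seeds = rng.integers(0, _TWO31, size=n)

    truths: list[GranuleTruth] = []
    for i in range(n):
        if fused[i]:
            truths.append(_make_fused(spec, rng, i, int(render_seeds[i])))
        else:
            truths.append(
                _make_singlet(
                    spec,
                    i,
                    float(d[i]),
                    float(ar[i]),
                    float(theta[i]),
                    float(hilum_sign[i] * hilum_u[i]),
                    int(render_seeds[i]),
                )
            )
    return truths


def _make_singlet(
    spec: PopulationSpec,
    gid: int,
    d: float,
    ar: float,
    theta: float,
    hilum_frac: float,
    render_seed: int,
    class_label: str = "singlet",
) -> GranuleTruth:
    a = (d / 2.0) / math.sqrt(ar)
    b = (d / 2.0) * math.sqrt(ar)
    off = spec.hilum_offset_frac * a * hilum_frac
    hx, hy = off * math.cos(theta), off * math.sin(theta)
    return GranuleTruth(
        id=gid,
        class_label=class_label,
        semi_axes=(a, b, b),
        orientation=theta,
        lobes=(Lobe(0.0, 0.0, a, b, theta),),
        hilum_positions=((hx, hy),),
        true_volume=4.0 / 3.0 * math.pi * a * b * b,
        true_aspect_ratio=b / a,
        boundary_noise=spec.boundary_noise,
        render_seed=render_seed,
    )


def _union_volume_two_spheres(r: float, sep: float) -> float:
    """Volume of the union of two equal spheres of radius ``r`` at centre
    separation ``sep`` (exact lens-subtraction formula)."""
    v_sphere = 4.0 / 3.0 * math.pi * r**3
    if sep >= 2 * r:
        return 2 * v_sphere
    lens = math.pi * (4 * r + sep) * (2 * r - sep) ** 2 / 12.0
    return 2 * v_sphere - lens


def _make_fused(
    spec: PopulationSpec, rng: np.random.Generator, gid: int, render_seed: int
) -> GranuleTruth:
    # Fused granules arise from two initiations that grew into one large
    # granule, so they are drawn from the upper part of the size mixture.
    d = float(_draw_mixture(rng, spec.modes, 1)[0])
    while d < spec.fused_min_diameter:
        d = float(_draw_mixture(rng, spec.modes, 1)[0])
    theta = float(rng.uniform(0.0, math.pi))
    r_lobe = 0.75 * (d / 2.0)
    sep = max(spec.hilum_min_separation, 0.9 * r_lobe)
    ux, uy = math.cos(theta), math.sin(theta)
    c1 = (-sep / 2.0 * ux, -sep / 2.0 * uy)
    c2 = (sep / 2.0 * ux, sep / 2.0 * uy)
    a_eff = sep / 2.0 + r_lobe
    return GranuleTruth(
        id=gid,
        class_label="fused",
        semi_axes=(a_eff, r_lobe, r_lobe),
        orientation=theta,
        lobes=(
            Lobe(c1[0], c1[1], r_lobe, r_lobe, theta),
            Lobe(c2[0], c2[1], r_lobe, r_lobe, theta),
        ),
        hilum_positions=(c1, c2),
        true_volume=_union_volume_two_spheres(r_lobe, sep),
        true_aspect_ratio=r_lobe / a_eff,
        boundary_noise=spec.boundary_noise,
        render_seed=render_seed,
    )


def spherized(truths: list[GranuleTruth]) -> list[GranuleTruth]:
    """Return a copy of the population made spherical at fixed volume.

    Every granule is replaced by a single-lobed sphere with the same
    ``true_volume`` and one central hilum — the siPTST2b-like transform used
    to separate shape effects from size effects.
    """
    out = []
    for t in truths:
        r = (3.0 * t.true_volume / (4.0 * math.pi)) ** (1.0 / 3.0)
        out.append(
            replace(
                t,
                class_label="singlet",
                semi_axes=(r, r, r),
                lobes=(Lobe(0.0, 0.0, r, r, 0.0),),
                hilum_positions=((0.0, 0.0),),
                true_aspect_ratio=1.0,
            )
        )
    return out


_NOISE_HARMONICS = np.arange(2, 7)  # k = 2..6


def _lobe_intensity(
    x: np.ndarray,
    y: np.ndarray,
    lobe: Lobe,
    coeffs: np.ndarray,
    cfg: IntensityConfig,
) -> np.ndarray:
    ct, st = math.cos(lobe.theta), math.sin(lobe.theta)
    u = ct * (x - lobe.dx) + st * (y - lobe.dy)
    v = -st * (x - lobe.dx) + ct * (y - lobe.dy)
    rho0 = np.hypot(u / lobe.semi_major, v / lobe.semi_minor)
    if coeffs.any():
        phi = np.arctan2(v, u)
        f = np.zeros_like(phi)
        for j, k in enumerate(_NOISE_HARMONICS):
            f += coeffs[0, j] * np.cos(k * phi) + coeffs[1, j] * np.sin(k * phi)
        rho = rho0 / np.clip(1.0 + f, 0.2, None)
    else:
        rho = rho0
    core = cfg.core_frac
    inten = np.zeros_like(rho)
    inside = rho <= 1.0
    plateau = rho <= core
    slope_reg = inside & ~plateau
    inten[plateau] = cfg.fg_peak
    inten[slope_reg] = cfg.fg_peak - (cfg.fg_peak - cfg.fg_edge) * (
        (rho[slope_reg] - core) / (1.0 - core)
    )
    if cfg.growth_rings:
        rings = cfg.ring_amplitude * np.cos(
            2 * math.pi * rho * lobe.semi_minor / cfg.ring_period_um
        )
        inten[inside] -= rings[inside]
    return inten


def render_object(
    truth: GranuleTruth,
    pixel_size: float,
    canvas: int | tuple[int, int] | None = None,
    intensity_cfg: IntensityConfig | None = None,
) -> ObjectImage:
    """Rasterize one granule truth onto a single-object frame.

    The foreground is the filled (possibly lobed) spheroid projection with
    multiplicative radial boundary noise; hila are Gaussian intensity
    depressions at their true positions.  Deterministic for a fixed
    ``truth.render_seed``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    cfg = intensity_cfg or IntensityConfig()
    extent = max(math.hypot(lb.dx, lb.dy) + lb.semi_major for lb in truth.lobes)
    extent = extent * (1.0 + 4.0 * truth.boundary_noise) + 1.0
    need = 2 * (int(math.ceil(extent / pixel_size)) + 3) + 1
    if canvas is None:
        rows = cols = need
    else:
        rows, cols = (canvas, canvas) if isinstance(canvas, int) else canvas
        if min(rows, cols) < need:
            raise ValueError(
                f"granule (needs {need} px) does not fit on canvas {rows}x{cols}"
            )
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ys, xs = np.mgrid[0:rows, 0:cols]
    x = (xs - cx) * pixel_size
    y = (ys - cy) * pixel_size

    rng = np.random.default_rng(truth.render_seed)
    fg = np.zeros((rows, cols))
    for lobe in truth.lobes:
        if truth.boundary_noise > 0:
            coeffs = rng.normal(
                0.0, truth.boundary_noise / math.sqrt(len(_NOISE_HARMONICS)), size=(2, 5)
            )
        else:
            coeffs = np.zeros((2, 5))
        fg = np.maximum(fg, _lobe_intensity(x, y, lobe, coeffs, cfg))

    img = np.where(fg > 0, fg, cfg.background)
    is_fg = fg > 0
    for i, (hx, hy) in enumerate(truth.hilum_positions):
        lobe = truth.lobes[min(i, len(truth.lobes) - 1)]
        sigma = max(cfg.hilum_sigma_min, cfg.hilum_sigma_frac * lobe.semi_minor)
        depth = cfg.hilum_depth * min(1.0, lobe.semi_minor / cfg.hilum_full_depth_minor)
        dip = depth * np.exp(-((x - hx) ** 2 + (y - hy) ** 2) / (2 * sigma**2))
        img = np.where(is_fg, img - dip, img)
    img = np.where(is_fg, np.clip(img, cfg.fg_floor, None), img)
    if cfg.pixel_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.pixel_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return ObjectImage(
        data=img,
        pixel_size=pixel_size,
        polarity="bright",
        provenance=f"render:{truth.id}:{truth.render_seed}",
    )


def _debris_truth(rng: np.random.Generator, gid: int) -> tuple[GranuleTruth, IntensityConfig]:
    """A small, dim, irregular speck (no bright core, no hilum dip)."""
    a = float(rng.uniform(0.6, 1.6))
    b = a * float(rng.uniform(0.4, 1.0))
    theta = float(rng.uniform(0, math.pi))
    t = GranuleTruth(
        id=gid,
        class_label="debris",
        semi_axes=(a, b, b),
        orientation=theta,
        lobes=(Lobe(0.0, 0.0, a, b, theta),),
        hilum_positions=(),
        true_volume=4.0 / 3.0 * math.pi * a * b * b,
        true_aspect_ratio=b / a,
        boundary_noise=0.15,
        render_seed=int(rng.integers(0, _TWO31)),
    )
    cfg = IntensityConfig(
        fg_edge=22.0, fg_peak=40.0, core_frac=0.3, hilum_depth=0.0, pixel_noise_sd=1.0
    )
    return t, cfg


def _companion_truth(
    spec: PopulationSpec, rng: np.random.Generator, gid: int
) -> GranuleTruth:
    d = float(_draw_mixture(rng, spec.modes, 1)[0])
    d0 = min(m.mean_diameter for m in spec.modes)
    ar = float(
        np.clip(
            1.0
            - spec.shape_coupling * math.log(d / d0)
            + rng.normal(0.0, spec.ar_noise_sd),
            spec.ar_min,
            1.0,
        )
    )
    return _make_singlet(
        spec,
        gid,
        d,
        ar,
        float(rng.uniform(0, math.pi)),
        float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)),
        int(rng.integers(0, _TWO31)),
        class_label="doublet_member",
    )


def _boundary_radius(lobes: tuple[Lobe, ...], direction: float) -> float:
    """Support radius of the lobe union along a direction from the origin."""
    ux, uy = math.cos(direction), math.sin(direction)
    best = 0.0
    for lb in lobes:
        # radius of the lobe's ellipse along the direction, from its centre
        ct, st = math.cos(lb.theta), math.sin(lb.theta)
        du = ct * ux + st * uy
        dv = -st * ux + ct * uy
        r = 1.0 / math.hypot(du / lb.semi_major, dv / lb.semi_minor)
        best = max(best, math.hypot(lb.dx, lb.dy) + r)
    return best


def spike_contaminants(
    images: list[ObjectImage],
    truths: list[GranuleTruth],
    doublet_rate: float,
    debris_rate: float,
    seed: int,
    spec: PopulationSpec | None = None,
    intensity_cfg: IntensityConfig | None = None,
) -> tuple[list[ObjectImage], pd.DataFrame]:
    """Replace a random fraction of frames with doublets or debris specks.

    ``doublet_rate`` of frames gain a second granule (half barely touching
    the first, half disjoint); ``debris_rate`` of frames are replaced by a
    dim irregular speck.  Returns the frame list plus a frame-level truth
    table (one row per frame).
    """
    if not 0 <= doublet_rate <= 1 or not 0 <= debris_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    if doublet_rate + debris_rate > 1:
        raise ValueError("doublet_rate + debris_rate must not exceed 1")
    if len(images) != len(truths):
        raise ValueError("images and truths must align")
    spec = spec or PopulationSpec(n=1)
    rng = np.random.default_rng(seed)
    n = len(images)
    rows = []
    out_images = list(images)
    if doublet_rate > 0 or debris_rate > 0:
        u = rng.random(n)
    else:
        u = np.full(n, 2.0)
    next_id = max((t.id for t in truths), default=-1) + 1
    for i, (img, t) in enumerate(zip(images, truths)):
        if u[i] < doublet_rate:
            comp = _companion_truth(spec, rng, next_id)
            next_id += 1
            direction = float(rng.uniform(0, 2 * math.pi))
            touching = bool(rng.random() < 0.5)
            gap = 0.98 if touching else 1.6
            dist = gap * (
                _boundary_radius(t.lobes, direction)
                + _boundary_radius(comp.lobes, direction + math.pi)
            )
            ox, oy = dist * math.cos(direction), dist * math.sin(direction)
            merged = replace(
                t,
                class_label="doublet_member",
                lobes=t.lobes
                + tuple(
                    replace(lb, dx=lb.dx + ox, dy=lb.dy + oy) for lb in comp.lobes
                ),
                hilum_positions=t.hilum_positions
                + tuple((hx + ox, hy + oy) for hx, hy in comp.hilum_positions),
            )
            out_images[i] = render_object(merged, img.pixel_size, intensity_cfg=intensity_cfg)
            rows.append(
                dict(
                    frame_id=i,
                    frame_class="doublet",
                    granule_id=t.id,
                    n_objects=2,
                    n_hila_true=len(t.hilum_positions),
                    touching=touching,
                )
            )
        elif u[i] < doublet_rate + debris_rate:
            speck, speck_cfg = _debris_truth(rng, next_id)
            next_id += 1
            out_images[i] = render_object(speck, img.pixel_size, intensity_cfg=speck_cfg)
            rows.append(
                dict(
                    frame_id=i,
                    frame_class="debris",
                    granule_id=speck.id,
                    n_objects=1,
                    n_hila_true=0,
                    touching=False,
                )
            )
        else:
            rows.append(
                dict(
                    frame_id=i,
                    frame_class=t.class_label,
                    granule_id=t.id,
                    n_objects=1,
                    n_hila_true=len(t.hilum_positions),
                    touching=False,
                )
            )
    return out_images, pd.DataFrame(rows)


def truth_table(truths: list[GranuleTruth]) -> pd.DataFrame:
    """Tabulate per-granule ground truth (one row per granule)."""
    return pd.DataFrame(
        dict(
            id=[t.id for t in truths],
            class_label=[t.class_label for t in truths],
            a_um=[t.semi_axes[0] for t in truths],
            b_um=[t.semi_axes[1] for t in truths],
            c_um=[t.semi_axes[2] for t in truths],
            orientation=[t.orientation for t in truths],
            n_hila=[len(t.hilum_positions) for t in truths],
            volume_um3=[t.true_volume for t in truths],
            aspect_ratio=[t.true_aspect_ratio for t in truths],
        )
    )


def simulate_frames(
    spec: PopulationSpec,
    pixel_size: float = 0.5,
    intensity_cfg: IntensityConfig | None = None,
) -> tuple[list[ObjectImage], pd.DataFrame, list[GranuleTruth]]:
    """Sample a population, render every granule and apply contamination.

    Returns ``(frames, frame_table, truths)`` where the frame table has one
    row per frame and records each frame's composition.
    """
    truths = sample_population(spec)
    frames = [render_object(t, pixel_size, intensity_cfg=intensity_cfg) for t in truths]
    frames, frame_tab = spike_contaminants(
        frames,
        truths,
        spec.doublet_rate,
        spec.debris_rate,
        seed=spec.seed + 1,
        spec=spec,
        intensity_cfg=intensity_cfg,
    )
    return frames, frame_tab, truths
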