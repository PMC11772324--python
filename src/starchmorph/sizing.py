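"""Granule sizing: forward-scatter emulation with bead calibration, gate
quantification, and Coulter-style volume-weighted size distributions.

The forward-scatter (FSC) signal is a declared phenomenological model:

    signal = k * d_eq**p * (1 + beta * (1 - aspect_ratio)) * (1 + eta)

with ``d_eq`` the volume-equivalent sphere diameter, power ``p`` (default
2), shape-sensitivity ``beta`` (default 0.3, FSC responds to major shape
changes) and multiplicative noise ``eta ~ N(0, sigma^2)``.  Calibration
against PMMA reference beads (1, 8, 30 and 60 um) is piecewise-linear in
log-log space, which is exact for a pure power law.  The Coulter-counter
emulation weights each granule by its volume and bins the equivalent
spherical diameter on a linear axis, so it is insensitive to shape changes
at a fixed volume distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthetic import GranuleTruth

__all__ = [
    "FscModel",
    "BeadCalibration",
    "GateSet",
    "SizeHistogram",
    "volume_equivalent_diameter",
    "fsc_signal",
    "fit_bead_calibration",
    "gate_fractions",
    "volume_histogram",
]


@dataclass(frozen=True)
class FscModel:
    """Forward-scatter model parameters."""

    k: float = 1.0
    p: float = 2.0
    beta: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0


def volume_equivalent_diameter(volume: np.ndarray | float) -> np.ndarray | float:
    """Diameter (um) of the sphere with the given volume (um^3)."""
    return (6.0 * np.asarray(volume, dtype=float) / math.pi) ** (1.0 / 3.0)


def fsc_signal(
    truths: list[GranuleTruth] | GranuleTruth,
    model: FscModel = FscModel(),
) -> np.ndarray | float:
    """Forward-scatter signal(s) for granule truth(s); seeded noise."""
    single = isinstance(truths, GranuleTruth)
    items = [truths] if single else list(truths)
    vols = np.array([t.true_volume for t in items])
    ars = np.array([t.true_aspect_ratio for t in items])
    if np.any(vols <= 0):
        raise ValueError("granule axes/volumes must be positive")
    d_eq = volume_equivalent_diameter(vols)
    sig = model.k * d_eq**model.p * (1.0 + model.beta * (1.0 - ars))
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        sig = sig * (1.0 + rng.normal(0.0, model.noise_sd, size=sig.shape))
    return float(sig[0]) if single else sig


def bead_signal(diameter: np.ndarray | float, model: FscModel = FscModel()) -> np.ndarray | float:
    """Noise-free signal of a spherical calibration bead."""
    return model.k * np.asarray(diameter, dtype=float) ** model.p


@dataclass
class BeadCalibration:
    """Piecewise-linear (log diameter, log signal) calibration curve.

    ``diameter()`` inverts the curve; outside the bead hull the end segments
    are extrapolated and ``extrapolated()`` flags those queries.
    """

    diameters: np.ndarray  # um, strictly increasing
    signals: np.ndarray  # instrument units, strictly increasing

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)

    def _interp(self, xq: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        out = np.interp(xq, x, y)
        slope_lo = (y[1] - y[0]) / (x[1] - x[0])
        slope_hi = (y[-1] - y[-2]) / (x[-1] - x[-2])
        lo = xq < x[0]
        hi = xq > x[-1]
        out = np.where(lo, y[0] + slope_lo * (xq - x[0]), out)
        out = np.where(hi, y[-1] + slope_hi * (xq - x[-1]), out)
        return out

    def diameter(self, signal: np.ndarray | float) -> np.ndarray | float:
        """Map signal -> diameter (um) through the inverse curve."""
        s = np.asarray(signal, dtype=float)
        if np.any(s <= 0):
            raise ValueError("signals must be positive")
        d = np.exp(self._interp(np.log(s), np.log(self.signals), np.log(self.diameters)))
        return float(d) if np.isscalar(signal) else d

    def signal(self, diameter: np.ndarray | float) -> np.ndarray | float:
        """Map diameter (um) -> expected signal."""
        d = np.asarray(diameter, dtype=float)
        if np.any(d <= 0):
            raise ValueError("diameters must be positive")
        s = np.exp(self._interp(np.log(d), np.log(self.diameters), np.log(self.signals)))
        return float(s) if np.isscalar(diameter) else s

    def extrapolated(self, signal: np.ndarray | float) -> np.ndarray | bool:
        """True where a signal query falls outside the bead hull."""
        s = np.asarray(signal, dtype=float)
        flag = (s < self.signals[0]) | (s > self.signals[-1])
        return bool(flag) if np.isscalar(signal) else flag


def fit_bead_calibration(beads) -> BeadCalibration:
    """Fit the calibration to (diameter um, signal) bead points.

    Beads may be given in any order; duplicate diameters or signals that do
    not increase with diameter are rejected.
    """
    pts = np.asarray(list(beads), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (diameter, signal) bead points")
    if np.any(pts <= 0):
        raise ValueError("bead diameters and signals must be positive")
    order = np.argsort(pts[:, 0])
    d, s = pts[order, 0], pts[order, 1]
    if np.any(np.diff(d) == 0):
        raise ValueError("duplicate bead diameters")
    if np.any(np.diff(s) <= 0):
        raise ValueError("bead signals must increase strictly with diameter")
    return BeadCalibration(diameters=d, signals=s)


@dataclass(frozen=True)
class GateSet:
    """Half-open diameter gates partitioning (0, inf), boundaries in um."""

    boundaries: tuple[float, ...] = (2.0, 7.0, 15.0, 50.0)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) < 1 or np.any(np.diff(b) <= 0) or b[0] <= 0:
            raise ValueError("gate boundaries must be positive and strictly increasing")

    @property
    def labels(self) -> list[str]:
        b = self.boundaries
        labs = [f"<{b[0]:g}"]
        labs += [f"{lo:g}-{hi:g}" for lo, hi in zip(b[:-1], b[1:])]
        labs.append(f">{b[-1]:g}")
        return labs

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate([[0.0], self.boundaries, [np.inf]])


def gate_fractions(diameters, gates: GateSet = GateSet()) -> dict[str, float]:
    """Number-weighted fraction of granules per diameter gate.

    Gates follow the half-open convention [low, high): a granule exactly at
    a boundary falls in the upper gate.  Fractions sum to 1.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter list")
    edges = gates.edges
    counts = np.array(
        [np.count_nonzero((d >= lo) & (d < hi)) for lo, hi in zip(edges[:-1], edges[1:])],
        dtype=float,
    )
    return dict(zip(gates.labels, counts / d.size))


@dataclass
class SizeHistogram:
    """Linearly binned size distribution; weights sum to 1."""

    edges: np.ndarray  # um, strictly increasing, linear spacing
    weights: np.ndarray
    weighting: str  # "number" or "volume"


def _extract_sizes(items) -> tuple[np.ndarray, np.ndarray]:
    """(equivalent spherical diameter, volume) from truths or records."""
    diams, vols = [], []
    for it in items:
        vol = getattr(it, "true_volume", None)
        if vol is None:
            # spheroid estimate from projected axes with depth = minor axis
            a = it.major_axis / 2.0
            b = it.minor_axis / 2.0
            vol = 4.0 / 3.0 * math.pi * a * b * b
        vols.append(vol)
        diams.append(volume_equivalent_diameter(vol))
    return np.asarray(diams), np.asarray(vols)


def volume_histogram(items, bin_width: float = 2.0, weighting: str = "volume") -> SizeHistogram:
    """Coulter-style size distribution with each granule weighted by volume.

    ``items`` are granule truths (true volume used) or shape records
    (spheroid volume estimated from the projected axes, depth = minor
    axis).  Sizes are equivalent spherical diameters on linear bins.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d, v = _extract_sizes(list(items))
    if d.size == 0:
        raise ValueError("no granules")
    if np.any(d <= 0):
        raise ValueError("sizes must be positive")
    hi = (math.floor(d.max() / bin_width) + 1) * bin_width
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    w = v if weighting == "volume" else np.ones_like(d)
    hist, _ = np.histogram(d, bins=edges, weights=w)
    return SizeHistogram(edges=edges, weights=hist / hist.sum(), weighting=weighting)
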