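"""Two-pass single-object quality filtering for imaging flow cytometry frames.

The filter reproduces the acquisition-software procedure used to isolate
individual starch granules: a broad intensity mask (instrument window 0-600)
with a spot count that rejects frames holding more or fewer than one object;
a second, stringent window (0-13) on the same spot-count feature that
resolves the bright cores of closely attached granules; and a final
shape-parameter gate that removes residual doublets.  Downstream shape
measurement always uses the broad-window mask.

Windows are expressed in instrument units on a brightfield-complement
channel ``c = clip(I_ref - I, 0)`` with full-scale ``I_ref = 613``: rendered
background (I in [0, 10]) falls outside the broad window, granule foreground
(I >= 14) inside it, and only the bright lobe cores (I >= 600) inside the
stringent window — so a frame with two attached granules shows one broad
spot but two stringent cores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .morphometry import aspect_ratio_from_mask
from .synthetic import ObjectImage

__all__ = [
    "MaskWindow",
    "QCConfig",
    "QCResult",
    "qc_channel",
    "mask_by_intensity",
    "count_spots",
    "qc_filter",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MaskWindow:
    """Inclusive intensity window [low, high] in instrument units."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low < 0 or self.high < 0:
            raise ValueError("window bounds must be >= 0")
        if self.low > self.high:
            raise ValueError("window low must not exceed high")


BROAD_WINDOW = MaskWindow(0.0, 600.0)
STRINGENT_WINDOW = MaskWindow(0.0, 13.0)


@dataclass(frozen=True)
class QCConfig:
    """Configuration of the three-pass filter.

    ``area_bounds_px`` and ``ar_bounds`` are the (permissive by default)
    shape-reject gates applied to the broad-window mask of surviving frames.
    """

    broad: MaskWindow = BROAD_WINDOW
    stringent: MaskWindow = STRINGENT_WINDOW
    intensity_ceiling: float = 613.0
    min_area: int = 4
    stringent_min_area: int = 4
    expected_spots: int = 1
    area_bounds_px: tuple[float, float] = (4.0, float("inf"))
    ar_bounds: tuple[float, float] = (0.0, 1.0)


@dataclass
class QCResult:
    """Outcome of the filter over a frame set.

    ``kept`` and ``discarded`` partition the input; ``retention`` is
    ``len(kept) / total``.  ``details`` holds one row per frame with the
    spot counts of each pass and the decision.
    """

    kept: list[int]
    discarded: list[tuple[int, str]]
    retention: float
    details: pd.DataFrame = field(default_factory=pd.DataFrame)


def qc_channel(image: ObjectImage, ceiling: float = 613.0) -> np.ndarray:
    """Brightfield-complement channel the mask windows operate on."""
    return np.clip(ceiling - image.data, 0.0, None)


def _window_mask(channel: np.ndarray, window: MaskWindow) -> np.ndarray:
    return (channel >= window.low) & (channel <= window.high)


def _filter_small(mask: np.ndarray, min_area: int) -> tuple[np.ndarray, int]:
    """8-connected components of area >= min_area; returns (mask, count)."""
    labels, nlab = ndimage.label(mask, structure=_EIGHT)
    if nlab == 0:
        return np.zeros_like(mask), 0
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= min_area)
    keep = keep[keep > 0]
    out = np.isin(labels, keep)
    return out, len(keep)


def mask_by_intensity(
    image: ObjectImage,
    window: MaskWindow = BROAD_WINDOW,
    min_area: int = 4,
    ceiling: float = 613.0,
) -> np.ndarray:
    """Binary mask of pixels inside the window, small components removed."""
    mask, _ = _filter_small(_window_mask(qc_channel(image, ceiling), window), min_area)
    return mask


def count_spots(
    image: ObjectImage,
    window: MaskWindow = BROAD_WINDOW,
    min_area: int = 4,
    ceiling: float = 613.0,
) -> int:
    """Number of 8-connected window components of area >= min_area."""
    _, n = _filter_small(_window_mask(qc_channel(image, ceiling), window), min_area)
    return n


def qc_filter(
    frames: list[ObjectImage],
    cfg: QCConfig = QCConfig(),
    frame_ids: list[int] | None = None,
) -> QCResult:
    """Run the three-pass single-object filter over a frame set."""
    if not frames:
        raise ValueError("empty frame list")
    ids = frame_ids if frame_ids is not None else list(range(len(frames)))
    kept: list[int] = []
    discarded: list[tuple[int, str]] = []
    rows = []
    for fid, frame in zip(ids, frames):
        n_broad = count_spots(frame, cfg.broad, cfg.min_area, cfg.intensity_ceiling)
        n_str = -1
        decision, reason = "keep", ""
        if n_broad == 0:
            decision, reason = "discard", "no_object"
        elif n_broad != cfg.expected_spots:
            decision, reason = "discard", "multi_spot"
        else:
            n_str = count_spots(
                frame, cfg.stringent, cfg.stringent_min_area, cfg.intensity_ceiling
            )
            if n_str == 0:
                decision, reason = "discard", "no_object"
            elif n_str != cfg.expected_spots:
                decision, reason = "discard", "multi_spot"
            else:
                mask = mask_by_intensity(
                    frame, cfg.broad, cfg.min_area, cfg.intensity_ceiling
                )
                area = float(mask.sum())
                ar = aspect_ratio_from_mask(mask)
                lo_a, hi_a = cfg.area_bounds_px
                lo_r, hi_r = cfg.ar_bounds
                if not (lo_a <= area <= hi_a) or not (lo_r <= ar <= hi_r):
                    decision, reason = "discard", "shape_reject"
        if decision == "keep":
            kept.append(fid)
        else:
            discarded.append((fid, reason))
        rows.append(
            dict(
                frame_id=fid,
                spots_broad=n_broad,
                spots_stringent=n_str,
                decision=decision,
                reason=reason,
            )
        )
    return QCResult(
        kept=kept,
        discarded=discarded,
        retention=len(kept) / len(frames),
        details=pd.DataFrame(rows),
    )
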