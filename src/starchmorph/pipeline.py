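"""End-to-end convenience layer: simulate -> QC -> measure in one call."""

from __future__ import annotations

import pandas as pd

from . import morphometry, qc as qcmod
from .morphometry import HilumConfig, ShapeRecord
from .qc import QCConfig, QCResult
from .synthetic import IntensityConfig, ObjectImage, PopulationSpec, simulate_frames

__all__ = ["measure_frames", "run_population"]


def measure_frames(
    frames: list[ObjectImage],
    qc_result: QCResult | None = None,
    cfg: QCConfig = QCConfig(),
    hilum_cfg: HilumConfig = HilumConfig(),
) -> list[ShapeRecord]:
    """Measure every kept frame using the broad-window mask."""
    keep = set(qc_result.kept) if qc_result is not None else set(range(len(frames)))
    records = []
    for fid, frame in enumerate(frames):
        if fid not in keep:
            continue
        mask = qcmod.mask_by_intensity(frame, cfg.broad, cfg.min_area, cfg.intensity_ceiling)
        records.append(
            morphometry.measure(frame, mask, frame_id=fid, hilum_cfg=hilum_cfg)
        )
    return records


def run_population(
    spec: PopulationSpec,
    pixel_size: float = 0.5,
    qc_cfg: QCConfig = QCConfig(),
    hilum_cfg: HilumConfig = HilumConfig(),
    intensity_cfg: IntensityConfig | None = None,
) -> dict:
    """Simulate a population, QC-filter it and measure surviving frames.

    Returns a dict with the frames, frame-level truth table, per-granule
    truths, :class:`QCResult` and the measured shape-record table.
    """
    frames, frame_tab, truths = simulate_frames(spec, pixel_size, intensity_cfg)
    qc_result = qcmod.qc_filter(frames, qc_cfg)
    records = measure_frames(frames, qc_result, qc_cfg, hilum_cfg)
    shapes = morphometry.records_frame(records) if records else pd.DataFrame()
    return dict(
        frames=frames,
        frame_table=frame_tab,
        truths=truths,
        qc=qc_result,
        records=records,
        shapes=shapes,
    )
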