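"""Tuber composition and expression formulas.

Implements the printed assay arithmetic exactly: iodine-complex amylose
estimation from a blank-corrected absorbance ratio, gravimetric moisture
content, glucose-based starch content with an anhydroglucose correction,
efficiency-corrected (Pfaffl) relative qPCR expression against a reference
gene, and 1-based inclusive genomic interval lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "AssayReading",
    "AMYLOSE_RATIO_MIN",
    "AMYLOSE_RATIO_MAX",
    "ANHYDRO_FACTOR",
    "amylose_percent",
    "amylose_percent_from_ratio",
    "moisture_percent",
    "starch_percent",
    "pfaffl_expression",
    "interval_length",
]

# Valid domain of the amylose calibration ratio R = A_long / A_short:
# the numerator 3.5 - 5.1 R is zero at R = 3.5/5.1 (0% amylose) and the
# denominator 10.4 R - 19.9 is singular at R = 19.9/10.4.
AMYLOSE_RATIO_MIN = 3.5 / 5.1
AMYLOSE_RATIO_MAX = 19.9 / 10.4

#: anhydroglucose residue mass over free glucose mass (162/180): hydrolysis
#: adds one water per glucosyl unit released from the starch polymer.
ANHYDRO_FACTOR = 162.0 / 180.0


@dataclass
class AssayReading:
    """Raw inputs to the composition and expression formulas.

    Absorbances: ``a_high``/``a_low`` at the long/short wavelength (the
    620/535 nm and 618/550 nm labels are treated interchangeably — the
    formula consumes only the blank-corrected ratio).  Weights in grams,
    masses in mg, Ct in cycles, amplification efficiencies in (1, 2].
    """

    a_high: float = 0.0
    a_low: float = 0.0
    blank_high: float = 0.0
    blank_low: float = 0.0
    w_wet: float = 0.0
    w_dry: float = 0.0
    w_tube: float = 0.0
    glucose_released: float = 0.0
    flour_mass: float = 0.0
    ct_target: float = 0.0
    ct_ref: float = 0.0
    e_target: float = 2.0
    e_ref: float = 2.0


def amylose_percent_from_ratio(ratio: float) -> float:
    """Percent amylose from the blank-corrected absorbance ratio R.

    ``100 * (3.5 - 5.1 R) / (10.4 R - 19.9)``, valid for
    ``3.5/5.1 <= R < 19.9/10.4``.  Outside that domain the estimate is
    negative or singular and a :class:`ValueError` names the bound.
    """
    if ratio < AMYLOSE_RATIO_MIN:
        raise ValueError(
            f"absorbance ratio {ratio:.4f} below lower bound 3.5/5.1 = "
            f"{AMYLOSE_RATIO_MIN:.4f} (negative amylose)"
        )
    if ratio >= AMYLOSE_RATIO_MAX:
        raise ValueError(
            f"absorbance ratio {ratio:.4f} at or beyond singularity 19.9/10.4 = "
            f"{AMYLOSE_RATIO_MAX:.4f}"
        )
    value = 100.0 * (3.5 - 5.1 * ratio) / (10.4 * ratio - 19.9)
    if value > 100.0:
        warnings.warn(
            f"amylose estimate {value:.1f}% exceeds 100%: ratio near the "
            "calibration singularity",
            stacklevel=2,
        )
    return value


def amylose_percent(reading: AssayReading) -> float:
    """Percent amylose from blank-corrected long/short absorbances."""
    denom = reading.a_low - reading.blank_low
    if denom <= 0:
        raise ValueError("short-wavelength absorbance must exceed its blank")
    if reading.a_high < reading.blank_high:
        raise ValueError("long-wavelength absorbance below its blank")
    return amylose_percent_from_ratio((reading.a_high - reading.blank_high) / denom)


def moisture_percent(reading: AssayReading) -> float:
    """Gravimetric moisture: ``100 * (W_wet - W_dry) / (W_wet - W_tube)``."""
    if reading.w_wet <= reading.w_tube:
        raise ValueError("wet weight must exceed tube weight")
    if reading.w_dry > reading.w_wet:
        raise ValueError("dry weight cannot exceed wet weight")
    if reading.w_dry <= 0:
        raise ValueError("dry weight must be positive")
    return 100.0 * (reading.w_wet - reading.w_dry) / (reading.w_wet - reading.w_tube)


def starch_percent(
    glucose_released: float,
    flour_mass: float,
    anhydro_factor: float = ANHYDRO_FACTOR,
) -> float:
    """Starch content as glucose released on hydrolysis, per flour mass.

    ``100 * glucose_released * anhydro_factor / flour_mass`` with masses in
    the same unit (mg).  Values above 100% are physically impossible and
    raise a warning (assay or weighing error).
    """
    if flour_mass <= 0:
        raise ValueError("flour mass must be positive")
    if glucose_released < 0:
        raise ValueError("glucose mass cannot be negative")
    value = 100.0 * glucose_released * anhydro_factor / flour_mass
    if value > 100.0:
        warnings.warn(f"starch content {value:.1f}% exceeds 100%", stacklevel=2)
    return value


def _check_efficiency(e: float, name: str) -> None:
    if not 1.0 < e <= 2.0:
        raise ValueError(f"{name} amplification efficiency must be in (1, 2], got {e}")


def pfaffl_expression(
    ct_target: float,
    ct_ref: float,
    e_target: float = 2.0,
    e_ref: float = 2.0,
    calibrator: tuple[float, float] | None = None,
) -> float:
    """Efficiency-corrected relative expression against a reference gene.

    Within-sample form (default): ``E_ref**Ct_ref / E_target**Ct_target``,
    expression relative to the reference gene in the same sample; with both
    efficiencies 2 this is ``2**(Ct_ref - Ct_target)``.

    Two-sample (calibrator) mode: pass ``calibrator=(ct_target_0,
    ct_ref_0)`` for the classic ratio
    ``E_target**dCt_target / E_ref**dCt_ref`` with ``dCt = Ct_0 - Ct``.
    """
    _check_efficiency(e_target, "target")
    _check_efficiency(e_ref, "reference")
    if calibrator is None:
        return e_ref**ct_ref / e_target**ct_target
    ct_t0, ct_r0 = calibrator
    return e_target ** (ct_t0 - ct_target) / e_ref ** (ct_r0 - ct_ref)


def interval_length(start: int, end: int) -> int:
    """Length in bp of a 1-based inclusive coordinate interval."""
    if start < 1:
        raise ValueError("coordinates are 1-based: start must be >= 1")
    if end < start:
        raise ValueError(f"inverted interval: end {end} < start {start}")
    return end - start + 1
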