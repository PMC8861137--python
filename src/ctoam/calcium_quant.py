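"""HU-to-calcium calibration and relative calcium concentration.

The headline statistic of the analysis is the *relative calcium
concentration* of a plate: the absolute calcium content (per-pixel
calcium integrated over pixel area) divided by the plate surface area
(valid-pixel count times pixel area).  The two integrals reduce exactly
to the area-weighted mean per-pixel calcium, reported in mg/ml.

The default calibration is a line through (0 HU, 0 mg/ml) and
(1000 HU, 600 mg/ml).  It is a configurable placeholder — no published
HU-to-calcium lookup table accompanies this analysis — and every
cohort-level statistic built on it is a ratio, which is invariant to the
calibration slope when the intercept is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DesignError, EmptyMaskError
from .volume_io import Densitogram


@dataclass(frozen=True)
class CalciumCalibration:
    """Linear HU -> mg/ml map; predictions are clamped at >= 0."""

    slope: float  # (mg/ml) per HU
    intercept: float  # mg/ml
    valid_range: tuple[float, float]  # HU range spanned by the fit points

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DesignError(f"calibration slope must be > 0, got {self.slope}")


#: Placeholder calibration: 0 HU -> 0 mg/ml, 1000 HU -> 600 mg/ml.
DEFAULT_CALIBRATION = CalciumCalibration(slope=0.6, intercept=0.0, valid_range=(0.0, 1000.0))


@dataclass(frozen=True)
class CalciumReport:
    """Quantification of one plate."""

    absolute_ca: float  # mm^2 * mg/ml
    area_mm2: float
    relative_ca: float  # mg/ml
    n_pixels: int
    extrapolated: bool  # any pixel outside the calibration's fitted HU range


def fit_calibration(points) -> CalciumCalibration:
    """Ordinary least-squares line through (HU, mg/ml) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise DesignError("need >= 2 (HU, mg/ml) points")
    hu, ca = pts[:, 0], pts[:, 1]
    if np.unique(hu).size < 2:
        raise DesignError("need >= 2 distinct HU values to fit a line")
    slope, intercept = np.polyfit(hu, ca, 1)
    return CalciumCalibration(
        slope=float(slope),
        intercept=float(intercept),
        valid_range=(float(hu.min()), float(hu.max())),
    )


def hu_to_calcium(cal: CalciumCalibration, hu) -> np.ndarray | float:
    """Predicted calcium in mg/ml, clamped at 0; extrapolates outside the fit range."""
    out = np.maximum(0.0, cal.intercept + cal.slope * np.asarray(hu, dtype=float))
    return float(out) if out.ndim == 0 else out


def quantify(d: Densitogram, cal: CalciumCalibration = DEFAULT_CALIBRATION) -> CalciumReport:
    """Absolute and relative calcium of a plate.

    absolute_ca = sum over valid pixels of calcium * pixel area;
    area = n_valid * dx * dy; relative_ca = absolute_ca / area, i.e. the
    mean per-pixel calcium.
    """
    sel = d.valid == 1
    n = int(sel.sum())
    if n == 0:
        raise EmptyMaskError("empty plate: no valid pixels to quantify")
    dx, dy = d.pixel_spacing
    ca = hu_to_calcium(cal, d.values[sel])
    area = n * dx * dy
    absolute = float(ca.sum() * dx * dy)
    lo, hi = cal.valid_range
    hu_vals = d.values[sel]
    return CalciumReport(
        absolute_ca=absolute,
        area_mm2=area,
        relative_ca=absolute / area,
        n_pixels=n,
        extrapolated=bool((hu_vals < lo).any() or (hu_vals > hi).any()),
    )


__all__ = [
    "CalciumCalibration",
    "CalciumReport",
    "DEFAULT_CALIBRATION",
    "fit_calibration",
    "hu_to_calcium",
    "quantify",
]
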