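"""Library-level orchestration: volume -> shell -> MIP -> quantities.

These helpers chain the stage modules for the common case (one vertebra,
one side) and for whole simulated cohorts; the command-line layer and the
test-suite both drive the pipeline through them.
"""

from __future__ import annotations

import pandas as pd

from .calcium_quant import CalciumCalibration, CalciumReport, DEFAULT_CALIBRATION, quantify
from .densitogram_mip import project_mip
from .group_stats import percent_of_healthy
from .phantoms import CohortSim
from .sbp_extraction import extract_shell, orient_perpendicular
from .volume_io import CTVolume, Densitogram, LabelMask, PlateMeta


def measure_plate(
    vol: CTVolume,
    mask: LabelMask,
    side: str,
    meta: PlateMeta | None = None,
    depth_mm: float = 2.0,
    rotation_deg: tuple[float, float, float] | None = None,
    cal: CalciumCalibration = DEFAULT_CALIBRATION,
) -> tuple[Densitogram, CalciumReport]:
    """Densitogram and calcium report for one endplate.

    With ``rotation_deg`` given, the vertebra is first rotated/resampled
    to the en-face view; otherwise the grid is used as-is.
    """
    if rotation_deg is not None:
        vol, mask = orient_perpendicular(vol, mask, rotation_deg)
    shell = extract_shell(mask, side=side, depth_mm=depth_mm, spacing=vol.spacing)
    dens = project_mip(vol, shell, meta=meta)
    return dens, quantify(dens, cal)


def measure_cohort(
    sim: CohortSim,
    depth_mm: float = 2.0,
    cal: CalciumCalibration = DEFAULT_CALIBRATION,
    keep_densitograms: bool = False,
):
    """Run the measurement pipeline over every simulated plate.

    Returns a DataFrame of plate records (one row per subject, level and
    side) and, optionally, the densitograms keyed by
    (subject, level, side).
    """
    rows = []
    densitograms = {}
    for plate in sim.plates:
        for side in ("superior", "inferior"):
            dens, report = measure_plate(
                plate.volume, plate.mask, side, meta=plate.meta(side),
                depth_mm=depth_mm, cal=cal,
            )
            if keep_densitograms:
                densitograms[(plate.subject, plate.level, side)] = dens
            rows.append(
                {
                    "subject": plate.subject,
                    "level": plate.level,
                    "side": side,
                    "condition": plate.condition,
                    "relative_ca": report.relative_ca,
                    "area_mm2": report.area_mm2,
                    "n_pixels": report.n_pixels,
                }
            )
    df = pd.DataFrame(rows)
    return (df, densitograms) if keep_densitograms else df


def recovered_percent(measured: pd.DataFrame, level: str, side: str) -> int:
    """Pipeline-recovered percent-of-healthy at one level and side."""
    sel = measured[(measured.level == level) & (measured.side == side)]
    mean_h = sel.loc[sel.condition == "healthy", "relative_ca"].mean()
    mean_d = sel.loc[sel.condition == "ddd", "relative_ca"].mean()
    return percent_of_healthy(mean_d, mean_h)


__all__ = ["measure_plate", "measure_cohort", "recovered_percent"]
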