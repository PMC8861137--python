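"""Mean densitograms, false-color rendering and threshold maps.

Level/side-matched raster densitograms are averaged per cell over the
images in which that cell is foreground (intersection-only averaging
would discard the peripheral rim — exactly the region of interest).  The
>1000 HU threshold statistic is computed on the non-interpolated mean
raster; bicubic upsampling is for display only.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from matplotlib import colormaps

from .errors import EmptyMaskError, ParameterError
from .grid_maxima import RasterDensitogram
from .volume_io import PlateMeta

#: value of background cells in threshold maps
BACKGROUND = -1

#: RGBA reserved for background pixels in rendered maps
BACKGROUND_RGBA = (0.82, 0.82, 0.82, 1.0)


def average_rasters(
    rasters: Sequence[RasterDensitogram],
    min_coverage: int | None = None,
) -> tuple[RasterDensitogram, np.ndarray]:
    """Per-cell mean of matched rasters plus a coverage map.

    All rasters must share level, side and condition.  ``coverage``
    counts contributing images per cell; cells covered by fewer than
    ``min_coverage`` images (default: half the images, rounded up) are
    masked to background.
    """
    if len(rasters) == 0:
        raise EmptyMaskError("no rasters to average")
    key = (rasters[0].meta.level, rasters[0].meta.side, rasters[0].meta.condition)
    for r in rasters[1:]:
        if (r.meta.level, r.meta.side, r.meta.condition) != key:
            raise ParameterError(
                "rasters mix level/side/condition; refusing to average "
                f"{key} with {(r.meta.level, r.meta.side, r.meta.condition)}"
            )
    if min_coverage is None:
        min_coverage = math.ceil(len(rasters) / 2)

    stack = np.stack([r.cells for r in rasters])
    fg = np.isfinite(stack)
    coverage = fg.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(np.where(fg, stack, 0.0), axis=0) / np.where(
            coverage > 0, coverage, 1
        )
    mean = np.where(coverage >= max(1, min_coverage), mean, np.nan)
    occ = np.stack([r.occupancy for r in rasters]).mean(axis=0)
    occ = np.where(np.isfinite(mean), occ, 0.0)
    level, side, condition = key
    meta = PlateMeta(
        subject=f"mean(n={len(rasters)})", level=level, side=side, condition=condition
    )
    mean_raster = RasterDensitogram(
        cells=mean, occupancy=occ, meta=meta, cell_size_mm=rasters[0].cell_size_mm
    )
    return mean_raster, coverage


def render_false_color(
    cells: np.ndarray,
    lo: float = 800.0,
    hi: float = 2200.0,
    background_rgba: tuple = BACKGROUND_RGBA,
) -> np.ndarray:
    """Jet false-color rendering of a (mean) raster or densitogram.

    HU in [lo, hi] map linearly onto the jet scale; values <= lo share
    the lowest color, >= hi the highest.  Background (NaN) gets a
    reserved color distinct from any jet entry.
    """
    if lo >= hi:
        raise ParameterError(f"require lo < hi, got lo={lo}, hi={hi}")
    cells = np.asarray(cells, dtype=float)
    fg = np.isfinite(cells)
    norm = np.clip((np.where(fg, cells, lo) - lo) / (hi - lo), 0.0, 1.0)
    rgba = colormaps["jet"](norm)
    rgba[~fg] = background_rgba
    return rgba


def _keys_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Cubic-convolution interpolation kernel (Keys), parameter a."""
    t = np.abs(t)
    out = np.zeros_like(t)
    near = t <= 1
    far = (t > 1) & (t < 2)
    out[near] = (a + 2) * t[near] ** 3 - (a + 3) * t[near] ** 2 + 1
    out[far] = a * (t[far] ** 3 - 5 * t[far] ** 2 + 8 * t[far] - 4)
    return out


def interpolate_bicubic(cells: np.ndarray, factor: int = 4) -> np.ndarray:
    """Cubic-convolution (a = -0.5) upsampling with background exclusion.

    Background cells carry no weight: the kernel is renormalized over
    foreground support (normalized convolution), so plate borders do not
    bleed toward the background sentinel.  factor=1 is the identity.
    Display-only smoothing — statistics always use the raw raster.
    """
    if int(factor) != factor or factor < 1:
        raise ParameterError(f"factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    cells = np.asarray(cells, dtype=float)
    if factor == 1:
        return cells.copy()
    ny, nx = cells.shape
    fg = np.isfinite(cells).astype(float)
    vals = np.where(fg == 1, cells, 0.0)

    def axis_taps(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        u = (np.arange(n * factor) + 0.5) / factor - 0.5
        base = np.floor(u).astype(int)
        taps = base[:, None] + np.arange(-1, 3)[None, :]  # (n*f, 4)
        w = _keys_kernel(u[:, None] - taps)
        inside = (taps >= 0) & (taps < n)
        return np.clip(taps, 0, n - 1), w, inside.astype(float)

    ty, wy, iny = axis_taps(ny)
    tx, wx, inx = axis_taps(nx)

    num = np.zeros((ny * factor, nx * factor))
    den = np.zeros_like(num)
    for p in range(4):
        for q in range(4):
            vy = vals[ty[:, p], :][:, tx[:, q]]
            my = fg[ty[:, p], :][:, tx[:, q]]
            w = (wy[:, p] * iny[:, p])[:, None] * (wx[:, q] * inx[:, q])[None, :]
            num += w * my * vy
            den += w * my
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    # a cell's upsampled pixels stay background if their nearest input cell is
    nearest_fg = fg[np.repeat(np.arange(ny), factor), :][:, np.repeat(np.arange(nx), factor)]
    out[(nearest_fg == 0) | ~np.isfinite(out)] = np.nan
    return out


def threshold_high_mineralization(cells: np.ndarray, thr: float = 1000.0) -> np.ndarray:
    """Binary high-mineralization map: 1 iff value > thr (strict), else 0.

    Background cells stay background (coded BACKGROUND = -1).
    """
    cells = np.asarray(cells, dtype=float)
    fg = np.isfinite(cells)
    out = np.full(cells.shape, BACKGROUND, dtype=np.int8)
    out[fg] = (cells[fg] > thr).astype(np.int8)
    return out


def high_mineralization_area(cells: np.ndarray, thr: float = 1000.0) -> int:
    """Count of foreground cells strictly above thr."""
    t = threshold_high_mineralization(cells, thr)
    return int((t == 1).sum())


__all__ = [
    "BACKGROUND",
    "BACKGROUND_RGBA",
    "average_rasters",
    "render_false_color",
    "interpolate_bicubic",
    "threshold_high_mineralization",
    "high_mineralization_area",
]
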