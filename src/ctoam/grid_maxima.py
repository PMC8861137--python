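"""Fixed 50x40 grid: fractional-area rasterization and local maxima.

Every densitogram, whatever its pixel count, is standardized onto a grid
of 50 columns (mediolateral) x 40 rows (anteroposterior) spanning the
tight bounding box of the plate footprint.  Each cell's value is the
area-weighted mean of the valid source pixels overlapping it, with
pixels split fractionally at cell borders — so the grid both resizes and
size-normalizes plates, and the quantity
``sum(cell value * covered area)`` is conserved exactly.

Local maxima are detected on the rasterized grid.  A cell is a maximum
iff it is foreground and strictly greater than every foreground cell
among its neighbours (8-connected by default, 4-connected available);
plateaus produce no maxima, isolated foreground cells do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyMaskError, ParameterError
from .volume_io import Densitogram, MaximaRecord, PlateMeta

GRID_ROWS = 40
GRID_COLS = 50


@dataclass
class RasterDensitogram:
    """Densitogram resampled to the fixed 40x50 grid.

    ``cells`` holds mean HU (NaN = background); ``occupancy`` the
    fraction of each cell's area covered by valid plate pixels.
    """

    cells: np.ndarray
    occupancy: np.ndarray
    meta: PlateMeta = field(default_factory=PlateMeta)
    cell_size_mm: tuple[float, float] = (1.0, 1.0)  # (height, width)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.cells.shape != (GRID_ROWS, GRID_COLS):
            raise ParameterError(
                f"grid must be {GRID_ROWS}x{GRID_COLS}, got {self.cells.shape}"
            )
        if self.occupancy.shape != self.cells.shape:
            raise ParameterError("occupancy shape must match cells")
        if ((self.occupancy < -1e-12) | (self.occupancy > 1 + 1e-12)).any():
            raise ParameterError("occupancy must lie in [0, 1]")

    @property
    def foreground(self) -> np.ndarray:
        return np.isfinite(self.cells)


def _overlap_weights(lo: float, hi: float, n_cells: int, n_pix: int) -> np.ndarray:
    """1D overlap lengths between pixel intervals [j, j+1) and equal cells on [lo, hi).

    Returns a (n_cells, n_pix) matrix in pixel units.
    """
    h = (hi - lo) / n_cells
    cell_lo = lo + h * np.arange(n_cells)[:, None]
    cell_hi = cell_lo + h
    pix_lo = np.arange(n_pix)[None, :]
    pix_hi = pix_lo + 1
    return np.clip(np.minimum(cell_hi, pix_hi) - np.maximum(cell_lo, pix_lo), 0.0, None)


def rasterize(d: Densitogram, occupancy_min: float = 0.5) -> RasterDensitogram:
    """Resample a densitogram onto the 40x50 grid by fractional pixel areas.

    The grid spans the tight bounding box of the valid pixels.  Cells
    with occupancy <= ``occupancy_min`` are background.
    """
    if not (0 <= occupancy_min < 1):
        raise ParameterError(f"occupancy_min must be in [0, 1), got {occupancy_min}")
    valid = d.valid == 1
    if not valid.any():
        raise EmptyMaskError("cannot rasterize an empty densitogram")
    rows = np.where(valid.any(axis=1))[0]
    cols = np.where(valid.any(axis=0))[0]
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1

    Wy = _overlap_weights(r0, r1, GRID_ROWS, d.values.shape[0])  # (40, ny)
    Wx = _overlap_weights(c0, c1, GRID_COLS, d.values.shape[1])  # (50, nx)

    m = valid.astype(float)
    v = np.where(valid, d.values, 0.0)
    covered = Wy @ m @ Wx.T  # covered area per cell, pixel units
    num = Wy @ (v * m) @ Wx.T
    cell_h = (r1 - r0) / GRID_ROWS
    cell_w = (c1 - c0) / GRID_COLS
    occupancy = covered / (cell_h * cell_w)
    occupancy = np.clip(occupancy, 0.0, 1.0)  # guard float round-off
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = np.where(covered > 0, num / np.where(covered > 0, covered, 1.0), np.nan)
    cells[occupancy <= occupancy_min] = np.nan
    dy, dx = d.pixel_spacing[1], d.pixel_spacing[0]
    return RasterDensitogram(
        cells=cells,
        occupancy=occupancy,
        meta=d.meta,
        cell_size_mm=(cell_h * dy, cell_w * dx),
    )


def find_local_maxima(r: RasterDensitogram, connectivity: int = 8) -> list[MaximaRecord]:
    """Strict local maxima of the raster, in row-major order.

    Background neighbours never disqualify a cell; ties (plateaus) yield
    no maxima.
    """
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    cells = np.where(r.foreground, r.cells, -np.inf)
    padded = np.pad(cells, 1, constant_values=-np.inf)
    if connectivity == 8:
        shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    is_max = r.foreground.copy()
    for di, dj in shifts:
        nb = padded[1 + di : 1 + di + GRID_ROWS, 1 + dj : 1 + dj + GRID_COLS]
        is_max &= cells > nb
    out = [
        MaximaRecord(row=int(i), col=int(j), hu=float(r.cells[i, j]))
        for i, j in np.argwhere(is_max)
    ]
    return out


def cap_top_k(records, k: int = 20) -> list[MaximaRecord]:
    """Keep the k highest-HU maxima; ties broken by row-major (row, col) order.

    Output is sorted descending by HU (row-major within ties) and the
    operation is idempotent.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    ordered = sorted(records, key=lambda rec: (-rec.hu, rec.row, rec.col))
    return ordered[:k]


__all__ = [
    "GRID_ROWS",
    "GRID_COLS",
    "RasterDensitogram",
    "rasterize",
    "find_local_maxima",
    "cap_top_k",
]
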