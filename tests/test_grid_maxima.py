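import numpy as np
import pytest

from conftest import random_densitogram
from ctoam.errors import ParameterError
from ctoam.grid_maxima import (
    GRID_COLS,
    GRID_ROWS,
    RasterDensitogram,
    cap_top_k,
    find_local_maxima,
    rasterize,
)
from ctoam.volume_io import Densitogram, MaximaRecord


def brute_force_rasterize(d):
    """Independent rectangle-intersection integration, cell by cell."""
    valid = d.valid == 1
    rows = np.where(valid.any(axis=1))[0]
    cols = np.where(valid.any(axis=0))[0]
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    ch = (r1 - r0) / GRID_ROWS
    cw = (c1 - c0) / GRID_COLS
    cells = np.full((GRID_ROWS, GRID_COLS), np.nan)
    occ = np.zeros((GRID_ROWS, GRID_COLS))
    py = np.arange(d.values.shape[0])
    px = np.arange(d.values.shape[1])
    for i in range(GRID_ROWS):
        ylo, yhi = r0 + i * ch, r0 + (i + 1) * ch
        oy = np.clip(np.minimum(py + 1, yhi) - np.maximum(py, ylo), 0, None)
        for j in range(GRID_COLS):
            xlo, xhi = c0 + j * cw, c0 + (j + 1) * cw
            ox = np.clip(np.minimum(px + 1, xhi) - np.maximum(px, xlo), 0, None)
            area = np.outer(oy, ox) * valid
            tot = area.sum()
            occ[i, j] = tot / (ch * cw)
            if tot > 0:
                cells[i, j] = (area * np.where(valid, d.values, 0)).sum() / tot
    return cells, occ


def test_constant_fully_covering_densitogram():
    d = Densitogram(
        values=np.full((80, 100), 1234.0),
        valid=np.ones((80, 100), np.uint8),
        pixel_spacing=(1, 1),
    )
    r = rasterize(d, occupancy_min=0.0)
    assert np.allclose(r.cells, 1234.0)
    assert np.allclose(r.occupancy, 1.0)


def test_integer_tiling_exact_row_means():
    # 100x80 pixels -> exactly 2x2 pixels per cell (wait: 80 rows/40, 100 cols/50)
    ny, nx = 80, 100
    values = np.tile(np.arange(ny, dtype=float)[:, None], (1, nx))
    d = Densitogram(
        values=values, valid=np.ones((ny, nx), np.uint8), pixel_spacing=(1, 1)
    )
    r = rasterize(d, occupancy_min=0.0)
    expected_rows = np.arange(0, ny, 2) + 0.5  # mean of the 2 pixel-row indices
    assert np.allclose(r.cells, expected_rows[:, None])
    assert r.cell_size_mm == pytest.approx((2.0, 2.0))


def test_fractional_tiling_matches_overlap_oracle(rng):
    d = random_densitogram(rng, 55, 43)
    r = rasterize(d, occupancy_min=0.0)
    cells0, occ0 = brute_force_rasterize(d)
    fg = np.isfinite(cells0)
    assert np.array_equal(np.isfinite(r.cells), fg)
    assert np.allclose(r.cells[fg], cells0[fg], rtol=1e-9)
    assert np.allclose(r.occupancy, occ0, atol=1e-9)


def test_rasterize_conservation(rng):
    d = random_densitogram(rng, 61, 47)
    r = rasterize(d, occupancy_min=0.0)
    valid = d.valid == 1
    rows = np.where(valid.any(axis=1))[0]
    cols = np.where(valid.any(axis=0))[0]
    ch = (rows[-1] + 1 - rows[0]) / GRID_ROWS
    cw = (cols[-1] + 1 - cols[0]) / GRID_COLS
    lhs = np.nansum(np.where(np.isfinite(r.cells), r.cells, 0) * r.occupancy) * ch * cw
    rhs = d.values[valid].sum()
    assert lhs == pytest.approx(rhs, rel=1e-6)


def test_occupancy_min_masks_sparse_cells(rng):
    d = random_densitogram(rng, 50, 50, hole_p=0.6)
    r_all = rasterize(d, occupancy_min=0.0)
    r_half = rasterize(d, occupancy_min=0.5)
    assert np.isfinite(r_half.cells).sum() <= np.isfinite(r_all.cells).sum()
    assert not np.isfinite(r_half.cells[r_half.occupancy <= 0.5]).any()


def test_rasterize_parameter_validation(rng):
    d = random_densitogram(rng, 20, 20)
    with pytest.raises(ParameterError):
        rasterize(d, occupancy_min=1.0)


# --- local maxima ----------------------------------------------------------


def grid_from(cells):
    cells = np.asarray(cells, dtype=float)
    full = np.full((GRID_ROWS, GRID_COLS), np.nan)
    full[: cells.shape[0], : cells.shape[1]] = cells
    occ = np.where(np.isfinite(full), 1.0, 0.0)
    return RasterDensitogram(cells=full, occupancy=occ)


def brute_force_maxima(r, connectivity=8):
    out = []
    cells = r.cells
    for i in range(GRID_ROWS):
        for j in range(GRID_COLS):
            if not np.isfinite(cells[i, j]):
                continue
            is_max = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if (di, dj) == (0, 0):
                        continue
                    if connectivity == 4 and abs(di) + abs(dj) != 1:
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < GRID_ROWS and 0 <= nj < GRID_COLS:
                        if np.isfinite(cells[ni, nj]) and not cells[i, j] > cells[ni, nj]:
                            is_max = False
            if is_max:
                out.append((i, j))
    return out


def test_single_gaussian_bump_single_maximum():
    ii, jj = np.mgrid[0:GRID_ROWS, 0:GRID_COLS]
    cells = 1000 + 800 * np.exp(-((ii - 20.0) ** 2 + (jj - 25.0) ** 2) / 60.0)
    r = RasterDensitogram(cells=cells, occupancy=np.ones_like(cells))
    maxima = find_local_maxima(r)
    assert [(m.row, m.col) for m in maxima] == [(20, 25)]


def test_constant_plateau_has_no_maxima():
    r = RasterDensitogram(
        cells=np.full((GRID_ROWS, GRID_COLS), 900.0),
        occupancy=np.ones((GRID_ROWS, GRID_COLS)),
    )
    assert find_local_maxima(r) == []


def test_isolated_foreground_cell_is_maximum():
    cells = np.full((GRID_ROWS, GRID_COLS), np.nan)
    cells[5, 5] = 1200.0
    r = RasterDensitogram(cells=cells, occupancy=np.where(np.isfinite(cells), 1.0, 0.0))
    maxima = find_local_maxima(r)
    assert [(m.row, m.col, m.hu) for m in maxima] == [(5, 5, 1200.0)]


@pytest.mark.parametrize("connectivity", [4, 8])
def test_random_grids_match_exhaustive_scan(rng, connectivity):
    for _ in range(10):
        cells = rng.uniform(500, 2000, (GRID_ROWS, GRID_COLS))
        cells[rng.random((GRID_ROWS, GRID_COLS)) < 0.3] = np.nan
        r = RasterDensitogram(
            cells=cells, occupancy=np.where(np.isfinite(cells), 1.0, 0.0)
        )
        got = [(m.row, m.col) for m in find_local_maxima(r, connectivity=connectivity)]
        assert got == brute_force_maxima(r, connectivity)


def test_maxima_invariant_under_constant_shift(rng):
    cells = rng.uniform(500, 2000, (GRID_ROWS, GRID_COLS))
    r1 = RasterDensitogram(cells=cells, occupancy=np.ones_like(cells))
    r2 = RasterDensitogram(cells=cells + 400.0, occupancy=np.ones_like(cells))
    assert [(m.row, m.col) for m in find_local_maxima(r1)] == [
        (m.row, m.col) for m in find_local_maxima(r2)
    ]


# --- cap_top_k -------------------------------------------------------------


def test_cap_returns_all_when_under_k():
    recs = [MaximaRecord(i, i, 1000.0 + i) for i in range(5)]
    assert len(cap_top_k(recs, k=20)) == 5


def test_cap_matches_full_sort(rng):
    recs = [
        MaximaRecord(int(r), int(c), float(h))
        for r, c, h in zip(
            rng.integers(0, 40, 25),
            rng.integers(0, 50, 25),
            rng.permutation(np.linspace(1000, 2400, 25)),
        )
    ]
    capped = cap_top_k(recs, k=20)
    oracle = sorted(recs, key=lambda m: -m.hu)[:20]
    assert [m.hu for m in capped] == [m.hu for m in oracle]


def test_cap_tie_break_keeps_row_major_earlier():
    recs = [MaximaRecord(i, 0, 2000.0 - i) for i in range(19)]
    tie_a = MaximaRecord(25, 3, 1500.0)
    tie_b = MaximaRecord(25, 7, 1500.0)
    tie_c = MaximaRecord(30, 1, 1500.0)
    capped = cap_top_k(recs + [tie_c, tie_b, tie_a], k=20)
    assert len(capped) == 20
    assert capped[-1] == tie_a  # row-major earliest of the tied records


def test_cap_idempotent(rng):
    recs = [
        MaximaRecord(int(r), int(c), float(h))
        for r, c, h in zip(
            rng.integers(0, 40, 30), rng.integers(0, 50, 30), rng.uniform(900, 2200, 30)
        )
    ]
    once = cap_top_k(recs, k=20)
    assert cap_top_k(once, k=20) == once
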