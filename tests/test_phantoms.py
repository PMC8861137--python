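import dataclasses

import numpy as np
import pytest

from ctoam.errors import ParameterError
from ctoam.grid_maxima import rasterize
from ctoam.mean_map import threshold_high_mineralization
from ctoam.phantoms import (
    PatternField,
    PhantomSpec,
    ellipse_boundary_distance,
    make_phantom,
    pattern_value,
    severity_for_mean_ratio,
    simulate_cohort,
)
from ctoam.pipeline import measure_plate


# --- ellipse distance ------------------------------------------------------


def test_circle_distance_is_analytic(rng):
    r = rng.uniform(0, 0.99, 50)
    theta = rng.uniform(0, 2 * np.pi, 50)
    a = 10.0
    d = ellipse_boundary_distance(a, a, r * a * np.cos(theta), r * a * np.sin(theta))
    assert np.allclose(d, a - r * a, atol=1e-8)


def test_ellipse_distance_axis_points():
    a, b = 20.0, 10.0
    assert ellipse_boundary_distance(a, b, 0.0, 0.0)[0] == pytest.approx(b)
    assert ellipse_boundary_distance(a, b, 19.0, 0.0)[0] == pytest.approx(1.0)
    assert ellipse_boundary_distance(a, b, 0.0, 8.0)[0] == pytest.approx(2.0)
    # exterior point
    assert ellipse_boundary_distance(a, b, 0.0, 12.0)[0] == pytest.approx(2.0)


def test_ellipse_distance_matches_dense_boundary_sampling(rng):
    a, b = 22.5, 17.5
    t = np.linspace(0, 2 * np.pi, 400000)
    bx, by = a * np.cos(t), b * np.sin(t)
    for _ in range(20):
        # random interior point
        while True:
            x = rng.uniform(-a, a)
            y = rng.uniform(-b, b)
            if (x / a) ** 2 + (y / b) ** 2 < 1:
                break
        oracle = np.hypot(bx - x, by - y).min()
        got = ellipse_boundary_distance(a, b, x, y)[0]
        assert got == pytest.approx(oracle, abs=1e-4)


# --- pattern ---------------------------------------------------------------


def test_pattern_baseline_far_from_ring():
    spec = dataclasses.replace(PhantomSpec(), hotspots=())
    # center is > ring_width from the boundary
    assert pattern_value(spec, 0.0, 0.0) == pytest.approx(spec.baseline_hu)


def test_pattern_full_ring_amplitude_on_boundary():
    spec = dataclasses.replace(PhantomSpec(), hotspots=())
    v = pattern_value(spec, spec.semi_axis_x_mm, 0.0)
    assert v == pytest.approx(spec.baseline_hu + spec.ring_amplitude_hu)


def test_pattern_severity_zero_is_identity(rng):
    spec = PhantomSpec()
    ax, ay = spec.semi_axis_x_mm, spec.semi_axis_y_mm
    pts = []
    while len(pts) < 30:
        x, y = rng.uniform(-ax, ax), rng.uniform(-ay, ay)
        if (x / ax) ** 2 + (y / ay) ** 2 < 1:
            pts.append((x, y))
    xs, ys = np.array(pts).T
    assert np.array_equal(
        pattern_value(spec, xs, ys), pattern_value(spec.with_severity(0.0), xs, ys)
    )


def test_pattern_outside_footprint_rejected():
    spec = PhantomSpec()
    with pytest.raises(ParameterError):
        pattern_value(spec, spec.semi_axis_x_mm * 1.1, 0.0)


def test_pattern_monotone_in_severity(rng):
    spec = PhantomSpec()
    ax, ay = spec.semi_axis_x_mm, spec.semi_axis_y_mm
    xs, ys = [], []
    while len(xs) < 100:
        x, y = rng.uniform(-ax, ax), rng.uniform(-ay, ay)
        if (x / ax) ** 2 + (y / ay) ** 2 < 1:
            xs.append(x)
            ys.append(y)
    xs, ys = np.array(xs), np.array(ys)
    prev = pattern_value(spec.with_severity(0.0), xs, ys)
    for s in (0.2, 0.5, 0.8, 1.0):
        cur = pattern_value(spec.with_severity(s), xs, ys)
        assert (cur >= prev - 1e-12).all()
        prev = cur


def test_pattern_continuous_near_ring_edge():
    spec = dataclasses.replace(PhantomSpec(), hotspots=())
    ax = spec.semi_axis_x_mm
    # step across the ring-support edge (distance == ring width)
    xs = np.linspace(ax - spec.ring_width_mm - 0.5, ax - spec.ring_width_mm + 0.5, 201)
    vals = pattern_value(spec, xs, np.zeros_like(xs))
    assert np.abs(np.diff(vals)).max() < 5.0  # no jumps


def test_dorsal_median_field_raises_dorsal_half():
    spec = dataclasses.replace(PhantomSpec(), hotspots=(), dorsal_median_field=True)
    base = dataclasses.replace(spec, dorsal_median_field=False)
    y = spec.semi_axis_y_mm * 0.5
    assert pattern_value(spec, 0.0, y) > pattern_value(base, 0.0, y)
    assert pattern_value(spec, 0.0, -y) == pytest.approx(pattern_value(base, 0.0, -y))


# --- voxelization ----------------------------------------------------------


def test_noiseless_shell_equals_pattern(noiseless_spec, noiseless_phantom):
    vol, mask, truth = noiseless_phantom
    spec = noiseless_spec
    dx, dy, _ = spec.spacing
    nx, ny, _ = vol.shape
    x = (np.arange(nx) - (nx - 1) / 2) * dx
    y = (np.arange(ny) - (ny - 1) / 2) * dy
    # cranial shell slice: z of first mask voxel
    z_sup = np.argwhere(mask.voxels.any(axis=(0, 1)))[0, 0]
    inside = mask.voxels[:, :, z_sup] == 1
    X, Y = np.meshgrid(x, y, indexing="ij")
    expected = pattern_value(spec, X[inside], Y[inside])
    got = vol.voxels[:, :, z_sup][inside].astype(float)
    assert np.abs(got - expected).max() <= 0.5 + 1e-9  # integer rounding only


def test_make_phantom_deterministic():
    spec = PhantomSpec()
    v1, m1, _ = make_phantom(spec, seed=42, compute_truth=False)
    v2, m2, _ = make_phantom(spec, seed=42, compute_truth=False)
    assert np.array_equal(v1.voxels, v2.voxels)
    assert np.array_equal(m1.voxels, m2.voxels)
    v3, _, _ = make_phantom(spec, seed=43, compute_truth=False)
    assert not np.array_equal(v1.voxels, v3.voxels)


def test_make_phantom_rejects_coarse_spacing():
    with pytest.raises(ParameterError):
        make_phantom(PhantomSpec(spacing=(0.5, 0.5, 20.0)), seed=0, compute_truth=False)


def test_end_to_end_recovery_noiseless(noiseless_phantom):
    vol, mask, truth = noiseless_phantom
    for side in ("superior", "inferior"):
        _, report = measure_plate(vol, mask, side)
        assert report.relative_ca == pytest.approx(truth["relative_ca"], rel=0.01)


def test_recovered_calcium_monotone_in_severity(noiseless_spec):
    prev = -np.inf
    for s in (0.0, 0.25, 0.5, 0.75, 1.0):
        vol, mask, _ = make_phantom(
            noiseless_spec.with_severity(s), seed=5, compute_truth=False
        )
        _, report = measure_plate(vol, mask, "superior")
        assert report.relative_ca > prev
        prev = report.relative_ca


def test_ddd_threshold_ring_contains_healthy_ring(noiseless_spec):
    rings = {}
    for s in (0.0, 0.5):
        vol, mask, _ = make_phantom(
            noiseless_spec.with_severity(s), seed=9, compute_truth=False
        )
        dens, _ = measure_plate(vol, mask, "superior")
        raster = rasterize(dens, occupancy_min=0.5)
        rings[s] = threshold_high_mineralization(raster.cells) == 1
    healthy, ddd = rings[0.0], rings[0.5]
    assert (ddd | healthy).sum() == ddd.sum()  # healthy ring subset of DDD ring
    assert ddd.sum() > healthy.sum()  # strict: degeneration broadens the ring


# --- cohorts ---------------------------------------------------------------


def test_severity_solver_hits_target_ratio():
    spec = PhantomSpec()
    sev = severity_for_mean_ratio(spec, 1.34, oversample=4)
    fld = PatternField(spec, oversample=4)
    assert fld.mean_calcium(sev) / fld.mean_calcium(0.0) == pytest.approx(1.34, abs=1e-3)
    with pytest.raises(ParameterError):
        severity_for_mean_ratio(spec, 0.9)


def test_simulate_cohort_deterministic_truth():
    a = simulate_cohort(2, 2, severity=0.4, seed=3)
    b = simulate_cohort(2, 2, severity=0.4, seed=3)
    assert a.truth.equals(b.truth)
    assert np.array_equal(a.plates[0].volume.voxels, b.plates[0].volume.voxels)


def test_simulate_cohort_truth_scales_with_subject_factor():
    sim = simulate_cohort(3, 3, severity=0.5, seed=1, oversample=4)
    fld = PatternField(sim.base_spec, oversample=4)
    for _, row in sim.truth.iterrows():
        expected = row["scale"] * fld.mean_calcium(row["severity"])
        assert row["relative_ca_truth"] == pytest.approx(expected, rel=1e-9)


def test_simulate_cohort_counts():
    sim = simulate_cohort(2, 3, levels=("L4", "L5"), seed=0, oversample=4)
    assert len(sim.plates) == (2 + 3) * 2
    assert len(sim.truth) == (2 + 3) * 2 * 2  # two sides per plate
    assert set(sim.truth.condition) == {"healthy", "ddd"}
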