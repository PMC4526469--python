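"""Track QC, kernel UDs, isopleths and the UDOI overlap index."""

import numpy as np
import pandas as pd
import pytest

from sealniche.geo import LocalProjection
from sealniche.spatial import (
    MaskError,
    Raster,
    UDGrid,
    adhoc_bandwidth,
    estimate_ud,
    interpolate_track,
    isopleth,
    speed_filter,
    udoi,
)

PROJ = LocalProjection()


def _fixes(xy_km, dt_min=10, individual="A", sex="M"):
    xy = np.asarray(xy_km, dtype=float) * 1000.0
    lon, lat = PROJ.inverse(xy[:, 0], xy[:, 1])
    return pd.DataFrame(
        {
            "individual": individual,
            "sex": sex,
            "timestamp": pd.Timestamp("2013-06-04")
            + pd.to_timedelta(np.arange(len(xy)) * dt_min, unit="min"),
            "lon": lon,
            "lat": lat,
        }
    )


# ---------------------------------------------------------------------------
# Speed filter
# ---------------------------------------------------------------------------


def test_stationary_track_unfiltered():
    df = _fixes([[0, 0]] * 10)
    kept, log = speed_filter(df)
    assert len(kept) == 10 and log.empty


def test_single_displaced_fix_removed():
    pts = [[0.1 * i, 0.0] for i in range(10)]  # ~0.17 m/s
    pts[5] = [0.5, 12.0]  # implies ~20 m/s
    kept, log = speed_filter(_fixes(pts))
    assert len(kept) == 9
    assert log.iloc[0]["timestamp"] == pd.Timestamp("2013-06-04 00:50")
    assert log.iloc[0]["implied_speed_ms"] > 8.0


def test_speed_filter_is_idempotent():
    pts = [[0.3 * i, 0.0] for i in range(20)]
    pts[4] = [10.0, 10.0]
    pts[11] = [-8.0, 4.0]
    kept, log1 = speed_filter(_fixes(pts))
    again, log2 = speed_filter(kept)
    assert log2.empty
    pd.testing.assert_frame_equal(kept, again)


def test_first_fix_is_never_removed():
    pts = [[0, 0], [50, 0], [50.1, 0], [50.2, 0]]  # first segment impossible
    kept, log = speed_filter(_fixes(pts))
    assert kept.iloc[0]["timestamp"] == pd.Timestamp("2013-06-04")
    # the filter resolved all violations
    k, _ = speed_filter(kept)
    assert len(k) == len(kept)


def test_degenerate_track_warns():
    pts = [[0, 0], [60, 60], [-60, 30]]
    with pytest.warns(UserWarning, match="degenerated"):
        speed_filter(_fixes(pts))


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------


def test_on_grid_fixes_returned_unchanged():
    df = _fixes([[i, 0] for i in range(5)])
    out = interpolate_track(df, PROJ)
    assert len(out) == 5
    assert np.allclose(out["x"], np.arange(5) * 1000.0, atol=1e-6)


def test_midpoint_for_double_interval():
    df = _fixes([[0, 0], [2, 4]], dt_min=20)
    out = interpolate_track(df, PROJ)
    assert len(out) == 3
    assert out.iloc[1][["x", "y"]].to_numpy() == pytest.approx([1000.0, 2000.0], abs=1e-6)


def test_35_day_track_grid_count():
    t = pd.Timestamp("2013-06-04") + pd.to_timedelta([0, 35 * 86400], unit="s")
    lon, lat = PROJ.inverse(np.array([0.0, 10000.0]), np.array([0.0, 0.0]))
    df = pd.DataFrame({"individual": "A", "sex": "M", "timestamp": t,
                       "lon": lon, "lat": lat})
    out = interpolate_track(df, PROJ, max_gap_s=np.inf)
    assert len(out) == 35 * 144 + 1


def test_long_gaps_left_uninterpolated():
    df = _fixes([[0, 0], [1, 0], [2, 0]], dt_min=10)
    df.loc[2, "timestamp"] += pd.Timedelta(days=2)  # 2-day hole
    out = interpolate_track(df, PROJ, max_gap_s=86400)
    # only the grid points on actual fixes survive inside the gap
    assert len(out) == 3


# ---------------------------------------------------------------------------
# Kernel UD
# ---------------------------------------------------------------------------


def _cluster_positions(n=200, seed=0, spread=3000.0, centre=(0.0, 0.0)):
    rng = np.random.default_rng(seed)
    return (centre[0] + spread * rng.standard_normal(n),
            centre[1] + spread * rng.standard_normal(n))


def test_ud_mode_at_cluster_centroid():
    x, y = _cluster_positions()
    ud = estimate_ud(x, y, cell=500.0)
    r, c = np.unravel_index(np.argmax(ud.density), ud.density.shape)
    cx = ud.x0 + ud.cell * (c + 0.5)
    cy = ud.y0 + ud.cell * (r + 0.5)
    assert np.hypot(cx - x.mean(), cy - y.mean()) < 3 * ud.cell


def test_ud_normalises_to_one():
    x, y = _cluster_positions(seed=1)
    ud = estimate_ud(x, y, cell=750.0)
    assert ud.total_mass() == pytest.approx(1.0, abs=1e-9)


def test_kde_equals_brute_force_sum_of_gaussians():
    """Independent oracle: direct python-loop Gaussian sum at random cells."""
    x, y = _cluster_positions(n=120, seed=2)
    ud = estimate_ud(x, y, cell=1000.0)
    rng = np.random.default_rng(3)
    ny, nx = ud.density.shape
    h = ud.bandwidth
    for _ in range(100):
        r, c = rng.integers(0, ny), rng.integers(0, nx)
        gx = ud.x0 + ud.cell * (c + 0.5)
        gy = ud.y0 + ud.cell * (r + 0.5)
        dens = 0.0
        for xi, yi in zip(x, y):
            dens += np.exp(-((gx - xi) ** 2 + (gy - yi) ** 2) / (2 * h * h))
        dens /= 2 * np.pi * h * h * len(x)
        assert abs(dens - ud.density[r, c]) < 1e-10


def test_all_sea_mask_is_identity():
    x, y = _cluster_positions(seed=4)
    sea = Raster(np.full((60, 60), -50.0), x0=-30000, y0=-30000, cell=1000.0)
    ud_plain = estimate_ud(x, y, cell=1000.0)
    ud_masked = estimate_ud(x, y, cell=1000.0, mask=sea)
    assert np.allclose(ud_plain.density, ud_masked.density)


def test_land_cells_zeroed_and_renormalised():
    x, y = _cluster_positions(seed=5)
    # land everywhere north of y = 0
    vals = np.full((80, 80), -50.0)
    mask = Raster(vals, x0=-40000, y0=-40000, cell=1000.0)
    mask.values[40:, :] = 10.0
    ud = estimate_ud(x, y, cell=1000.0, mask=mask)
    gx, gy = np.meshgrid(*ud.__class__ and
                         (ud.x0 + ud.cell * (np.arange(ud.density.shape[1]) + 0.5),
                          ud.y0 + ud.cell * (np.arange(ud.density.shape[0]) + 0.5)))
    assert (ud.density[gy >= 0] == 0.0).all()
    assert ud.total_mass() == pytest.approx(1.0, abs=1e-9)


def test_all_land_mask_raises():
    x, y = _cluster_positions(seed=6)
    land = Raster(np.full((80, 80), 5.0), x0=-40000, y0=-40000, cell=1000.0)
    with pytest.raises(MaskError):
        estimate_ud(x, y, cell=1000.0, mask=land)


def test_ud_needs_enough_positions():
    with pytest.raises(ValueError):
        estimate_ud(np.zeros(10), np.zeros(10))


def test_adhoc_bandwidth_formula():
    rng = np.random.default_rng(0)
    x, y = rng.normal(0, 100.0, 400), rng.normal(0, 60.0, 400)
    h = adhoc_bandwidth(x, y)
    sigma = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
    assert h == pytest.approx(sigma * 400 ** (-1 / 6))


# ---------------------------------------------------------------------------
# Isopleths & UDOI
# ---------------------------------------------------------------------------


def _uniform_ud(rows, cols, cell=1000.0, x0=0.0, origin_row=0, shape=(8, 8)):
    dens = np.zeros(shape)
    dens[rows, cols] = 1.0
    dens /= dens.sum() * cell * cell
    return UDGrid(density=dens, x0=x0, y0=0.0, cell=cell,
                  sea=np.ones(shape, bool), bandwidth=cell, n_positions=100)


def test_isopleth_level_one_is_all_nonzero_cells():
    ud = _uniform_ud(slice(0, 4), slice(0, 4))
    iso = isopleth(ud, 1.0)
    assert iso.cells.sum() == 16


def test_isopleth_nesting():
    rng = np.random.default_rng(1)
    dens = rng.random((12, 12))
    dens /= dens.sum() * 1e6
    ud = UDGrid(density=dens, x0=0, y0=0, cell=1000.0,
                sea=np.ones((12, 12), bool), bandwidth=1.0, n_positions=100)
    i50 = isopleth(ud, 0.5)
    i95 = isopleth(ud, 0.95)
    assert (i50.cells <= i95.cells).all()
    assert i95.cumulative_probability >= 0.95


def test_udoi_identical_uniform_is_one():
    ud = _uniform_ud(slice(0, 5), slice(0, 5))
    res = udoi(ud, ud, level=0.95)
    assert res.udoi == pytest.approx(1.0, abs=1e-9)


def test_udoi_disjoint_is_zero():
    ud1 = _uniform_ud(slice(0, 3), slice(0, 3))
    ud2 = _uniform_ud(slice(5, 8), slice(5, 8))
    res = udoi(ud1, ud2)
    assert res.udoi == 0.0
    assert res.overlap_area_km2 == 0.0


def test_udoi_matches_brute_force_double_sum():
    rng = np.random.default_rng(7)
    shape = (10, 10)
    cell = 1000.0
    mats = []
    for _ in range(2):
        d = rng.random(shape)
        d /= d.sum() * cell * cell
        mats.append(UDGrid(density=d, x0=0, y0=0, cell=cell,
                           sea=np.ones(shape, bool), bandwidth=1.0, n_positions=100))
    res = udoi(mats[0], mats[1], level=0.95)
    inter = isopleth(mats[0], 0.95).cells & isopleth(mats[1], 0.95).cells
    brute = 0.0
    for r in range(shape[0]):
        for c in range(shape[1]):
            brute += mats[0].density[r, c] * mats[1].density[r, c] * cell * cell
    expected = inter.sum() * cell * cell * brute
    assert abs(res.udoi - expected) < 1e-12


def test_udoi_symmetry():
    rng = np.random.default_rng(8)
    mats = []
    for _ in range(2):
        d = rng.random((15, 15))
        d /= d.sum() * 1e6
        mats.append(UDGrid(density=d, x0=0, y0=0, cell=1000.0,
                           sea=np.ones((15, 15), bool), bandwidth=1.0, n_positions=100))
    assert udoi(mats[0], mats[1]).udoi == pytest.approx(udoi(mats[1], mats[0]).udoi)


def test_udoi_grid_geometry_must_match():
    ud1 = _uniform_ud(slice(0, 3), slice(0, 3))
    ud2 = _uniform_ud(slice(0, 3), slice(0, 3), x0=500.0)
    with pytest.raises(ValueError):
        udoi(ud1, ud2)


def test_udoi_stable_under_grid_refinement():
    """Halving the cell size changes UDOI by < 2% for smooth UDs."""
    xa, ya = _cluster_positions(n=400, seed=9, spread=5000.0, centre=(0, 0))
    xb, yb = _cluster_positions(n=400, seed=10, spread=5000.0, centre=(4000, 0))
    vals = {}
    for cell in (1000.0, 500.0):
        grid = (-30000.0, -30000.0, int(60000 / cell), int(60000 / cell))
        ud1 = estimate_ud(xa, ya, cell=cell, bandwidth=2500.0, grid=grid)
        ud2 = estimate_ud(xb, yb, cell=cell, bandwidth=2500.0, grid=grid)
        vals[cell] = udoi(ud1, ud2).udoi
    assert vals[500.0] == pytest.approx(vals[1000.0], rel=0.02)
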