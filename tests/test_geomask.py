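import math

import numpy as np
import networkx as nx
import pandas as pd
import pytest
import shapely

from snowscr.geomask import (
    ConductanceModel,
    LeastCostEngine,
    RasterGrid,
    biomass_surface,
    build_mask,
    least_cost_distances,
    moving_window_smooth,
    polygon_density,
    read_asc,
    suggest_buffer,
    terrain_ruggedness_index,
    write_asc,
)

from conftest import make_mask


# ---------------------------------------------------------------------- mask

def test_build_mask_single_detector_axis_neighbours():
    """Buffer equal to the spacing keeps the centre pixel and its four axis
    neighbours (diagonals are at spacing*sqrt(2) > buffer)."""
    mask = build_mask(np.array([[0.0, 0.0]]), buffer_width=500.0, spacing=500.0)
    assert mask.n_pixels == 5
    d = np.hypot(mask.centers[:, 0], mask.centers[:, 1])
    assert np.all(d <= 500.0 + 1e-6)


def test_build_mask_matches_bruteforce_two_detectors():
    det = np.array([[0.0, 0.0], [10_000.0, 0.0]])
    buffer, spacing = 1_000.0, 500.0
    mask = build_mask(det, buffer, spacing)
    # brute-force scan over the anchored candidate lattice
    pad = math.ceil(buffer / spacing)
    expected = set()
    for i in range(-pad, int((det[:, 0].max() - det[:, 0].min()) / spacing) + pad + 1):
        for j in range(-pad, pad + 1):
            x, y = i * spacing, j * spacing
            if min(np.hypot(x - dx, y - dy) for dx, dy in det) <= buffer + 1e-9:
                expected.add((x, y))
    got = {(round(x, 3), round(y, 3)) for x, y in mask.centers}
    assert got == expected


def test_build_mask_altitude_exclusion_matches_bruteforce():
    """A DEM plateau above the cutoff excludes exactly the brute-force set."""
    n = 120
    vals = np.full((n, n), 4000.0)
    vals[:, n // 2 :] = 5_400.0  # east half is a high plateau
    dem = RasterGrid(-30_000.0, -30_000.0, 500.0, vals)
    det = np.array([[0.0, 0.0]])
    buffer, spacing = 5_000.0, 500.0
    mask = build_mask(det, buffer, spacing, exclusion="Altitude > 5200",
                      rasters={"Altitude": dem})
    pad = math.ceil(buffer / spacing)
    count = 0
    for i in range(-pad, pad + 1):
        for j in range(-pad, pad + 1):
            x, y = i * spacing, j * spacing
            if np.hypot(x, y) <= buffer + 1e-9 and dem.sample(x, y) <= 5200:
                count += 1
    assert mask.n_pixels == count
    assert np.all(mask.covariates["Altitude"] <= 5200)


def test_build_mask_empty_after_exclusion_names_predicate():
    dem = RasterGrid(-2000.0, -2000.0, 500.0, np.full((10, 10), 6000.0))
    with pytest.raises(ValueError, match="Altitude > 5200"):
        build_mask(np.array([[0.0, 0.0]]), 1000.0, 500.0,
                   exclusion="Altitude > 5200", rasters={"Altitude": dem})


@pytest.mark.parametrize("sigma,mult,expected", [(6000.0, 4.0, 24_000.0), (1.0, 1.0, 1.0)])
def test_suggest_buffer(sigma, mult, expected):
    assert suggest_buffer(sigma, mult) == expected


def test_suggest_buffer_default_multiplier_and_error():
    assert suggest_buffer(2500.0) == 10_000.0
    with pytest.raises(ValueError):
        suggest_buffer(0.0)


# ----------------------------------------------------------------- ruggedness

def test_tri_flat_dem_is_zero():
    dem = RasterGrid(0, 0, 30.0, np.full((6, 6), 4321.0))
    assert np.allclose(terrain_ruggedness_index(dem).values, 0.0)


def test_tri_unit_impulse_centre():
    vals = np.zeros((3, 3))
    vals[1, 1] = 1.0
    tri = terrain_ruggedness_index(RasterGrid(0, 0, 30.0, vals))
    assert tri.values[1, 1] == pytest.approx(math.sqrt(8), abs=1e-12)


def test_tri_matches_loop_oracle():
    rng = np.random.default_rng(42)
    vals = rng.uniform(3000, 5000, size=(5, 5))
    tri = terrain_ruggedness_index(RasterGrid(0, 0, 30.0, vals)).values
    for r in range(5):
        for c in range(5):
            acc = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < 5 and 0 <= cc < 5:
                        acc += (vals[rr, cc] - vals[r, c]) ** 2
            assert tri[r, c] == pytest.approx(math.sqrt(acc), rel=1e-12)


def test_tri_shift_invariant_scale_equivariant():
    rng = np.random.default_rng(7)
    vals = rng.normal(size=(6, 7))
    base = terrain_ruggedness_index(RasterGrid(0, 0, 30.0, vals)).values
    shifted = terrain_ruggedness_index(RasterGrid(0, 0, 30.0, vals + 1234.5)).values
    scaled = terrain_ruggedness_index(RasterGrid(0, 0, 30.0, vals * -3.0)).values
    assert np.allclose(base, shifted, atol=1e-8)
    assert np.allclose(scaled, 3.0 * base, rtol=1e-10)


def test_tri_too_small():
    with pytest.raises(ValueError):
        terrain_ruggedness_index(RasterGrid(0, 0, 30.0, np.zeros((1, 1))))


# ------------------------------------------------------------------ smoothing

def test_smooth_constant_unchanged():
    g = RasterGrid(0, 0, 500.0, np.full((8, 8), 3.14))
    out = moving_window_smooth(g, 1500.0)
    assert np.allclose(out.values, 3.14)


def test_smooth_impulse_divided_by_window_size():
    vals = np.zeros((11, 11))
    vals[5, 5] = 1.0
    g = RasterGrid(0, 0, 500.0, vals)
    radius = 1500.0
    out = moving_window_smooth(g, radius)
    # brute-force count of cells in the circular window
    k = sum(
        1
        for dx in range(-3, 4)
        for dy in range(-3, 4)
        if (dx**2 + dy**2) * 500.0**2 <= radius**2 + 1e-6
    )
    assert out.values[5, 5] == pytest.approx(1.0 / k, rel=1e-12)


def test_smooth_radius_below_spacing_errors():
    g = RasterGrid(0, 0, 500.0, np.zeros((4, 4)))
    with pytest.raises(ValueError):
        moving_window_smooth(g, 499.9)


def test_smooth_toroidal_preserves_global_mean():
    rng = np.random.default_rng(3)
    g = RasterGrid(0, 0, 500.0, rng.normal(size=(12, 12)))
    out = moving_window_smooth(g, 1500.0, mode="wrap")
    assert out.values.mean() == pytest.approx(g.values.mean(), abs=1e-12)


def test_smooth_square_window_option():
    vals = np.zeros((9, 9))
    vals[4, 4] = 1.0
    out = moving_window_smooth(RasterGrid(0, 0, 500.0, vals), 500.0, shape="square")
    assert out.values[4, 4] == pytest.approx(1.0 / 9.0)


# ------------------------------------------------------------ polygon density

def test_polygon_density_square():
    grid = RasterGrid(0, 0, 1000.0, np.zeros((20, 20)))
    square = shapely.box(2000, 2000, 12_000, 12_000)  # 10 km x 10 km
    out = polygon_density([square], [100.0], grid)
    inside = out.sample(7000, 7000)
    outside = out.sample(500, 500)
    assert inside == pytest.approx(1.0)
    assert outside == 0.0


def test_polygon_density_two_disjoint_squares_bruteforce():
    grid = RasterGrid(0, 0, 500.0, np.zeros((30, 30)))
    a = shapely.box(0, 0, 5000, 5000)
    b = shapely.box(8000, 8000, 12_000, 10_000)
    out = polygon_density([a, b], [50.0, 16.0], grid)
    xx, yy = grid.cell_centers()
    expected = np.zeros(len(xx))
    for poly, cnt in [(a, 50.0), (b, 16.0)]:
        for i, (x, y) in enumerate(zip(xx, yy)):
            if poly.intersects(shapely.Point(x, y)):
                expected[i] += cnt / (poly.area / 1e6)
    assert np.allclose(out.values.ravel(), expected)


def test_polygon_density_zero_head_and_degenerate():
    grid = RasterGrid(0, 0, 1000.0, np.zeros((5, 5)))
    out = polygon_density([shapely.box(0, 0, 3000, 3000)], [0.0], grid)
    assert np.all(out.values == 0.0)
    with pytest.raises(ValueError):
        polygon_density([shapely.LineString([(0, 0), (1, 1)]).buffer(0)], [5.0], grid)


# -------------------------------------------------------------------- biomass

def test_biomass_linear_combination():
    small = RasterGrid(0, 0, 500.0, np.ones((4, 4)))
    large = RasterGrid(0, 0, 500.0, np.ones((4, 4)))
    out = biomass_surface(small, large, 35.0, 250.0)
    assert np.allclose(out.values, 285.0)
    zero = biomass_surface(small.with_values(np.zeros((4, 4))),
                           large.with_values(np.zeros((4, 4))))
    assert np.all(zero.values == 0.0)


def test_biomass_matches_cellwise_loop_and_alignment_error():
    rng = np.random.default_rng(11)
    s = RasterGrid(0, 0, 500.0, rng.uniform(0, 10, (6, 6)))
    l = RasterGrid(0, 0, 500.0, rng.uniform(0, 14, (6, 6)))
    out = biomass_surface(s, l, 35.0, 250.0).values
    for r in range(6):
        for c in range(6):
            assert out[r, c] == pytest.approx(s.values[r, c] * 35 + l.values[r, c] * 250)
    with pytest.raises(ValueError):
        biomass_surface(s, RasterGrid(100, 0, 500.0, l.values))


# --------------------------------------------------------- least-cost distance

def test_lcp_uniform_conductance_collinear():
    mask = make_mask(5, 1, spacing=1000.0, covariates={"Altitude": np.zeros(5)})
    cm = ConductanceModel("Altitude", 0.0)
    d = least_cost_distances(mask, cm, mask.centers[[0]], mask.centers[[1]])
    assert d[0, 0] == pytest.approx(1000.0)
    same = least_cost_distances(mask, cm, mask.centers[[2]], mask.centers[[2]])
    assert same[0, 0] == 0.0


def test_lcp_matches_networkx_dijkstra_with_barrier():
    """Low conductance across the middle row forces a detour; the cost must
    equal Dijkstra on the explicitly enumerated weighted graph."""
    n_cols, n_rows = 5, 3
    alt = np.zeros(n_cols * n_rows)
    # middle row, interior columns: deep 'gorge' (very low conductance)
    for c in range(1, 4):
        alt[1 * n_cols + c] = -10.0
    mask = make_mask(n_cols, n_rows, spacing=1000.0, covariates={"Altitude": alt})
    alpha = 2.0
    cm = ConductanceModel("Altitude", alpha)
    z = (alt - alt.mean()) / alt.std()
    g = nx.Graph()
    for i in range(mask.n_pixels):
        for j in range(mask.n_pixels):
            if j <= i:
                continue
            dx = mask.centers[j, 0] - mask.centers[i, 0]
            dy = mask.centers[j, 1] - mask.centers[i, 1]
            if max(abs(dx), abs(dy)) <= 1000.0 + 1e-6 and (dx or dy):
                w = math.hypot(dx, dy) * 0.5 * (math.exp(-alpha * z[i]) + math.exp(-alpha * z[j]))
                g.add_edge(i, j, weight=w)
    src, dst = 5, 9  # west and east ends of the middle row
    expected = nx.dijkstra_path_length(g, src, dst, weight="weight")
    got = least_cost_distances(mask, cm, mask.centers[[src]], mask.centers[[dst]])[0, 0]
    assert got == pytest.approx(expected, rel=1e-9)
    path = nx.dijkstra_path(g, src, dst, weight="weight")
    barrier = {1 * n_cols + c for c in range(1, 4)}
    assert not barrier & set(path)  # optimal route detours around the gorge
    path_straight = [5, 6, 7, 8, 9]
    straight = sum(g.edges[a, b]["weight"] for a, b in zip(path_straight, path_straight[1:]))
    assert straight > got  # the straight route through the gorge costs more


def test_lcp_octile_bound_alpha_zero():
    """On a full rectangular mask with uniform conductance the 8-neighbour
    metric exceeds Euclidean distance by at most the octile factor ~1.082."""
    mask = make_mask(9, 7, spacing=500.0, covariates={"Altitude": np.zeros(63)})
    engine = LeastCostEngine(mask, "Altitude")
    d = engine.distances(0.0, np.arange(mask.n_pixels))
    diff = mask.centers[:, None, :] - mask.centers[None, :, :]
    eucl = np.sqrt((diff**2).sum(axis=2))
    off = eucl > 0
    ratio = d[off] / eucl[off]
    assert np.all(ratio >= 1.0 - 1e-9)
    assert np.all(ratio <= 1.0824 + 1e-6)


def test_lcp_symmetry_and_triangle_random_masks():
    rng = np.random.default_rng(0)
    for _ in range(25):
        keep = rng.random(16) < 0.8
        if keep.sum() < 3:
            continue
        alt = rng.normal(size=16)[keep]
        full = make_mask(4, 4, spacing=1000.0)
        mask = make_mask(4, 4, spacing=1000.0)
        centers = full.centers[keep]
        from snowscr.geomask import MaskGrid
        mask = MaskGrid(centers=centers, spacing=1000.0,
                        covariates=pd.DataFrame({"Altitude": alt}))
        engine = LeastCostEngine(mask, "Altitude")
        d = engine.distances(rng.uniform(-1, 1), np.arange(mask.n_pixels))
        assert np.allclose(d, d.T, equal_nan=True)
        n = mask.n_pixels
        via = d[:, None, :] + d[None, :, :].transpose(1, 0, 2)
        assert np.all(d[:, None, :].repeat(n, 1) <= via + 1e-6)


def test_lcp_monotone_alpha_on_high_side():
    """With conductance increasing in altitude, raising alpha makes travel on
    the high-altitude side weakly cheaper."""
    alt = np.linspace(3000, 5000, 10)
    mask = make_mask(10, 1, spacing=1000.0, covariates={"Altitude": alt})
    engine = LeastCostEngine(mask, "Altitude")
    prev = np.inf
    for alpha in (0.0, 0.2, 0.5, 1.0):
        d = engine.distances(alpha, np.array([7]))[0, 9]  # both pixels high side
        assert d <= prev + 1e-9
        prev = d


def test_lcp_point_outside_mask_errors():
    mask = make_mask(3, 3, spacing=1000.0, covariates={"Altitude": np.zeros(9)})
    cm = ConductanceModel("Altitude", 0.0)
    with pytest.raises(ValueError, match="outside"):
        least_cost_distances(mask, cm, np.array([[99_000.0, 0.0]]), mask.centers[[0]])


def test_lcp_disconnected_inf_with_warning():
    from snowscr.geomask import MaskGrid
    centers = np.array([[500.0, 500.0], [10_500.0, 500.0]])  # far apart, no adjacency
    mask = MaskGrid(centers=centers, spacing=1000.0,
                    covariates=pd.DataFrame({"Altitude": [0.0, 1.0]}))
    cm = ConductanceModel("Altitude", 0.0)
    with pytest.warns(UserWarning, match="disconnected"):
        d = least_cost_distances(mask, cm, centers[[0]], centers[[1]])
    assert np.isinf(d[0, 0])


# ------------------------------------------------------------------- asc I/O

def test_asc_roundtrip(tmp_path):
    rng = np.random.default_rng(5)
    vals = rng.normal(size=(6, 4))
    vals[2, 1] = -9999.0
    g = RasterGrid(-1000.0, 2000.0, 500.0, vals)
    path = tmp_path / "x.asc"
    write_asc(g, path)
    back = read_asc(path)
    assert back.n_rows == 6 and back.n_cols == 4
    assert back.origin_x == g.origin_x and back.origin_y == g.origin_y
    assert np.allclose(back.values, g.values, atol=1e-9)
    assert back.is_nodata()[2, 1]
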