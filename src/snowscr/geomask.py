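"""Habitat masks, covariate rasters and least-cost ecological distance.

Spatial capture-recapture integrates the unknown activity-centre locations
over a discretized "habitat mask": the set of pixel centres within a buffer
of the detector array, minus excluded habitat (here, typically terrain above
5,200 m).  This module builds that mask, prepares the covariate surfaces
that drive the density model (terrain ruggedness, moving-window smoothing,
pasture-polygon livestock densities, livestock biomass), and computes
least-cost-path (ecological) distances on the mask under a parameterized
conductance model, where per-pixel conductance is c(s) = exp(alpha * z(s))
for a standardized covariate z (altitude in the motivating study).

Coordinates are planar meters throughout; rasters use the ESRI ASCII grid
dialect with a lower-left origin.  Internally ``RasterGrid.values[0, 0]`` is
the south-west cell (row index increases northward); the .asc writer flips
rows back to the north-up order the format requires.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "RasterGrid",
    "MaskGrid",
    "ConductanceModel",
    "LeastCostEngine",
    "build_mask",
    "suggest_buffer",
    "terrain_ruggedness_index",
    "moving_window_smooth",
    "polygon_density",
    "biomass_surface",
    "least_cost_distances",
    "read_asc",
    "write_asc",
]

#: Default unit body masses (kg) used to convert livestock head densities to
#: biomass.  Small-bodied stock are sheep/goats; large-bodied are yak, cattle
#: hybrids and horses.  Overridable in :func:`biomass_surface`.
DEFAULT_UNIT_MASS_SMALL_KG = 35.0
DEFAULT_UNIT_MASS_LARGE_KG = 250.0

_OCTILE_EPS = 1e-9


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

@dataclass
class RasterGrid:
    """A single-layer planar raster on a regular square grid.

    Parameters
    ----------
    origin_x, origin_y
        Coordinates (m) of the lower-left *corner* of the grid.
    spacing
        Cell side length (m).
    values
        ``(n_rows, n_cols)`` array; row 0 is the southernmost row.
    nodata
        Sentinel for missing cells.
    """

    origin_x: float
    origin_y: float
    spacing: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("values must be a 2-D array with at least one cell")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.spacing

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.n_rows) + 0.5) * self.spacing

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (x, y) coordinates of every cell centre (row-major)."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return xx.ravel(), yy.ravel()

    def is_nodata(self) -> np.ndarray:
        v = self.values
        return ~np.isfinite(v) | np.isclose(v, self.nodata)

    def sample(self, x, y):
        """Nearest-cell lookup at planar coordinates (vectorized)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.clip(np.floor((x - self.origin_x) / self.spacing).astype(int), 0, self.n_cols - 1)
        row = np.clip(np.floor((y - self.origin_y) / self.spacing).astype(int), 0, self.n_rows - 1)
        out = self.values[row, col]
        nd = self.is_nodata()[row, col]
        return np.where(nd, np.nan, out)

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.origin_x, self.origin_y, self.spacing, values, self.nodata)

    def aligned_with(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.spacing - other.spacing) <= tol
        )


def write_asc(grid: RasterGrid, path) -> None:
    """Write a raster as an ESRI ASCII grid (.asc)."""
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y!r}\n"
        f"cellsize {grid.spacing!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    body = np.where(grid.is_nodata(), grid.nodata, grid.values)[::-1]  # north-up on disk
    with open(path, "w") as fh:
        fh.write(header)
        for row in body:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_asc(path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    values = np.asarray(rows, dtype=float)[::-1]  # back to south-up internal order
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"raster body shape {values.shape} does not match header")
    return RasterGrid(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        spacing=header["cellsize"],
        values=values,
        nodata=header.get("nodata_value", -9999.0),
    )


# ---------------------------------------------------------------------------
# Covariate surface preparation
# ---------------------------------------------------------------------------

def terrain_ruggedness_index(dem: RasterGrid) -> RasterGrid:
    """Terrain ruggedness index: per cell, sqrt of the summed squared
    elevation differences to its 8 neighbours; border cells use the
    neighbours that exist (no padding)."""
    if dem.n_rows < 2 or dem.n_cols < 2:
        raise ValueError("DEM must be at least 2x2 to compute ruggedness")
    z = np.where(dem.is_nodata(), np.nan, dem.values)
    padded = np.pad(z, 1, constant_values=np.nan)
    acc = np.zeros_like(z)
    nr, nc = z.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = padded[1 + dr : 1 + dr + nr, 1 + dc : 1 + dc + nc]
            diff2 = (nb - z) ** 2
            acc += np.where(np.isnan(diff2), 0.0, diff2)
    tri = np.sqrt(acc)
    tri[np.isnan(z)] = dem.nodata
    return dem.with_values(tri)


def moving_window_smooth(
    surface: RasterGrid,
    radius: float,
    shape: str = "circular",
    mode: str = "constant",
) -> RasterGrid:
    """Replace each cell by the mean over a moving window of given radius (m).

    ``shape`` is "circular" (cells whose centres lie within ``radius``) or
    "square" (Chebyshev window).  nodata cells are excluded from the mean;
    ``mode`` follows scipy.ndimage boundary semantics ("constant" treats
    outside cells as absent; "wrap" gives a toroidal grid).
    """
    if radius < surface.spacing:
        raise ValueError(f"window radius {radius} m is smaller than the cell spacing {surface.spacing} m")
    if shape not in {"circular", "square"}:
        raise ValueError("shape must be 'circular' or 'square'")
    k = int(math.floor(radius / surface.spacing + 1e-9))
    dx, dy = np.meshgrid(np.arange(-k, k + 1), np.arange(-k, k + 1))
    if shape == "circular":
        footprint = (dx**2 + dy**2) * surface.spacing**2 <= radius**2 + 1e-6
    else:
        footprint = np.ones_like(dx, dtype=bool)
    valid = ~surface.is_nodata()
    vals = np.where(valid, surface.values, 0.0)
    foot = footprint.astype(float)
    ssum = ndimage.correlate(vals, foot, mode=mode, cval=0.0)
    scount = ndimage.correlate(valid.astype(float), foot, mode=mode, cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(scount > 0, ssum / scount, surface.nodata)
    out[~valid] = surface.nodata
    return surface.with_values(out)


def polygon_density(
    polygons: Sequence[shapely.Geometry],
    counts: Sequence[float],
    grid: RasterGrid,
) -> RasterGrid:
    """Rasterize per-polygon head counts into a density surface (heads/km²).

    Cells whose centre falls in polygon *i* receive ``counts[i] / area_i``;
    overlapping polygons sum; cells in no polygon get 0.
    """
    if len(polygons) != len(counts):
        raise ValueError("polygons and counts must have equal length")
    xx, yy = grid.cell_centers()
    out = np.zeros(grid.values.shape, dtype=float).ravel()
    for poly, count in zip(polygons, counts):
        if count < 0:
            raise ValueError("counts must be >= 0")
        area_km2 = poly.area / 1e6
        if area_km2 <= 0:
            raise ValueError("degenerate (zero-area) polygon")
        inside = shapely.intersects_xy(poly, xx, yy)
        out[inside] += count / area_km2
    return grid.with_values(out.reshape(grid.values.shape))


def biomass_surface(
    small_density: RasterGrid,
    large_density: RasterGrid,
    unit_mass_small: float = DEFAULT_UNIT_MASS_SMALL_KG,
    unit_mass_large: float = DEFAULT_UNIT_MASS_LARGE_KG,
) -> RasterGrid:
    """Combine small/large livestock head densities into biomass (kg/km²)."""
    if not small_density.aligned_with(large_density):
        raise ValueError("livestock density grids are not aligned")
    if unit_mass_small <= 0 or unit_mass_large <= 0:
        raise ValueError("unit masses must be > 0")
    nd = small_density.is_nodata() | large_density.is_nodata()
    out = small_density.values * unit_mass_small + large_density.values * unit_mass_large
    out = np.where(nd, small_density.nodata, out)
    return small_density.with_values(out)


# ---------------------------------------------------------------------------
# Habitat mask
# ---------------------------------------------------------------------------

@dataclass
class MaskGrid:
    """The integration region: pixel centres with attached covariates.

    ``covariates`` is indexed 0..n_pixels-1 in the same order as ``centers``.
    ``col_index``/``row_index`` place every pixel on the underlying regular
    grid so adjacency (for least-cost paths) is well defined.
    """

    centers: np.ndarray
    spacing: float
    covariates: pd.DataFrame
    col_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    row_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        n = len(self.centers)
        if n == 0:
            raise ValueError("mask has no pixels")
        if len(np.unique(np.round(self.centers, 6), axis=0)) != n:
            raise ValueError("mask pixel centres must be unique")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=range(n))
        self.covariates = self.covariates.reset_index(drop=True)
        if len(self.covariates) != n:
            raise ValueError("covariate table length does not match pixel count")
        for col in self.covariates.columns:
            vals = self.covariates[col].to_numpy()
            if np.issubdtype(vals.dtype, np.number) and not np.all(np.isfinite(vals)):
                raise ValueError(f"covariate {col!r} is not finite at every mask pixel")
        if self.col_index is None or self.row_index is None:
            x0 = self.centers[:, 0].min()
            y0 = self.centers[:, 1].min()
            self.col_index = np.round((self.centers[:, 0] - x0) / self.spacing).astype(int)
            self.row_index = np.round((self.centers[:, 1] - y0) / self.spacing).astype(int)

    @property
    def n_pixels(self) -> int:
        return len(self.centers)

    @property
    def area_per_pixel(self) -> float:
        """Pixel area in km²."""
        return (self.spacing / 1000.0) ** 2

    @property
    def total_area(self) -> float:
        """Mask area in km²."""
        return self.n_pixels * self.area_per_pixel

    def snap(self, points: np.ndarray) -> np.ndarray:
        """Indices of the mask pixels nearest each point.

        A point farther than half a diagonal from every pixel centre is
        outside the mask.  Equidistant ties resolve to the lowest pixel
        index (cKDTree returns the smallest index on ties).
        """
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        tree = cKDTree(self.centers)
        dist, idx = tree.query(points)
        limit = self.spacing * math.sqrt(2) / 2 + 1e-6
        if np.any(dist > limit):
            bad = points[dist > limit][0]
            raise ValueError(f"point ({bad[0]:.1f}, {bad[1]:.1f}) lies outside the mask")
        return np.asarray(idx, dtype=int)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"x": self.centers[:, 0], "y": self.centers[:, 1]})
        out = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spacing: float) -> "MaskGrid":
        df = pd.read_csv(path)
        centers = df[["x", "y"]].to_numpy(float)
        cov = df.drop(columns=["x", "y"])
        return cls(centers=centers, spacing=spacing, covariates=cov)


def suggest_buffer(sigma_hat: float, multiplier: float = 4.0) -> float:
    """Suggested mask buffer width: ``multiplier × sigma_hat`` (m).

    With the default multiplier of 4, encounter probability under a
    half-normal detection function at the buffer edge is ~exp(-8) of its
    value at the activity centre, so bias from truncating the integration
    region is negligible.
    """
    if sigma_hat <= 0:
        raise ValueError("sigma_hat must be > 0")
    return multiplier * sigma_hat


def build_mask(
    detectors,
    buffer_width: float,
    spacing: float,
    exclusion: "str | Callable[[pd.DataFrame], np.ndarray] | None" = None,
    rasters: "Mapping[str, RasterGrid] | None" = None,
) -> MaskGrid:
    """Build the habitat mask: pixel centres within ``buffer_width`` of at
    least one detector, minus pixels where ``exclusion`` is true.

    The pixel lattice is anchored so a pixel centre coincides with the
    detector bounding-box minimum.  ``rasters`` are sampled (nearest cell) at
    each centre to form the covariate table; ``exclusion`` is a pandas
    ``eval`` expression on those covariates (e.g. ``"Altitude > 5200"``) or a
    callable returning a boolean array.  Pixels whose sampled covariates are
    missing (nodata) are dropped.
    """
    from .captures import DetectorArray  # avoid cycle at import time

    if isinstance(detectors, DetectorArray):
        det_xy = detectors.xy
    else:
        det_xy = np.asarray(detectors, dtype=float).reshape(-1, 2)
    if len(det_xy) < 1:
        raise ValueError("at least one detector is required")
    if buffer_width <= 0 or spacing <= 0:
        raise ValueError("buffer_width and spacing must be > 0")

    pad = int(math.ceil(buffer_width / spacing))
    x_min, y_min = det_xy.min(axis=0)
    x_max, y_max = det_xy.max(axis=0)
    xs = x_min + np.arange(-pad, int(math.ceil((x_max - x_min) / spacing)) + pad + 1) * spacing
    ys = y_min + np.arange(-pad, int(math.ceil((y_max - y_min) / spacing)) + pad + 1) * spacing
    xx, yy = np.meshgrid(xs, ys)
    centers = np.column_stack([xx.ravel(), yy.ravel()])

    tree = cKDTree(det_xy)
    dist, _ = tree.query(centers)
    keep = dist <= buffer_width + _OCTILE_EPS
    centers = centers[keep]
    if len(centers) == 0:
        raise ValueError("no pixels within buffer of any detector")

    cov = pd.DataFrame(index=range(len(centers)))
    if rasters:
        for name, grid in rasters.items():
            cov[name] = grid.sample(centers[:, 0], centers[:, 1])
        finite = np.all(np.isfinite(cov.to_numpy(float)), axis=1)
        if not finite.all():
            centers = centers[finite]
            cov = cov.loc[finite].reset_index(drop=True)
        if len(centers) == 0:
            raise ValueError("all buffered pixels have missing covariate values")

    if exclusion is not None:
        if callable(exclusion):
            excl = np.asarray(exclusion(cov), dtype=bool)
            label = getattr(exclusion, "__name__", repr(exclusion))
        else:
            excl = cov.eval(exclusion).to_numpy(dtype=bool)
            label = exclusion
        keep2 = ~excl
        if not keep2.any():
            raise ValueError(f"mask is empty after applying exclusion predicate {label!r}")
        centers = centers[keep2]
        cov = cov.loc[keep2].reset_index(drop=True)

    return MaskGrid(centers=centers, spacing=spacing, covariates=cov)


# ---------------------------------------------------------------------------
# Least-cost (ecological) distance
# ---------------------------------------------------------------------------

@dataclass
class ConductanceModel:
    """Log-linear conductance on one standardized mask covariate.

    Per-pixel conductance is ``c(s) = exp(coefficient * z(s))`` with ``z``
    the z-scored covariate; positive coefficients make high-covariate pixels
    cheaper to traverse.  ``coefficient = 0`` reduces least-cost distance to
    plain grid-graph shortest paths.
    """

    covariate: str = "Altitude"
    coefficient: float = 0.0
    neighbourhood: int = 8

    def __post_init__(self) -> None:
        if not np.isfinite(self.coefficient):
            raise ValueError("conductance coefficient must be finite")
        if self.neighbourhood not in (4, 8):
            raise ValueError("neighbourhood must be 4 or 8")


class LeastCostEngine:
    """Precomputed adjacency for repeated least-cost solves on one mask.

    Edges connect 4- or 8-neighbour pixels; an edge's traversal cost is the
    Euclidean step length times the mean of the two pixel *resistances*
    (1/conductance).  Built once per mask/covariate; per-alpha distance
    matrices are cached because a quasi-Newton fit revisits nearby alpha
    values constantly.
    """

    def __init__(self, mask: MaskGrid, covariate: str | None, neighbourhood: int = 8):
        self.mask = mask
        self.n = mask.n_pixels
        if covariate is not None:
            if covariate not in mask.covariates.columns:
                raise KeyError(f"mask has no covariate named {covariate!r}")
            z = mask.covariates[covariate].to_numpy(float)
            sd = z.std()
            self.z = (z - z.mean()) / (sd if sd > 0 else 1.0)
        else:
            self.z = np.zeros(self.n)
        offsets = [(1, 0), (0, 1)]
        if neighbourhood == 8:
            offsets += [(1, 1), (1, -1)]
        index = {(c, r): i for i, (c, r) in enumerate(zip(mask.col_index, mask.row_index))}
        a_idx, b_idx, steps = [], [], []
        for dc, dr in offsets:
            step = mask.spacing * math.hypot(dc, dr)
            for i, (c, r) in enumerate(zip(mask.col_index, mask.row_index)):
                j = index.get((c + dc, r + dr))
                if j is not None:
                    a_idx.append(i)
                    b_idx.append(j)
                    steps.append(step)
        self.edge_a = np.asarray(a_idx, dtype=int)
        self.edge_b = np.asarray(b_idx, dtype=int)
        self.steps = np.asarray(steps, dtype=float)
        self._cache: dict[tuple[float, tuple], np.ndarray] = {}

    def distances(self, alpha: float, from_idx: np.ndarray) -> np.ndarray:
        """All least-cost distances (m) from the given source pixels to every
        mask pixel; unreachable pixels get +inf."""
        from_idx = np.atleast_1d(np.asarray(from_idx, dtype=int))
        key = (round(float(alpha), 12), tuple(from_idx.tolist()))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        resistance = np.exp(-alpha * self.z)  # 1/c(s)
        w = self.steps * 0.5 * (resistance[self.edge_a] + resistance[self.edge_b])
        graph = csr_matrix((w, (self.edge_a, self.edge_b)), shape=(self.n, self.n))
        dist = dijkstra(graph, directed=False, indices=from_idx)
        if len(self._cache) > 32:
            self._cache.clear()
        self._cache[key] = dist
        return dist


def least_cost_distances(
    mask: MaskGrid,
    conductance: ConductanceModel,
    from_points: np.ndarray,
    to_points: np.ndarray,
) -> np.ndarray:
    """Least-cost-path distances (m) between point sets snapped to the mask.

    Returns a ``(len(from_points), len(to_points))`` matrix.  With
    ``conductance.coefficient == 0`` every edge weight equals its Euclidean
    step length, so this is the 8- (or 4-) neighbour grid metric.
    Disconnected pairs return +inf with a warning.
    """
    engine = LeastCostEngine(mask, conductance.covariate if conductance.covariate else None,
                             conductance.neighbourhood)
    from_idx = mask.snap(from_points)
    to_idx = mask.snap(to_points)
    full = engine.distances(conductance.coefficient, from_idx)
    out = full[:, to_idx]
    if np.isinf(out).any():
        warnings.warn("some from/to pixel pairs are disconnected on the mask; returning +inf")
    return out
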