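"""Synthetic study generator: landscape, population, detections, surveys.

Every input the analysis chain consumes can be generated here with the
statistical structure the models assume: smooth spatially autocorrelated
covariate fields over a ~50×50 km planar grid, activity centres from a
log-linear inhomogeneous Poisson process, Poisson count detections whose
rate declines (half-normally) with least-cost distance, and two-observer
group sightings with independent per-observer detection probabilities.

Default field ranges emulate the motivating Trans-Himalayan study area
(altitude ~3,300–5,500 m, wild prey 0.01–0.58 animals/km², livestock
densities up to ~11–14 head/km²), and the default structural truth uses the
study's headline estimates (standardized wild-prey density slope 0.61,
conductance coefficient 0.36 on altitude, two-camera encounter effect 0.56,
80-day session).  One global seed spawns per-component child seeds via
``numpy.random.SeedSequence`` (order: landscape, detectors, population,
detections, double-observer), so each component is independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .captures import CaptureHistory, DetectionEvent, DetectorArray, TOPOGRAPHY_LEVELS
from .double_observer import GroupRecord
from .geomask import (
    LeastCostEngine,
    MaskGrid,
    RasterGrid,
    biomass_surface,
    build_mask,
    moving_window_smooth,
    terrain_ruggedness_index,
)
from .scr_core import ScrModelSpec, ScrParams, detector_design, evaluate_density

__all__ = [
    "SimConfig",
    "FieldSpec",
    "gen_landscape",
    "derive_surfaces",
    "gen_detectors",
    "gen_population",
    "gen_detections",
    "gen_double_observer",
    "simulate_study",
    "SimulatedDetections",
    "SimulatedStudy",
]


@dataclass(frozen=True)
class FieldSpec:
    """Marginal behaviour of one synthetic covariate field: centre value,
    marginal SD of the autocorrelated surface, and hard clip bounds."""

    mid: float
    sd: float
    lo: float
    hi: float


# Field ranges matching the study area's reported covariate summaries.
DEFAULT_FIELDS: dict[str, FieldSpec] = {
    "DEM": FieldSpec(mid=4400.0, sd=500.0, lo=3298.0, hi=5500.0),
    "WildPrey": FieldSpec(mid=0.25, sd=0.18, lo=0.01, hi=0.58),
    "SmallLivestock": FieldSpec(mid=1.0, sd=1.75, lo=0.0, hi=11.39),
    "LargeLivestock": FieldSpec(mid=1.4, sd=2.2, lo=0.0, hi=14.11),
    "SettlementDistance": FieldSpec(mid=600.0, sd=415.0, lo=1.21, hi=1580.82),
}


@dataclass
class SimConfig:
    """Everything that defines one synthetic study, keyed by a single seed."""

    seed: int = 0
    # landscape
    extent_m: float = 50_000.0
    raster_spacing_m: float = 500.0
    smooth_scale_m: float = 3_000.0
    fields: Mapping[str, FieldSpec] = field(default_factory=lambda: dict(DEFAULT_FIELDS))
    # mask
    buffer_m: float = 24_000.0
    mask_spacing_m: float = 500.0
    exclude_above_m: float | None = 5_200.0
    # detectors
    n_det_x: int = 6
    n_det_y: int = 5
    det_spacing_m: float = 4_000.0
    n_double_cameras: int = 16
    layout: str = "grid"  # or "biased" (sign-survey-like, prey-weighted)
    session_days: float = 80.0
    # structural truth (link scale)
    density_terms: tuple[str, ...] = ("WildPrey",)
    theta0: float = math.log(0.005)        # 0.5 animals / 100 km²
    theta_slopes: tuple[float, ...] = (0.61,)
    lambda0_terms: tuple[str, ...] = ("Topo", "Cameras")
    phi0: float = -2.55
    phi_slopes: tuple[float, ...] = (0.44, 0.74, 0.56)  # gully bed, ridgeline, two cameras
    beta0: float = 8.75                     # log sigma (m)
    noneuc: str | None = "Altitude"
    alpha: float = 0.36
    # double-observer truth
    block_groups: Mapping[str, int] = field(default_factory=lambda: {
        "Chandertal": 4, "Kibber Plateau": 45, "Dhar Ula": 12, "Dhankar Lalung": 9,
        "Dhar Pangmo": 5, "Guiling": 7, "Lossar Kiato": 10,
    })
    block_areas: Mapping[str, float] = field(default_factory=lambda: {
        "Chandertal": 768.0, "Kibber Plateau": 1623.0, "Dhar Ula": 578.0,
        "Dhankar Lalung": 513.0, "Dhar Pangmo": 1423.0, "Guiling": 346.0,
        "Lossar Kiato": 1117.0,
    })
    mean_group_size: float = 14.0
    p1: float = 0.92
    p2: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.p1 <= 1 and 0 < self.p2 <= 1):
            raise ValueError("observer detection probabilities must be in (0, 1]")
        if len(self.theta_slopes) != len(self.density_terms):
            raise ValueError("theta_slopes must match density_terms")

    def child_rngs(self) -> dict[str, np.random.Generator]:
        ss = np.random.SeedSequence(self.seed)
        names = ["landscape", "detectors", "population", "detections", "double_observer"]
        return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}

    def true_spec(self) -> ScrModelSpec:
        return ScrModelSpec(density=self.density_terms, lambda0=self.lambda0_terms,
                            sigma=(), noneuc=self.noneuc)

    def true_params(self) -> ScrParams:
        return ScrParams(
            theta=np.concatenate([[self.theta0], self.theta_slopes]),
            phi=np.concatenate([[self.phi0], self.phi_slopes]),
            beta=np.array([self.beta0]),
            alpha=self.alpha if self.noneuc else None,
        )

    @classmethod
    def scaled_down(cls, seed: int = 0) -> "SimConfig":
        """A desk-scale study: 25 detectors at 6 km spacing, sigma ≈ 2.5 km
        with a 4-sigma (10 km) buffer, ~1,400-pixel mask at 1.2 km spacing,
        and a density intercept giving ≈ 20 detected individuals — the same
        structural truth at a size a laptop can replicate many times."""
        return cls(
            seed=seed,
            extent_m=46_000.0, raster_spacing_m=1_000.0, smooth_scale_m=6_000.0,
            buffer_m=10_000.0, mask_spacing_m=1_200.0, exclude_above_m=None,
            n_det_x=5, n_det_y=5, det_spacing_m=6_000.0, n_double_cameras=13,
            theta0=math.log(0.015),
            lambda0_terms=("Cameras",), phi_slopes=(0.56,),
            beta0=7.82,
        )


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def _smooth_field(shape, spacing, scale, spec: FieldSpec, rng) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if scale / spacing >= 2 * max(shape):
        # correlation length beyond the grid: the constant-field limit
        return np.full(shape, spec.mid)
    smoothed = gaussian_filter(noise, sigma=max(scale / spacing, 1e-9), mode="reflect")
    sd = smoothed.std()
    if sd < 1e-8:
        return np.full(shape, spec.mid)
    z = (smoothed - smoothed.mean()) / sd
    return np.clip(spec.mid + spec.sd * z, spec.lo, spec.hi)


def gen_landscape(config: SimConfig, rng: np.random.Generator | None = None) -> dict[str, RasterGrid]:
    """Smooth autocorrelated covariate rasters (kernel-smoothed Gaussian
    noise, affinely scaled and clipped into realistic ranges)."""
    if rng is None:
        rng = config.child_rngs()["landscape"]
    n = int(round(config.extent_m / config.raster_spacing_m))
    out = {}
    for name, spec in config.fields.items():
        vals = _smooth_field((n, n), config.raster_spacing_m, config.smooth_scale_m, spec, rng)
        out[name] = RasterGrid(0.0, 0.0, config.raster_spacing_m, vals)
    return out


def derive_surfaces(rasters: dict[str, RasterGrid]) -> dict[str, RasterGrid]:
    """Derived covariates the density model uses: terrain ruggedness
    (smoothed over 1.5 km, like livestock densities), a 5 km-smoothed wild
    prey surface, and livestock biomass; DEM is re-exposed as Altitude."""
    out = dict(rasters)
    out["Altitude"] = rasters["DEM"]
    tri = terrain_ruggedness_index(rasters["DEM"])
    out["Ruggedness"] = moving_window_smooth(tri, 1_500.0) if tri.spacing <= 1_500.0 else tri
    sm = rasters["SmallLivestock"]
    lg = rasters["LargeLivestock"]
    if sm.spacing <= 1_500.0:
        sm = moving_window_smooth(sm, 1_500.0)
        lg = moving_window_smooth(lg, 1_500.0)
    out["SmallLivestock"], out["LargeLivestock"] = sm, lg
    out["LSBiomass"] = biomass_surface(sm, lg)
    prey = rasters["WildPrey"]
    if prey.spacing <= 5_000.0:
        prey = moving_window_smooth(prey, 5_000.0)
    out["WildPrey"] = prey
    return out


# ---------------------------------------------------------------------------
# Detectors and population
# ---------------------------------------------------------------------------

def gen_detectors(config: SimConfig, rng: np.random.Generator | None = None,
                  rasters: dict[str, RasterGrid] | None = None) -> DetectorArray:
    """Detector layout: a centred grid, or a prey-weighted ("biased",
    sign-survey-like) random placement; a random subset gets two cameras and
    each site a random topography class."""
    if rng is None:
        rng = config.child_rngs()["detectors"]
    n = config.n_det_x * config.n_det_y
    cx = cy = config.extent_m / 2
    if config.layout == "grid":
        xs = cx + (np.arange(config.n_det_x) - (config.n_det_x - 1) / 2) * config.det_spacing_m
        ys = cy + (np.arange(config.n_det_y) - (config.n_det_y - 1) / 2) * config.det_spacing_m
        xx, yy = np.meshgrid(xs, ys)
        xy = np.column_stack([xx.ravel(), yy.ravel()])
    elif config.layout == "biased":
        if rasters is None or "WildPrey" not in rasters:
            raise ValueError("biased layout needs a WildPrey raster")
        grid = rasters["WildPrey"]
        gx, gy = grid.cell_centers()
        z = grid.values.ravel()
        w = np.exp((z - z.mean()) / (z.std() or 1.0))
        pick = rng.choice(len(gx), size=n, replace=False, p=w / w.sum())
        xy = np.column_stack([gx[pick], gy[pick]])
    else:
        raise ValueError("layout must be 'grid' or 'biased'")
    double = np.zeros(n, dtype=int)
    double[rng.choice(n, size=min(config.n_double_cameras, n), replace=False)] = 1
    topo = rng.choice(TOPOGRAPHY_LEVELS, size=n)
    return DetectorArray.from_arrays(
        ids=[f"T{i + 1:02d}" for i in range(n)],
        x=xy[:, 0], y=xy[:, 1],
        effort_days=np.full(n, config.session_days),
        n_cameras=1 + double, topography=topo,
    )


def gen_population(mask: MaskGrid, density, rng: np.random.Generator) -> np.ndarray:
    """Activity centres from an inhomogeneous Poisson process: per-pixel
    counts ~ Poisson(D(s)·a), positions uniform within each pixel.
    ``density`` is animals/km², scalar or per-pixel."""
    density = np.broadcast_to(np.asarray(density, dtype=float), (mask.n_pixels,))
    if not np.all(np.isfinite(density)):
        raise ValueError("densities must be finite")
    counts = rng.poisson(density * mask.area_per_pixel)
    centres = []
    half = mask.spacing / 2
    for px, k in zip(range(mask.n_pixels), counts):
        if k:
            offs = rng.uniform(-half, half, size=(k, 2))
            centres.append(mask.centers[px] + offs)
    if not centres:
        return np.empty((0, 2))
    return np.vstack(centres)


# ---------------------------------------------------------------------------
# Detections
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDetections:
    """Raw events, the count capture history of detected animals, and the
    full ground truth (counts for every simulated animal, detected or not)."""

    events: list[DetectionEvent]
    history: CaptureHistory
    y_full: np.ndarray        # (n_animals, K) including never-detected rows
    detected: np.ndarray      # boolean per animal
    ids: list[str]


def gen_detections(
    centres: np.ndarray,
    detectors: DetectorArray,
    params: ScrParams,
    spec: ScrModelSpec,
    session_days: float,
    rng: np.random.Generator,
    mask: MaskGrid | None = None,
    start: str = "2011-10-15T00:00:00",
) -> SimulatedDetections:
    """Poisson count detections under the half-normal encounter model, on
    Euclidean or least-cost distance per ``spec``.  Event timestamps are
    uniform over the session, so raw events may fall closer together than
    any independence window — downstream filtering is part of the test
    surface.  The returned history contains only detected animals; the full
    count matrix is kept as ground truth."""
    centres = np.asarray(centres, dtype=float).reshape(-1, 2)
    k_det = len(detectors)
    X_l, _ = detector_design(detectors, spec.lambda0, spec.standardize)
    X_s, _ = detector_design(detectors, spec.sigma, spec.standardize)
    lam0 = np.exp(X_l @ params.phi)
    sig = np.exp(X_s @ params.beta)
    if len(centres) == 0:
        y = np.zeros((0, k_det), dtype=int)
    else:
        if spec.noneuc is not None:
            if mask is None:
                raise ValueError("least-cost detections need the mask")
            engine = LeastCostEngine(mask, spec.noneuc)
            det_idx = mask.snap(detectors.xy)
            d = engine.distances(params.alpha or 0.0, det_idx)[:, mask.snap(centres)]
        else:
            diff = detectors.xy[:, None, :] - centres[None, :, :]
            d = np.sqrt((diff**2).sum(axis=2))
        mu = detectors.effort[:, None] * lam0[:, None] * np.exp(-(d**2) / (2 * sig[:, None] ** 2))
        y = rng.poisson(np.where(np.isfinite(mu), mu, 0.0)).T  # (n_animals, K)
    ids = [f"A{i + 1:03d}" for i in range(len(centres))]
    t0 = pd.Timestamp(start)
    events: list[DetectionEvent] = []
    det_ids = detectors.ids
    effort = detectors.effort
    for i in range(y.shape[0]):
        for k in np.nonzero(y[i])[0]:
            offsets = np.sort(rng.uniform(0, effort[k] * 24 * 3600, size=y[i, k]))
            for off in offsets:
                events.append(DetectionEvent(ids[i], det_ids[k], t0 + pd.Timedelta(seconds=float(off))))
    detected = y.sum(axis=1) > 0
    hist = CaptureHistory(
        y=pd.DataFrame(y[detected], index=[ids[i] for i in np.nonzero(detected)[0]], columns=det_ids),
        session_days=session_days,
    )
    return SimulatedDetections(events=events, history=hist, y_full=y, detected=detected, ids=ids)


# ---------------------------------------------------------------------------
# Double-observer survey
# ---------------------------------------------------------------------------

def gen_double_observer(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[GroupRecord], dict]:
    """Two-observer group sightings with independent per-observer detection.

    Per block, the true number of groups is fixed by the config; group
    sizes are 1 + Poisson(mean − 1); each observer sees each group
    independently with probability p1 / p2; groups missed by both are
    excluded from the records but counted in the returned truth."""
    if rng is None:
        rng = config.child_rngs()["double_observer"]
    records: list[GroupRecord] = []
    truth = {"groups_per_block": dict(config.block_groups), "total_groups": 0, "total_animals": 0}
    for block, g in config.block_groups.items():
        sizes = 1 + rng.poisson(max(config.mean_group_size - 1, 0), size=g)
        seen1 = rng.random(g) < config.p1
        seen2 = rng.random(g) < config.p2
        truth["total_groups"] += int(g)
        truth["total_animals"] += int(sizes.sum())
        for s, a, b in zip(sizes, seen1, seen2):
            if a or b:
                records.append(GroupRecord("wild prey", block, int(s), bool(a), bool(b)))
    return records, truth


# ---------------------------------------------------------------------------
# Whole-study bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimConfig
    rasters: dict[str, RasterGrid]
    detectors: DetectorArray
    mask: MaskGrid
    centres: np.ndarray
    detections: SimulatedDetections
    dobs_records: list[GroupRecord]
    dobs_truth: dict

    @property
    def true_n(self) -> int:
        return len(self.centres)


def simulate_study(config: SimConfig, with_double_observer: bool = True) -> SimulatedStudy:
    """Generate one complete synthetic study: landscape, detectors, habitat
    mask with covariates, activity centres, camera-trap detections and
    (optionally) the double-observer prey survey."""
    rngs = config.child_rngs()
    rasters = derive_surfaces(gen_landscape(config, rngs["landscape"]))
    detectors = gen_detectors(config, rngs["detectors"], rasters)
    mask_covs = {"Altitude": rasters["Altitude"], "WildPrey": rasters["WildPrey"],
                 "Ruggedness": rasters["Ruggedness"], "LSBiomass": rasters["LSBiomass"],
                 "SmallLivestock": rasters["SmallLivestock"],
                 "LargeLivestock": rasters["LargeLivestock"],
                 "SettlementDistance": rasters["SettlementDistance"]}
    exclusion = f"Altitude > {config.exclude_above_m}" if config.exclude_above_m else None
    mask = build_mask(detectors, config.buffer_m, config.mask_spacing_m,
                      exclusion=exclusion, rasters=mask_covs)
    density = evaluate_density(mask, config.true_spec(), config.true_params().theta)
    centres = gen_population(mask, density, rngs["population"])
    detections = gen_detections(
        centres, detectors, config.true_params(), config.true_spec(),
        config.session_days, rngs["detections"], mask=mask,
    )
    if with_double_observer:
        records, truth = gen_double_observer(config, rngs["double_observer"])
    else:
        records, truth = [], {}
    return SimulatedStudy(config=config, rasters=rasters, detectors=detectors,
                          mask=mask, centres=centres, detections=detections,
                          dobs_records=records, dobs_truth=truth)
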