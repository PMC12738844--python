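"""Synthetic desk-scale scenarios: footprints, labels, hazard, admin units.

Every other module is testable against these generators without external
data.  Buildings are rectangles and L-shapes placed around class-specific
cluster centres, with class-specific area, elongation and shape-complexity
distributions so that the morphology feature families statistically
separate the eight use types -- mimicking the real-world regularity that
land use is spatially clustered and morphologically distinctive.  Floor
counts are drawn from class-conditional distributions (residential skewed
to one or two floors, commercial taller).  Realism is secondary to
statistical controllability: geometry is valid by construction.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import voronoi_diagram
from shapely import affinity

from .engine import BuildingRecord
from .geometry import Footprint
from .models import USE_TYPES
from .occupancy import OccupancySpec
from .projection import ProjectionPolicy
from .raster import GridSpec, QuantileRaster


@dataclass(frozen=True)
class ClassArchetype:
    """Morphology and floor-count parameters for one use type."""

    area_logmean: float            # ln(sqft)
    area_logsd: float
    aspect: tuple[float, float]    # elongation range (>= 1)
    l_shape_prob: float
    n_clusters: int
    cluster_sd_ft: float
    floors: dict[int, float]


#: Default archetypes.  Areas, elongations, shape complexity and clustering
#: are deliberately distinctive per class; floor distributions follow the
#: premise that residential structures typically have one to two floors
#: while commercial and institutional stock builds taller.
DEFAULT_ARCHETYPES: dict[str, ClassArchetype] = {
    "Residential": ClassArchetype(math.log(900), 0.25, (1.0, 1.5), 0.15, 12, 400.0,
                                  {1: 0.55, 2: 0.40, 3: 0.05}),
    "Institutional": ClassArchetype(math.log(16000), 0.30, (1.0, 1.5), 0.60, 5, 700.0,
                                    {1: 0.25, 2: 0.40, 3: 0.25, 4: 0.10}),
    "Retail": ClassArchetype(math.log(2600), 0.25, (1.5, 2.5), 0.05, 4, 300.0,
                             {1: 0.70, 2: 0.30}),
    "Commercial": ClassArchetype(math.log(7000), 0.30, (1.0, 2.0), 0.30, 3, 500.0,
                                 {2: 0.20, 3: 0.30, 4: 0.25, 5: 0.15, 6: 0.10}),
    "Transportation": ClassArchetype(math.log(30000), 0.35, (4.0, 8.0), 0.0, 5, 1600.0,
                                     {1: 0.90, 2: 0.10}),
    "Military": ClassArchetype(math.log(12000), 0.30, (2.5, 3.5), 0.0, 3, 900.0,
                               {1: 0.60, 2: 0.30, 3: 0.10}),
    "Recreation": ClassArchetype(math.log(45000), 0.30, (1.0, 1.2), 0.0, 6, 1500.0,
                                 {1: 1.0}),
    "Agriculture": ClassArchetype(math.log(5000), 0.30, (3.0, 4.0), 0.0, 6, 1200.0,
                                  {1: 1.0}),
}

DEFAULT_CLASS_MIX: dict[str, float] = {
    "Residential": 0.60, "Institutional": 0.07, "Retail": 0.06,
    "Commercial": 0.09, "Transportation": 0.04, "Military": 0.03,
    "Recreation": 0.05, "Agriculture": 0.06,
}

#: Facility-level Beta occupancy specs (people per 1000 ft^2) per broad use
#: type and time period.  Residential night rates exceed day rates;
#: workplaces and venues peak by day.
DEFAULT_CATALOGUE_ROWS: list[tuple[str, str, str, float, float, float]] = [
    # facility_type, use_type, period, alpha, beta, o_max
    ("single_family", "Residential", "day", 2.0, 6.0, 6.0),
    ("multi_family", "Residential", "day", 2.5, 5.0, 8.0),
    ("single_family", "Residential", "night", 4.0, 4.0, 6.0),
    ("multi_family", "Residential", "night", 5.0, 3.5, 8.0),
    ("school", "Institutional", "day", 3.0, 4.0, 20.0),
    ("clinic", "Institutional", "day", 2.5, 5.0, 14.0),
    ("school", "Institutional", "night", 1.2, 10.0, 20.0),
    ("clinic", "Institutional", "night", 1.5, 8.0, 14.0),
    ("shop", "Retail", "day", 2.0, 5.0, 15.0),
    ("market_hall", "Retail", "day", 2.5, 4.0, 25.0),
    ("shop", "Retail", "night", 1.2, 12.0, 15.0),
    ("market_hall", "Retail", "night", 1.2, 12.0, 25.0),
    ("office", "Commercial", "day", 3.0, 4.5, 12.0),
    ("hotel", "Commercial", "day", 2.0, 6.0, 10.0),
    ("office", "Commercial", "night", 1.2, 12.0, 12.0),
    ("hotel", "Commercial", "night", 3.0, 5.0, 10.0),
    ("terminal", "Transportation", "day", 2.0, 6.0, 18.0),
    ("depot", "Transportation", "day", 1.5, 8.0, 8.0),
    ("terminal", "Transportation", "night", 1.2, 10.0, 18.0),
    ("depot", "Transportation", "night", 1.1, 12.0, 8.0),
    ("barracks", "Military", "day", 2.5, 5.0, 9.0),
    ("barracks", "Military", "night", 4.0, 4.0, 9.0),
    ("sports_hall", "Recreation", "day", 1.8, 6.0, 20.0),
    ("sports_hall", "Recreation", "night", 1.2, 10.0, 20.0),
    ("storage_barn", "Agriculture", "day", 1.3, 10.0, 3.0),
    ("storage_barn", "Agriculture", "night", 1.1, 14.0, 3.0),
]


@dataclass
class ScenarioConfig:
    """Everything that defines a synthetic study area."""

    seed: int = 0
    lon_min: float = 121.000
    lat_min: float = 14.000
    lon_max: float = 121.050
    lat_max: float = 14.050
    n_buildings: int = 2000
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    archetypes: dict[str, ClassArchetype] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    n_admin_units: int = 30
    total_population: float = 100_000.0
    hazard_smooth_cells: float = 6.0
    hazard_breaks: tuple[float, float] = (0.5, 0.8)  # area quantiles low|mod|high

    def __post_init__(self) -> None:
        if self.n_buildings < 1:
            raise ValueError("need at least one building")
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"class mix sums to {total}, not 1")
        unknown = set(self.class_mix) - set(USE_TYPES)
        if unknown:
            raise ValueError(f"unknown use types in class mix: {sorted(unknown)}")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.lon_min, self.lat_min, self.lon_max, self.lat_max)

    @property
    def projection(self) -> ProjectionPolicy:
        return ProjectionPolicy.for_bounds(*self.extent)


def _footprint_polygon(
    rng: np.random.Generator,
    cx: float, cy: float,
    area: float, aspect: float, l_shape: bool,
) -> Polygon:
    """Axis-aligned rectangle or L-shape of given area, randomly rotated."""
    w = math.sqrt(area * aspect)
    h = area / w
    if l_shape:
        # carve a corner notch of ~35% of each side; rescale to target area
        nx, ny = 0.35 * w, 0.35 * h
        poly = Polygon([
            (0, 0), (w, 0), (w, h - ny), (w - nx, h - ny), (w - nx, h), (0, h)
        ])
        poly = affinity.scale(poly, math.sqrt(area / poly.area),
                              math.sqrt(area / poly.area), origin=(0, 0))
    else:
        poly = Polygon([(0, 0), (w, 0), (w, h), (0, h)])
    poly = affinity.rotate(poly, rng.uniform(0, 180), origin="centroid")
    c = poly.centroid
    return affinity.translate(poly, cx - c.x, cy - c.y)


class _SeparationHash:
    """Grid-hash rejection of centroids closer than a per-pair separation."""

    def __init__(self, cell_ft: float):
        self.cell = cell_ft
        self.points: list[tuple[float, float, float]] = []  # x, y, radius
        self.buckets: dict[tuple[int, int], list[int]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(x // self.cell), int(y // self.cell))

    def ok(self, x: float, y: float, radius: float) -> bool:
        kx, ky = self._key(x, y)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for i in self.buckets.get((kx + dx, ky + dy), ()):
                    px, py, pr = self.points[i]
                    if (px - x) ** 2 + (py - y) ** 2 < (0.7 * (radius + pr)) ** 2:
                        return False
        return True

    def add(self, x: float, y: float, radius: float) -> None:
        self.points.append((x, y, radius))
        self.buckets.setdefault(self._key(x, y), []).append(len(self.points) - 1)


def generate_buildings(
    cfg: ScenarioConfig,
) -> tuple[list[BuildingRecord], pd.DataFrame]:
    """Clustered, labelled footprints with ground-truth use type and floors.

    Returns the building records (footprints in geographic coordinates,
    area in sqft, known attributes left unset) and a ground-truth table
    indexed by building id with ``use_type``, ``floors`` and ``area_sqft``.
    """
    rng = np.random.default_rng(cfg.seed)
    policy = cfg.projection
    x_min, y_min = policy.to_feet(cfg.lon_min, cfg.lat_min)
    x_max, y_max = policy.to_feet(cfg.lon_max, cfg.lat_max)
    margin = 150.0  # keep footprints inside the extent
    classes = sorted(cfg.class_mix)
    counts = rng.multinomial(
        cfg.n_buildings, [cfg.class_mix[c] for c in classes]
    )

    cluster_centers = {
        c: np.column_stack([
            rng.uniform(x_min + margin, x_max - margin, cfg.archetypes[c].n_clusters),
            rng.uniform(y_min + margin, y_max - margin, cfg.archetypes[c].n_clusters),
        ])
        for c in classes
    }

    sep = _SeparationHash(cell_ft=500.0)
    records: list[BuildingRecord] = []
    truth_rows = []
    bid = 0
    failures = 0
    for cls, n_cls in zip(classes, counts):
        arch = cfg.archetypes[cls]
        floors_vals = np.array(sorted(arch.floors))
        floors_p = np.array([arch.floors[f] for f in floors_vals], dtype=float)
        for _ in range(n_cls):
            placed = False
            for _attempt in range(60):
                centre = cluster_centers[cls][rng.integers(arch.n_clusters)]
                x = centre[0] + rng.normal(0, arch.cluster_sd_ft)
                y = centre[1] + rng.normal(0, arch.cluster_sd_ft)
                if not (x_min + margin < x < x_max - margin
                        and y_min + margin < y < y_max - margin):
                    continue
                area = float(rng.lognormal(arch.area_logmean, arch.area_logsd))
                radius = math.sqrt(area) * 0.8
                if not sep.ok(x, y, radius):
                    continue
                aspect = rng.uniform(*arch.aspect)
                l_shape = rng.random() < arch.l_shape_prob
                poly_ft = _footprint_polygon(rng, x, y, area, aspect, l_shape)
                bx0, by0, bx1, by1 = poly_ft.bounds
                if bx0 <= x_min or by0 <= y_min or bx1 >= x_max or by1 >= y_max:
                    continue  # rotated footprint would poke past the extent
                sep.add(x, y, radius)
                placed = True
                break
            if not placed:
                failures += 1
                continue
            coords = np.asarray(poly_ft.exterior.coords)
            lon, lat = policy.to_geographic(coords[:, 0], coords[:, 1])
            geom = Polygon(np.column_stack([lon, lat]))
            floors = int(rng.choice(floors_vals, p=floors_p))
            fp = Footprint(id=f"b{bid:06d}", geometry=geom, source="synthetic")
            records.append(
                BuildingRecord(footprint=fp, area_sqft=area)
            )
            truth_rows.append(
                {"id": fp.id, "use_type": cls, "floors": floors, "area_sqft": area}
            )
            bid += 1
    if failures > 0.05 * cfg.n_buildings:
        raise RuntimeError(
            f"infeasible building density: {failures} placements failed; "
            "reduce n_buildings or enlarge the extent"
        )
    truth = pd.DataFrame(truth_rows).set_index("id")
    return records, truth


def generate_hazard(cfg: ScenarioConfig, grid: Optional[GridSpec] = None) -> QuantileRaster:
    """Spatially autocorrelated 3-class susceptibility raster (0.33/0.66/1.0)."""
    if grid is None:
        grid = GridSpec.from_extent(*cfg.extent)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    field_ = gaussian_filter(
        rng.normal(size=grid.shape), sigma=cfg.hazard_smooth_cells, mode="wrap"
    )
    lo, hi = np.quantile(field_, cfg.hazard_breaks)
    risk = np.where(field_ >= hi, 1.00, np.where(field_ >= lo, 0.66, 0.33))
    return QuantileRaster(grid=grid, bands={"risk": risk})


def generate_admin_units(cfg: ScenarioConfig) -> list[tuple[str, Polygon]]:
    """Voronoi partition of random seed points, clipped to the extent."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    extent_poly = box(*[cfg.extent[i] for i in (0, 1, 2, 3)])
    if cfg.n_admin_units == 1:
        return [("u000", extent_poly)]
    pts = MultiPoint([
        (rng.uniform(cfg.lon_min, cfg.lon_max), rng.uniform(cfg.lat_min, cfg.lat_max))
        for _ in range(cfg.n_admin_units)
    ])
    cells = voronoi_diagram(pts, envelope=extent_poly)
    units = []
    # map each seed to its containing Voronoi cell for a stable id order
    for i, pt in enumerate(pts.geoms):
        for cell in cells.geoms:
            if cell.contains(pt):
                units.append((f"u{i:03d}", cell.intersection(extent_poly)))
                break
    return units


def generate_occupancy_catalogue(cfg: ScenarioConfig) -> list[OccupancySpec]:
    """Facility-type Beta occupancy specs for all eight use types, day and night."""
    return [
        OccupancySpec(facility_type=ft, use_type=u, time_period=t,
                      alpha=a, beta=b, o_max=om)
        for ft, u, t, a, b, om in DEFAULT_CATALOGUE_ROWS
    ]


@dataclass
class ScenarioBundle:
    """Everything the pipeline consumes, plus retained ground truth."""

    config: ScenarioConfig
    buildings: list[BuildingRecord]
    truth: pd.DataFrame
    catalogue: list[OccupancySpec]
    hazard: QuantileRaster
    admin_units: list[tuple[str, Polygon]]
    grid: GridSpec
    total_population: float


def end_to_end_fixture(cfg: ScenarioConfig) -> ScenarioBundle:
    """One call yields buildings, occupancy catalogue, hazard and admin units."""
    grid = GridSpec.from_extent(*cfg.extent)
    buildings, truth = generate_buildings(cfg)
    return ScenarioBundle(
        config=cfg,
        buildings=buildings,
        truth=truth,
        catalogue=generate_occupancy_catalogue(cfg),
        hazard=generate_hazard(cfg, grid),
        admin_units=generate_admin_units(cfg),
        grid=grid,
        total_population=cfg.total_population,
    )
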