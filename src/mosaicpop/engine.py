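"""Building-level population estimation and gridding.

Two estimators share one algebra: population of a building is floor area
times floor count times occupancy per 1000 ft^2, averaged over time
periods, calibrated so the regional sum matches an authoritative total,
then split across 3-arc-second grid cells in proportion to footprint area
("molecules").

* The deterministic baseline fixes every input: known or default use type
  (residential) and floor count (between one and two), and the median
  occupancy rate per category.
* The probabilistic estimator draws use type, floor count (conditional on
  use type) and per-period occupancy rates K times per building, yielding
  an empirical population distribution summarized by its mean and the
  5th/50th/95th percentiles.  One global scaling factor calibrates the
  means to the authoritative total and is applied to all quantiles alike,
  preserving relative uncertainty.

Per-building random substreams are derived from (master seed, building id)
so results do not depend on iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .geometry import Footprint
from .models import FloorDistribution, JointAttributeTable, UseTypeDistribution
from .occupancy import OccupancyPool
from .raster import GridSpec, QuantileRaster

QUANTILES = (0.05, 0.50, 0.95)

#: Default floor-count assumption when labels are missing (the alternative
#: convention of 2 floors is also in circulation; both are supported).
DEFAULT_FLOORS = 1.5

DEFAULT_USE = "Residential"


@dataclass(frozen=True)
class TimeWeighting:
    """Named time periods and their nonnegative averaging weights."""

    periods: tuple[str, ...] = ("day", "night")
    weights: tuple[float, ...] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.periods) != len(self.weights):
            raise ValueError("periods and weights must align")
        if any(w < 0 for w in self.weights) or sum(self.weights) <= 0:
            raise ValueError("weights must be nonnegative with a positive sum")

    @property
    def normalized(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()


@dataclass
class BuildingRecord:
    """A footprint plus whatever attribute knowledge exists for it."""

    footprint: Footprint
    area_sqft: float
    known_use: Optional[str] = None
    known_floors: Optional[int] = None
    use_dist: Optional[UseTypeDistribution] = None
    floor_dist: Optional[FloorDistribution] = None
    joint: Optional[JointAttributeTable] = None

    def __post_init__(self) -> None:
        if self.area_sqft <= 0:
            raise ValueError(f"building {self.footprint.id!r}: nonpositive area")
        if self.known_floors is not None and self.known_floors < 1:
            raise ValueError(f"building {self.footprint.id!r}: floors must be >= 1")

    @property
    def id(self):
        return self.footprint.id


@dataclass
class BuildingDraws:
    """Monte Carlo population draws for one building."""

    building_id: object
    draws: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if np.any(self.draws < 0):
            raise ValueError("population draws must be nonnegative")

    @property
    def K(self) -> int:
        return len(self.draws)


@dataclass
class BuildingEstimate:
    """Summary of a building's population distribution."""

    building_id: object
    mean: float
    p05: float
    p50: float
    p95: float
    calibrated: bool = False
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.p05 <= self.p50 + 1e-12 and self.p50 <= self.p95 + 1e-12):
            raise ValueError("quantiles must be monotone: p05 <= p50 <= p95")
        if self.mean < 0:
            raise ValueError("mean must be nonnegative")

    def quantile(self, q: float) -> float:
        return {0.05: self.p05, 0.50: self.p50, 0.95: self.p95}[q]


@dataclass(frozen=True)
class MoleculeShare:
    """Fraction of one building's footprint area falling in one grid cell."""

    building_id: object
    cell: tuple[int, int]
    share: float


def _building_substream(master_seed: int, building_id) -> np.random.Generator:
    # stable per-building stream independent of iteration order
    tag = zlib.crc32(str(building_id).encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))


# ---------------------------------------------------------------------------
# Deterministic baseline
# ---------------------------------------------------------------------------

def lshd_estimate(
    record: BuildingRecord,
    catalogue: Mapping[tuple[str, str], float],
    tw: TimeWeighting = TimeWeighting(),
    default_use: str = DEFAULT_USE,
    default_floors: float = DEFAULT_FLOORS,
) -> float:
    """Preliminary deterministic estimate A * F * O/1000, time-averaged.

    ``catalogue`` maps (use type, time period) to the representative median
    occupancy rate (people per 1000 ft^2).
    """
    use = record.known_use if record.known_use is not None else default_use
    floors = record.known_floors if record.known_floors is not None else default_floors
    w = tw.normalized
    est = 0.0
    for wi, period in zip(w, tw.periods):
        key = (use, period)
        if key not in catalogue:
            raise KeyError(f"no occupancy rate for use type {use!r}, period {period!r}")
        est += wi * record.area_sqft * floors * catalogue[key] / 1000.0
    return est


# ---------------------------------------------------------------------------
# Monte Carlo estimator
# ---------------------------------------------------------------------------

def lsm_simulate(
    record: BuildingRecord,
    table: JointAttributeTable,
    pools: Mapping[tuple[str, str], OccupancyPool],
    tw: TimeWeighting = TimeWeighting(),
    K: int = 10_000,
    seed: int = 0,
) -> BuildingDraws:
    """K Monte Carlo population draws for one building.

    Each draw samples a use type from the marginal, a floor count from the
    conditional given that use type, and an occupancy rate per time period
    from the matching broad-category pool, then computes the time-weighted
    population A * f * o / 1000.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    marg = table.use_marginal
    active = np.where(marg > 0)[0]
    for i in active:
        u = table.use_types[i]
        for period in tw.periods:
            if (u, period) not in pools:
                raise KeyError(
                    f"no occupancy pool for use type {u!r}, period {period!r}"
                )

    rng = _building_substream(seed, record.id)
    w = tw.normalized

    u_idx = rng.choice(len(marg), size=K, p=marg / marg.sum())
    floors = np.empty(K)
    pop = np.zeros(K)
    for i in np.unique(u_idx):
        mask = u_idx == i
        m = int(mask.sum())
        cond = table.conditional[i]
        floors[mask] = rng.choice(table.floors, size=m, p=cond / cond.sum())
    for wi, period in zip(w, tw.periods):
        occ = np.empty(K)
        for i in np.unique(u_idx):
            mask = u_idx == i
            pool = pools[(table.use_types[i], period)]
            occ[mask] = rng.choice(pool.samples, size=int(mask.sum()), replace=True)
        pop += wi * record.area_sqft * floors * occ / 1000.0
    return BuildingDraws(building_id=record.id, draws=pop, seed=seed)


def degenerate_table(use_type: str, floors: int) -> JointAttributeTable:
    """Point-mass joint table (one use type, one floor count)."""
    from .models import build_joint_conditional

    return build_joint_conditional(
        UseTypeDistribution({use_type: 1.0}), FloorDistribution({int(floors): 1.0})
    )


def summarize(d: BuildingDraws) -> BuildingEstimate:
    """Mean and 5/50/95 percentiles (linear interpolation of order stats)."""
    q05, q50, q95 = np.quantile(d.draws, QUANTILES, method="linear")
    return BuildingEstimate(
        building_id=d.building_id,
        mean=float(d.draws.mean()),
        p05=float(q05), p50=float(q50), p95=float(q95),
    )


def calibrate(
    estimates: Sequence[BuildingEstimate],
    total_population: float,
    basis: str = "mean",
) -> tuple[list[BuildingEstimate], float]:
    """Scale all means and quantiles by a single factor alpha.

    ``basis`` selects the central estimate whose sum alpha pins to the
    authoritative total: ``"mean"`` (the per-building Monte Carlo mean) or
    ``"median"`` (the per-building P50, so the gridded P50 surface sums to
    the total).  With right-skewed draws the two differ by a few percent;
    both conventions appear in practice and either way the one factor is
    applied to the mean and every quantile, preserving relative spread.
    """
    if total_population <= 0:
        raise ValueError("authoritative total must be positive")
    if basis not in ("mean", "median"):
        raise ValueError("basis must be 'mean' or 'median'")
    total = sum(e.mean if basis == "mean" else e.p50 for e in estimates)
    if total <= 0:
        raise ValueError("cannot calibrate: sum of mean estimates is zero")
    alpha = total_population / total
    out = [
        replace(
            e,
            mean=e.mean * alpha, p05=e.p05 * alpha,
            p50=e.p50 * alpha, p95=e.p95 * alpha,
            calibrated=True, scale=alpha,
        )
        for e in estimates
    ]
    return out, alpha


# ---------------------------------------------------------------------------
# Gridding
# ---------------------------------------------------------------------------

def split_molecules(record: BuildingRecord, grid: GridSpec) -> list[MoleculeShare]:
    """Split a footprint along grid-cell boundaries into area shares.

    Shares are footprint-area fractions; because the working projection is
    affine in (lon, lat), degree-space area ratios equal projected-plane
    ratios exactly, so intersections are evaluated in geographic space.
    """
    geom = record.footprint.geometry
    total = geom.area
    shares: list[MoleculeShare] = []
    for row, col in grid.iter_cells_overlapping(*geom.bounds):
        inter = geom.intersection(grid.cell_polygon(row, col))
        if not inter.is_empty and inter.area > 0:
            shares.append(
                MoleculeShare(record.id, (row, col), inter.area / total)
            )
    if not shares:
        raise ValueError(
            f"building {record.id!r} does not overlap the grid extent"
        )
    s = sum(m.share for m in shares)
    if abs(s - 1.0) > 1e-6:
        # footprint partially outside the grid; renormalizing would hide it
        raise ValueError(
            f"building {record.id!r}: shares sum to {s:.6f}; footprint extends "
            "beyond the grid extent"
        )
    # remove float dust so the per-building shares sum to 1 exactly
    return [replace(m, share=m.share / s) for m in shares]


def aggregate_grid(
    estimates: Sequence[BuildingEstimate],
    molecules: Mapping[object, Sequence[MoleculeShare]],
    grid: GridSpec,
) -> QuantileRaster:
    """Sum area-weighted building quantiles into per-cell raster bands."""
    bands = {
        name: np.zeros(grid.shape)
        for name in ("mean", "p05", "p50", "p95")
    }
    for est in estimates:
        try:
            mols = molecules[est.building_id]
        except KeyError:
            raise KeyError(f"no molecules for building {est.building_id!r}") from None
        for m in mols:
            r, c = m.cell
            bands["mean"][r, c] += m.share * est.mean
            bands["p05"][r, c] += m.share * est.p05
            bands["p50"][r, c] += m.share * est.p50
            bands["p95"][r, c] += m.share * est.p95
    return QuantileRaster(grid=grid, bands=bands)


def confidence_layer(raster: QuantileRaster, rescale: bool = False) -> np.ndarray:
    """Per-cell confidence: 1 - (p95 - p05)/(p95 + p05), in [0, 1].

    Cells with both percentiles zero carry no population and no spread and
    are defined as confidence 1.  ``rescale`` min-max rescales over the
    valid cells for display.
    """
    p05, p95 = raster.band("p05"), raster.band("p95")
    denom = p95 + p05
    conf = np.ones(raster.grid.shape)
    nz = denom > 0
    conf[nz] = 1.0 - (p95[nz] - p05[nz]) / denom[nz]
    conf = np.clip(conf, 0.0, 1.0)
    if rescale:
        lo, hi = conf.min(), conf.max()
        if hi > lo:
            conf = (conf - lo) / (hi - lo)
    return conf
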