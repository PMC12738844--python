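"""High-level orchestration of the estimation pipeline.

Thin compositions of the core modules: build occupancy pools from a
catalogue, attach attribute distributions to buildings (from trained
models, known labels, or defaults), run the Monte Carlo over all
buildings, calibrate, and grid.  The CLI and the reproduction script both
drive these functions.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import (
    BuildingEstimate,
    BuildingRecord,
    TimeWeighting,
    aggregate_grid,
    calibrate,
    confidence_layer,
    degenerate_table,
    lsm_simulate,
    split_molecules,
    summarize,
)
from .models import (
    EnsembleModel,
    build_joint_conditional,
    predict_floor_distribution,
    predict_use_type_distribution,
)
from .occupancy import (
    OccupancyPool,
    OccupancySpec,
    lshd_category_rate,
    pool_broad_category,
)
from .raster import GridSpec, QuantileRaster


def build_pools(
    catalogue: Sequence[OccupancySpec],
    periods: Sequence[str] = ("day", "night"),
    n_per_facility: int = 10_000,
    seed: int = 0,
) -> dict[tuple[str, str], OccupancyPool]:
    """One broad-category occupancy pool per (use type, period)."""
    pools: dict[tuple[str, str], OccupancyPool] = {}
    keys = sorted({(s.use_type, s.time_period) for s in catalogue})
    for i, (u, t) in enumerate(keys):
        if t not in periods:
            continue
        specs = [s for s in catalogue if s.use_type == u and s.time_period == t]
        pools[(u, t)] = pool_broad_category(
            specs, n_per_facility=n_per_facility,
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31),
        )
    return pools


def lshd_catalogue(
    catalogue: Sequence[OccupancySpec],
    periods: Sequence[str] = ("day", "night"),
) -> dict[tuple[str, str], float]:
    """Deterministic median-based rates: mean of subcategory medians."""
    rates: dict[tuple[str, str], float] = {}
    for u, t in sorted({(s.use_type, s.time_period) for s in catalogue}):
        if t not in periods:
            continue
        specs = [s for s in catalogue if s.use_type == u and s.time_period == t]
        rates[(u, t)] = lshd_category_rate(specs)
    return rates


def attach_attribute_distributions(
    buildings: Sequence[BuildingRecord],
    features: Optional[pd.DataFrame] = None,
    usetype_model: Optional[EnsembleModel] = None,
    floor_model: Optional[EnsembleModel] = None,
) -> None:
    """Populate each building's joint (use, floors) table in place.

    Known labels take precedence (point mass); otherwise the trained models
    predict distributions from the feature row; a building with neither
    raises.
    """
    for b in buildings:
        if b.known_use is not None and b.known_floors is not None:
            b.joint = degenerate_table(b.known_use, b.known_floors)
            continue
        if features is None or usetype_model is None or floor_model is None:
            raise ValueError(
                f"building {b.id!r} lacks labels and no models/features supplied"
            )
        row = features.loc[b.id]
        u_dist = (
            predict_use_type_distribution(usetype_model, row)
            if b.known_use is None
            else None
        )
        f_dist = (
            predict_floor_distribution(floor_model, row)
            if b.known_floors is None
            else None
        )
        if u_dist is None:
            from .models import UseTypeDistribution

            u_dist = UseTypeDistribution({b.known_use: 1.0})
        if f_dist is None:
            from .models import FloorDistribution

            f_dist = FloorDistribution({int(b.known_floors): 1.0})
        b.joint = build_joint_conditional(u_dist, f_dist)


def simulate_all(
    buildings: Sequence[BuildingRecord],
    pools: Mapping[tuple[str, str], OccupancyPool],
    tw: TimeWeighting = TimeWeighting(),
    K: int = 10_000,
    seed: int = 0,
    total_population: Optional[float] = None,
) -> tuple[list[BuildingEstimate], float]:
    """Monte Carlo over all buildings; calibrated if a total is given."""
    estimates = []
    for b in buildings:
        if b.joint is None:
            raise ValueError(f"building {b.id!r} has no attribute distributions")
        draws = lsm_simulate(b, b.joint, pools, tw=tw, K=K, seed=seed)
        estimates.append(summarize(draws))
    alpha = 1.0
    if total_population is not None:
        estimates, alpha = calibrate(estimates, total_population)
    return estimates, alpha


def grid_all(
    buildings: Sequence[BuildingRecord],
    estimates: Sequence[BuildingEstimate],
    grid: GridSpec,
) -> QuantileRaster:
    """Molecule split, quantile aggregation, and the confidence band."""
    molecules = {b.id: split_molecules(b, grid) for b in buildings}
    raster = aggregate_grid(estimates, molecules, grid)
    raster.bands["confidence"] = confidence_layer(raster)
    return raster


def estimates_frame(estimates: Sequence[BuildingEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": e.building_id, "mean": e.mean, "p05": e.p05,
                "p50": e.p50, "p95": e.p95, "calibrated": e.calibrated,
                "scale": e.scale,
            }
            for e in estimates
        ]
    ).set_index("id")
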