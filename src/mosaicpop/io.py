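"""Readers and writers: GeoJSON buildings, YAML/CSV occupancy catalogues,
run configuration, and structured run logs.

Vector data travel as GeoJSON (WGS84 by that format's definition); rasters
as ESRI ASCII grids (see :mod:`mosaicpop.raster`).  Occupancy catalogues
are flat tables with columns ``facility_type, use_type, time_period,
alpha, beta, o_max``.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape
import shapely

from .engine import BuildingRecord, TimeWeighting
from .geometry import Footprint
from .occupancy import OccupancySpec
from .projection import ProjectionPolicy, project_geometry
from .raster import read_ascii_grid, write_ascii_grid, write_raster  # re-export

__all__ = [
    "read_buildings", "write_buildings",
    "read_catalogue", "write_catalogue",
    "read_ascii_grid", "write_ascii_grid", "write_raster",
    "RunConfig", "log_event",
]


def read_buildings(path) -> list[BuildingRecord]:
    """Load building records from a GeoJSON polygon layer.

    Optional feature properties ``use_type`` and ``floors`` populate the
    known attributes; missing properties leave them unknown.  Mixed
    geometry types and empty layers are rejected.
    """
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [])
    if not feats:
        raise ValueError(f"{path}: empty layer")
    geoms, props = [], []
    for f in feats:
        g = shape(f["geometry"])
        if g.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(
                f"{path}: mixed/non-polygon geometry ({g.geom_type}); "
                "only polygon layers are supported"
            )
        geoms.append(g)
        props.append(f.get("properties") or {})
    bounds = shapely.total_bounds(geoms)
    policy = ProjectionPolicy.for_bounds(*bounds)
    records = []
    for i, (g, p) in enumerate(zip(geoms, props)):
        fid = p.get("id", f"b{i:06d}")
        fp = Footprint(id=fid, geometry=g, source=p.get("source", str(path)))
        floors = p.get("floors")
        records.append(
            BuildingRecord(
                footprint=fp,
                area_sqft=project_geometry(g, policy).area,
                known_use=p.get("use_type"),
                known_floors=int(floors) if floors is not None else None,
            )
        )
    return records


def write_buildings(
    records: Sequence[BuildingRecord],
    path,
    truth: Optional[pd.DataFrame] = None,
) -> None:
    """Write building records (optionally with ground-truth attributes) as GeoJSON."""
    feats = []
    for r in records:
        props = {"id": str(r.id), "source": r.footprint.source}
        if r.known_use is not None:
            props["use_type"] = r.known_use
        if r.known_floors is not None:
            props["floors"] = int(r.known_floors)
        if truth is not None and r.id in truth.index:
            row = truth.loc[r.id]
            props["use_type"] = str(row["use_type"])
            props["floors"] = int(row["floors"])
        feats.append({
            "type": "Feature",
            "geometry": mapping(r.footprint.geometry),
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_catalogue(specs: Sequence[OccupancySpec], path) -> None:
    """Write an occupancy catalogue as YAML (or CSV if the suffix is .csv)."""
    rows = [
        {
            "facility_type": s.facility_type, "use_type": s.use_type,
            "time_period": s.time_period, "alpha": s.alpha,
            "beta": s.beta, "o_max": s.o_max,
        }
        for s in specs
    ]
    if str(path).endswith(".csv"):
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            yaml.safe_dump({"occupancy": rows}, fh, sort_keys=False)


def read_catalogue(path) -> list[OccupancySpec]:
    if str(path).endswith(".csv"):
        rows = pd.read_csv(path).to_dict("records")
    else:
        with open(path) as fh:
            rows = yaml.safe_load(fh)["occupancy"]
    return [
        OccupancySpec(
            facility_type=str(r["facility_type"]), use_type=str(r["use_type"]),
            time_period=str(r["time_period"]), alpha=float(r["alpha"]),
            beta=float(r["beta"]), o_max=float(r["o_max"]),
        )
        for r in rows
    ]


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    K: int = 10_000
    total_population: float = 100_000.0
    time_periods: tuple[str, ...] = ("day", "night")
    time_weights: tuple[float, ...] = (1.0, 1.0)
    default_floors: float = 1.5
    n_estimators: int = 100
    grid_search: str = "full"     # "full" (80 candidates) or "reduced"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.total_population <= 0:
            raise ValueError("total population must be positive")
        TimeWeighting(self.time_periods, self.time_weights)  # validates
        if self.grid_search not in ("full", "reduced"):
            raise ValueError("grid_search must be 'full' or 'reduced'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in cls.__dataclass_fields__ if k in raw}
        for k in ("time_periods", "time_weights"):
            if k in known:
                known[k] = tuple(known[k])
        return cls(**known)

    def time_weighting(self) -> TimeWeighting:
        return TimeWeighting(self.time_periods, self.time_weights)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def log_event(event: str, config: Optional[RunConfig] = None, stream=None, **extra) -> None:
    """Emit one JSON-lines log record with config hash, seed and version."""
    from . import __version__

    rec = {"event": event, "version": __version__}
    if config is not None:
        rec["config_hash"] = config.config_hash()
        rec["seed"] = config.seed
    rec.update(extra)
    print(json.dumps(rec, default=str), file=stream or sys.stderr)
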