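"""Decision support: uncertainty-weighted adjustment, exposure, ranking.

The adjustment factor turns a cell's (P5, P50, P95) population percentiles
into a single risk-aware estimate.  With

    gamma = 1 - (P95 - P5)/(P95 + P5)        (confidence coefficient)
    phi   = (P95 - P50)/P50                  (upside deviation: undercount)
    delta = (P50 - P5)/P50                   (downside deviation: overcount)
    mu    = phi + delta                      (total fractional spread)
    eta   = (phi - delta)/(mu + eps)         (normalized directional skew)

the factor is

    F = 1 + gamma*(w_u*phi - w_d*delta) + (1 - gamma)*w_sigma*mu*eta,

clamped to a configured range, and the adjusted population is F * P50.
Defaults mirror a conservative flood-planning stance: undercount weight
0.30, overcount weight 0.20, uncertainty weight 0.40, clamp [0.2, 2.5].

Hazard prioritization multiplies a population raster by a numerically
encoded risk raster, averages the composite score over admin units, ranks
units descending, and compares rankings between datasets with Spearman's
rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from shapely import STRtree
from shapely.geometry import Point

from .raster import GridSpec, QuantileRaster

#: Numeric encoding of the low/moderate/high hazard classes.
DEFAULT_RISK_VALUES = {"low": 0.33, "moderate": 0.66, "high": 1.00}


@dataclass(frozen=True)
class AdjustmentConfig:
    """Weights and guards for the uncertainty-weighted adjustment."""

    omega_u: float = 0.30     # undercount (upside) weight
    omega_d: float = 0.20     # overcount (downside) weight
    omega_sigma: float = 0.40  # overall uncertainty-magnitude weight
    epsilon: float = 1e-9
    clamp: tuple[float, float] = (0.2, 2.5)

    def __post_init__(self) -> None:
        if min(self.omega_u, self.omega_d, self.omega_sigma) < 0:
            raise ValueError("weights must be nonnegative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.clamp[0] >= self.clamp[1]:
            raise ValueError("clamp range must satisfy F_min < F_max")


@dataclass
class AdjustmentComponents:
    gamma: float
    phi: float
    delta: float
    mu: float
    eta: float
    F: float
    F_raw: float
    p_tilde: float


def adjustment_factor(
    p5: float, p50: float, p95: float, cfg: AdjustmentConfig = AdjustmentConfig()
) -> AdjustmentComponents:
    """Component-wise evaluation of the adjustment factor for one cell."""
    if not (0 <= p5 <= p50 <= p95):
        raise ValueError("percentiles must satisfy 0 <= p5 <= p50 <= p95")
    if p50 == 0:
        raise ValueError("p50 must be positive; fractional deviations undefined")
    gamma = 1.0 - (p95 - p5) / (p95 + p5)
    phi = (p95 - p50) / p50
    delta = (p50 - p5) / p50
    mu = phi + delta
    eta = (phi - delta) / (mu + cfg.epsilon)
    F_raw = 1.0 + gamma * (cfg.omega_u * phi - cfg.omega_d * delta) \
        + (1.0 - gamma) * cfg.omega_sigma * mu * eta
    F = float(np.clip(F_raw, *cfg.clamp))
    return AdjustmentComponents(
        gamma=gamma, phi=phi, delta=delta, mu=mu, eta=eta,
        F=F, F_raw=F_raw, p_tilde=F * p50,
    )


def adjusted_raster(
    raster: QuantileRaster, cfg: AdjustmentConfig = AdjustmentConfig()
) -> np.ndarray:
    """Cell-wise adjusted population F * P50.

    Cells with P50 = 0 pass through as 0 (nothing to adjust); nodata
    propagates.
    """
    p05 = raster.band("p05")
    p50 = raster.band("p50")
    p95 = raster.band("p95")
    out = np.zeros_like(p50)
    nodata = (p05 == raster.nodata) | (p50 == raster.nodata) | (p95 == raster.nodata)
    pos = (p50 > 0) & ~nodata
    g = 1.0 - (p95[pos] - p05[pos]) / (p95[pos] + p05[pos])
    phi = (p95[pos] - p50[pos]) / p50[pos]
    delta = (p50[pos] - p05[pos]) / p50[pos]
    mu = phi + delta
    eta = (phi - delta) / (mu + cfg.epsilon)
    F = 1.0 + g * (cfg.omega_u * phi - cfg.omega_d * delta) \
        + (1.0 - g) * cfg.omega_sigma * mu * eta
    out[pos] = np.clip(F, *cfg.clamp) * p50[pos]
    out[nodata] = raster.nodata
    return out


# ---------------------------------------------------------------------------
# Exposure and SDM scoring
# ---------------------------------------------------------------------------

@dataclass
class ExposureSummary:
    dataset: str
    totals: dict[str, float]
    percentages: dict[str, float]
    total_population: float


def exposure_summary(
    population: np.ndarray,
    zones: np.ndarray,
    zone_values: Mapping[str, float] = DEFAULT_RISK_VALUES,
    nodata: float = -1.0,
    dataset: str = "",
) -> ExposureSummary:
    """Total and percentage population per hazard zone."""
    if population.shape != zones.shape:
        raise ValueError("population and zone layers must share a shape")
    valid = population != nodata
    total = float(population[valid].sum())
    totals, pcts = {}, {}
    for name, val in zone_values.items():
        mask = valid & np.isclose(zones, val)
        t = float(population[mask].sum())
        totals[name] = t
        pcts[name] = 100.0 * t / total if total > 0 else 0.0
    return ExposureSummary(dataset, totals, pcts, total)


def sdm_scores(
    population: np.ndarray, risk: np.ndarray, nodata: float = -1.0
) -> np.ndarray:
    """Composite score S_i = p_i * r_i; nodata in either layer propagates."""
    if population.shape != risk.shape:
        raise ValueError("layers must share a shape")
    out = population * risk
    out[(population == nodata) | (risk == nodata)] = nodata
    return out


def rank_scores(values: np.ndarray) -> np.ndarray:
    """Descending ranks, 1 = highest, ties averaged."""
    return rankdata(-np.asarray(values, dtype=float), method="average")


def rank_units(
    scores: np.ndarray,
    grid: GridSpec,
    units: Sequence[tuple[object, object]],
    nodata: float = -1.0,
) -> pd.DataFrame:
    """Mean composite score and rank per admin unit.

    ``units`` is a sequence of (unit id, shapely polygon); a cell belongs to
    the unit containing its center.  Units containing no valid cell centers
    are excluded from the ranking and reported with NaN.
    """
    lon, lat = grid.cell_centers()
    valid = scores != nodata
    pts = [Point(x, y) for x, y in zip(lon[valid].ravel(), lat[valid].ravel())]
    vals = scores[valid].ravel()
    tree = STRtree(pts)

    means, counts, ids = [], [], []
    for uid, poly in units:
        idx = tree.query(poly, predicate="contains")
        ids.append(uid)
        counts.append(len(idx))
        means.append(float(vals[idx].mean()) if len(idx) else np.nan)
    df = pd.DataFrame({"unit": ids, "n_cells": counts, "mean_score": means})
    ranked = df["mean_score"].notna()
    df["rank"] = np.nan
    df.loc[ranked, "rank"] = rank_scores(df.loc[ranked, "mean_score"].to_numpy())
    return df.set_index("unit")


# ---------------------------------------------------------------------------
# Rank agreement
# ---------------------------------------------------------------------------

def spearman(ranks_a: Sequence[float], ranks_b: Sequence[float]) -> float:
    """Spearman's rho between two rankings of the same unit set.

    Uses the classic 1 - 6*sum(d^2)/(n(n^2-1)) formula when neither ranking
    has ties, and the moment correlation of average ranks otherwise.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rankings must be equal-length vectors")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two units")
    has_ties = len(np.unique(a)) < n or len(np.unique(b)) < n
    if not has_ties:
        d = a - b
        return float(1.0 - 6.0 * (d @ d) / (n * (n**2 - 1)))
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("degenerate ranking: all ranks tied")
    return float(np.corrcoef(a, b)[0, 1])


def interpret_rho(rho: float) -> str:
    """Agreement band: high / moderate / low / near-zero."""
    if rho > 0.75:
        return "high"
    if rho > 0.5:
        return "moderate"
    if rho > 0.25:
        return "low"
    return "near-zero"


def topn_agreement(
    rank_tables: Mapping[str, pd.Series],
    n_values: Iterable[int] = (25, 50, 75, 100),
) -> pd.DataFrame:
    """Pairwise rho over the union of top-N units from any dataset.

    ``rank_tables`` maps dataset name to a Series of ranks indexed by unit
    id (1 = highest priority).  For each N the unit set is the union of the
    datasets' top-N units; units are re-ranked within the subset by their
    original rank order before computing rho.
    """
    names = list(rank_tables)
    common = None
    for s in rank_tables.values():
        common = set(s.index) if common is None else common & set(s.index)
    rows = []
    for N in n_values:
        union: set = set()
        for s in rank_tables.values():
            union |= set(s[s <= N].index)
        union &= common
        units = sorted(union)
        if len(units) < 2:
            continue
        reranked = {
            name: rank_scores(-rank_tables[name].loc[units].to_numpy())
            for name in names
        }
        for i, na in enumerate(names):
            for nb in names[i + 1:]:
                rho = spearman(reranked[na], reranked[nb])
                rows.append({
                    "N": N, "a": na, "b": nb, "n_units": len(units),
                    "rho": rho, "band": interpret_rho(rho),
                })
    return pd.DataFrame(rows)
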