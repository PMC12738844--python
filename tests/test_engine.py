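"""Deterministic baseline, Monte Carlo estimator, calibration, gridding."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from mosaicpop.engine import (
    BuildingDraws,
    BuildingEstimate,
    BuildingRecord,
    TimeWeighting,
    aggregate_grid,
    calibrate,
    confidence_layer,
    degenerate_table,
    lshd_estimate,
    lsm_simulate,
    split_molecules,
    summarize,
)
from mosaicpop.geometry import Footprint
from mosaicpop.models import FloorDistribution, UseTypeDistribution, build_joint_conditional
from mosaicpop.occupancy import OccupancyPool
from mosaicpop.raster import CELLSIZE_3AS, GridSpec, QuantileRaster


def _record(bid="b1", area=2000.0, use=None, floors=None, geom=None):
    if geom is None:
        geom = Polygon([(121.001, 14.001), (121.0012, 14.001),
                        (121.0012, 14.0012), (121.001, 14.0012)])
    return BuildingRecord(
        footprint=Footprint(id=bid, geometry=geom),
        area_sqft=area, known_use=use, known_floors=floors,
    )


def _pool(u, t, values):
    return OccupancyPool(u, t, np.asarray(values, dtype=float),
                         o_max=float(np.max(values)))


SINGLE = TimeWeighting(("day",), (1.0,))


class TestLSHD:
    def test_direct_evaluation(self):
        rec = _record(area=2000, use="Residential", floors=2)
        est = lshd_estimate(rec, {("Residential", "day"): 5.0}, SINGLE)
        assert est == pytest.approx(20.0)

    def test_equal_weight_time_average(self):
        rec = _record(area=1000, use="Retail", floors=1)
        cat = {("Retail", "day"): 10.0, ("Retail", "night"): 30.0}
        est = lshd_estimate(rec, cat, TimeWeighting(("day", "night"), (1, 1)))
        assert est == pytest.approx(20.0)

    def test_defaults_applied(self):
        rec = _record(area=1000)  # no known use or floors
        est = lshd_estimate(rec, {("Residential", "day"): 4.0}, SINGLE)
        assert est == pytest.approx(1000 * 1.5 * 4.0 / 1000)

    def test_proportional_to_area(self):
        cat = {("Residential", "day"): 5.0}
        small = lshd_estimate(_record(area=10), cat, SINGLE)
        assert small == pytest.approx(10 * 1.5 * 5 / 1000)

    def test_missing_category_rejected(self):
        with pytest.raises(KeyError):
            lshd_estimate(_record(use="Military", floors=1), {("Residential", "day"): 1.0}, SINGLE)


class TestLSM:
    def test_degenerate_equals_lshd(self):
        rec = _record(area=3000, use="Retail", floors=2)
        table = degenerate_table("Retail", 2)
        pools = {("Retail", "day"): _pool("Retail", "day", [4.0]),
                 ("Retail", "night"): _pool("Retail", "night", [8.0])}
        tw = TimeWeighting(("day", "night"), (1, 1))
        draws = lsm_simulate(rec, table, pools, tw, K=200, seed=9)
        lshd = lshd_estimate(rec, {("Retail", "day"): 4.0, ("Retail", "night"): 8.0}, tw)
        assert draws.draws == pytest.approx(np.full(200, lshd))

    def test_mean_matches_analytic_expectation(self):
        rec = _record(area=2500)
        u = UseTypeDistribution({"Residential": 0.7, "Commercial": 0.3})
        f = FloorDistribution({1: 0.5, 2: 0.3, 4: 0.2})
        table = build_joint_conditional(u, f)
        rng = np.random.default_rng(5)
        pools = {
            (ut, t): _pool(ut, t, rng.uniform(1, 10, 500))
            for ut in ("Residential", "Commercial") for t in ("day", "night")
        }
        tw = TimeWeighting(("day", "night"), (2, 1))
        K = 20_000
        draws = lsm_simulate(rec, table, pools, tw, K=K, seed=11)
        w = np.array([2, 1]) / 3
        ef = f.probs[1] * 1 + f.probs[2] * 2 + f.probs[4] * 4
        expect = 0.0
        for ut, pu in u.probs.items():
            for wi, t in zip(w, ("day", "night")):
                expect += pu * wi * 2500 * ef * pools[(ut, t)].samples.mean() / 1000
        se = draws.draws.std() / np.sqrt(K)
        assert abs(draws.draws.mean() - expect) < 3 * se

    def test_reproducible_with_seed(self):
        rec = _record()
        table = degenerate_table("Residential", 1)
        pools = {("Residential", "day"): _pool("Residential", "day", [1, 2, 3])}
        d1 = lsm_simulate(rec, table, pools, SINGLE, K=100, seed=3)
        d2 = lsm_simulate(rec, table, pools, SINGLE, K=100, seed=3)
        np.testing.assert_array_equal(d1.draws, d2.draws)

    def test_invalid_K_rejected(self):
        rec = _record()
        with pytest.raises(ValueError):
            lsm_simulate(rec, degenerate_table("Residential", 1),
                         {("Residential", "day"): _pool("Residential", "day", [1])},
                         SINGLE, K=0)

    def test_missing_pool_rejected(self):
        rec = _record()
        with pytest.raises(KeyError):
            lsm_simulate(rec, degenerate_table("Military", 1),
                         {("Residential", "day"): _pool("Residential", "day", [1])},
                         SINGLE, K=10)


class TestSummarize:
    def test_constant_draws(self):
        e = summarize(BuildingDraws("b", np.full(50, 7.0), seed=0))
        assert (e.mean, e.p05, e.p50, e.p95) == (7, 7, 7, 7)

    def test_linear_interpolation_median(self):
        e = summarize(BuildingDraws("b", np.arange(1.0, 101.0), seed=0))
        assert e.p50 == pytest.approx(50.5)
        assert e.mean == pytest.approx(50.5)

    def test_monotone_quantiles(self, rng):
        e = summarize(BuildingDraws("b", rng.gamma(2, 10, 1000), seed=0))
        assert e.p05 <= e.p50 <= e.p95


class TestCalibrate:
    def _est(self, bid, mean, p05=None, p50=None, p95=None):
        return BuildingEstimate(bid, mean, p05 if p05 is not None else mean * 0.8,
                                p50 if p50 is not None else mean,
                                p95 if p95 is not None else mean * 1.3)

    def test_proportional_allocation(self):
        ests, alpha = calibrate([self._est("a", 10), self._est("b", 30)], 100)
        assert alpha == pytest.approx(2.5)
        assert [e.mean for e in ests] == pytest.approx([25, 75])

    def test_identity_when_total_matches(self):
        ests, alpha = calibrate([self._est("a", 40), self._est("b", 60)], 100)
        assert alpha == pytest.approx(1.0)

    def test_sum_equals_total_and_ratios_preserved(self, rng):
        raw = [self._est(f"b{i}", m) for i, m in enumerate(rng.uniform(1, 50, 200))]
        ests, _ = calibrate(raw, 12_345.0)
        assert sum(e.mean for e in ests) == pytest.approx(12_345.0, rel=1e-12)
        for before, after in zip(raw, ests):
            assert after.p95 / after.p05 == pytest.approx(before.p95 / before.p05, rel=1e-9)
            assert after.p05 <= after.p50 <= after.p95

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            calibrate([BuildingEstimate("a", 0, 0, 0, 0)], 100)


class TestMolecules:
    def test_fully_inside_one_cell(self):
        grid = GridSpec.from_extent(121.0, 14.0, 121.01, 14.01)
        rec = _record(geom=Polygon([(121.0001, 14.0001), (121.0004, 14.0001),
                                    (121.0004, 14.0004), (121.0001, 14.0004)]))
        mols = split_molecules(rec, grid)
        assert len(mols) == 1
        assert mols[0].share == pytest.approx(1.0)

    def test_even_straddle(self):
        grid = GridSpec.from_extent(121.0, 14.0, 121.01, 14.01)
        edge = grid.west + grid.cellsize  # vertical cell boundary
        half = 0.0002
        rec = _record(geom=Polygon([
            (edge - half, 14.0002), (edge + half, 14.0002),
            (edge + half, 14.0004), (edge - half, 14.0004)]))
        mols = split_molecules(rec, grid)
        shares = sorted(m.share for m in mols)
        assert shares == pytest.approx([0.5, 0.5], rel=1e-6)

    def test_random_polygons_conserve_area(self, rng):
        grid = GridSpec.from_extent(121.0, 14.0, 121.02, 14.02)
        for _ in range(20):
            cx = rng.uniform(121.001, 121.016)
            cy = rng.uniform(14.001, 14.016)
            w, h = rng.uniform(1e-4, 3e-3, 2)
            rec = _record(geom=Polygon([
                (cx, cy), (cx + w, cy), (cx + w, cy + h), (cx, cy + h)]))
            mols = split_molecules(rec, grid)
            assert sum(m.share for m in mols) == pytest.approx(1.0, abs=1e-9)

    def test_outside_grid_rejected(self):
        grid = GridSpec.from_extent(121.0, 14.0, 121.01, 14.01)
        rec = _record(geom=Polygon([(122.0, 15.0), (122.001, 15.0),
                                    (122.001, 15.001), (122.0, 15.001)]))
        with pytest.raises(ValueError, match="overlap"):
            split_molecules(rec, grid)


class TestAggregation:
    def test_single_building_single_cell(self):
        grid = GridSpec.from_extent(121.0, 14.0, 121.01, 14.01)
        rec = _record(geom=Polygon([(121.0001, 14.0001), (121.0003, 14.0001),
                                    (121.0003, 14.0003), (121.0001, 14.0003)]))
        mols = {rec.id: split_molecules(rec, grid)}
        est = BuildingEstimate(rec.id, 10, 8, 10, 14)
        raster = aggregate_grid([est], mols, grid)
        assert raster.band("p50").sum() == pytest.approx(10.0)
        r, c = mols[rec.id][0].cell
        assert raster.band("p95")[r, c] == pytest.approx(14.0)

    def test_mass_conserved_per_band(self, small_bundle, small_pools):
        from dataclasses import replace as dc_replace

        from mosaicpop.pipeline import attach_attribute_distributions, grid_all, simulate_all

        # copy records so the shared session fixture stays unmutated
        buildings = [
            dc_replace(
                b,
                known_use=small_bundle.truth.loc[b.id, "use_type"],
                known_floors=int(small_bundle.truth.loc[b.id, "floors"]),
            )
            for b in small_bundle.buildings[:100]
        ]
        attach_attribute_distributions(buildings)
        ests, _ = simulate_all(buildings, small_pools, K=200, seed=1,
                               total_population=5000.0)
        raster = grid_all(buildings, ests, small_bundle.grid)
        for band, attr in (("mean", "mean"), ("p05", "p05"), ("p50", "p50"), ("p95", "p95")):
            assert raster.band(band).sum() == pytest.approx(
                sum(getattr(e, attr) for e in ests), rel=1e-6
            )


class TestConfidence:
    def _raster(self, p05, p95):
        grid = GridSpec(west=121.0, south=14.0, ncols=1, nrows=1)
        return QuantileRaster(grid=grid, bands={
            "p05": np.array([[p05]]), "p50": np.array([[(p05 + p95) / 2]]),
            "p95": np.array([[p95]]),
        })

    def test_zero_spread_full_confidence(self):
        assert confidence_layer(self._raster(5.0, 5.0))[0, 0] == pytest.approx(1.0)

    def test_maximal_spread_zero_confidence(self):
        assert confidence_layer(self._raster(0.0, 9.0))[0, 0] == pytest.approx(0.0)

    def test_empty_cell_is_full_confidence(self):
        assert confidence_layer(self._raster(0.0, 0.0))[0, 0] == pytest.approx(1.0)

    def test_formula_oracle(self, rng):
        grid = GridSpec(west=121.0, south=14.0, ncols=4, nrows=3)
        p05 = rng.uniform(0, 5, (3, 4))
        p95 = p05 + rng.uniform(0, 10, (3, 4))
        raster = QuantileRaster(grid=grid, bands={
            "p05": p05, "p50": (p05 + p95) / 2, "p95": p95})
        conf = confidence_layer(raster)
        expected = 1 - (p95 - p05) / (p95 + p05)
        np.testing.assert_allclose(conf, expected, rtol=1e-9)
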