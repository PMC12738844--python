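"""Uncertainty-weighted adjustment, exposure, SDM scoring and rank agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from shapely.geometry import box

from mosaicpop.decisions import (
    DEFAULT_RISK_VALUES,
    AdjustmentConfig,
    adjusted_raster,
    adjustment_factor,
    exposure_summary,
    interpret_rho,
    rank_scores,
    rank_units,
    sdm_scores,
    spearman,
    topn_agreement,
)
from mosaicpop.raster import GridSpec, QuantileRaster

CFG = AdjustmentConfig()  # omega_u=0.30, omega_d=0.20, omega_sigma=0.40


def _oracle_F(p5, p50, p95, cfg):
    """Independent step-by-step evaluation of the five component formulas."""
    gamma = 1 - (p95 - p5) / (p95 + p5)
    phi = (p95 - p50) / p50
    delta = (p50 - p5) / p50
    mu = phi + delta
    eta = (phi - delta) / (mu + cfg.epsilon)
    F = 1 + gamma * (cfg.omega_u * phi - cfg.omega_d * delta) \
        + (1 - gamma) * cfg.omega_sigma * mu * eta
    return min(max(F, cfg.clamp[0]), cfg.clamp[1])


class TestAdjustmentFactor:
    def test_zero_spread_unity(self):
        c = adjustment_factor(5.0, 5.0, 5.0, CFG)
        assert (c.gamma, c.phi, c.delta, c.mu, c.eta) == (1, 0, 0, 0, 0)
        assert c.F == 1.0
        assert c.p_tilde == pytest.approx(5.0)

    def test_symmetric_spread_with_equal_weights(self):
        cfg = AdjustmentConfig(omega_u=0.25, omega_d=0.25)
        c = adjustment_factor(80, 100, 120, cfg)
        assert c.F == pytest.approx(1.0)

    def test_worked_example_matches_component_oracle(self):
        c = adjustment_factor(80, 100, 160, CFG)
        assert c.gamma == pytest.approx(1 - 80 / 240)
        assert c.phi == pytest.approx(0.6)
        assert c.delta == pytest.approx(0.2)
        assert c.mu == pytest.approx(0.8)
        assert c.eta == pytest.approx(0.4 / (0.8 + 1e-9))
        assert c.F == pytest.approx(_oracle_F(80, 100, 160, CFG), rel=1e-12)

    def test_clamped_to_bounds(self):
        cfg = AdjustmentConfig(omega_u=10.0, omega_d=0.0, omega_sigma=0.0)
        c = adjustment_factor(99, 100, 10_000, cfg)
        assert c.F == cfg.clamp[1]
        cfg2 = AdjustmentConfig(omega_u=0.0, omega_d=10.0, omega_sigma=0.0)
        c2 = adjustment_factor(50, 100, 100, cfg2)
        assert c2.F == cfg2.clamp[0]

    def test_thousand_random_triples_against_oracle(self, rng):
        for _ in range(1000):
            p50 = rng.uniform(1, 1000)
            p5 = p50 * rng.uniform(0, 1)
            p95 = p50 * rng.uniform(1, 5)
            c = adjustment_factor(p5, p50, p95, CFG)
            assert c.F == pytest.approx(_oracle_F(p5, p50, p95, CFG), rel=1e-12)
            assert c.mu == pytest.approx(c.phi + c.delta, rel=1e-12)
            assert abs(c.eta) <= 1.0 + 1e-12

    def test_undercount_weight_raises_F_for_right_skew(self):
        lo = adjustment_factor(90, 100, 200, AdjustmentConfig(omega_u=0.1)).F
        hi = adjustment_factor(90, 100, 200, AdjustmentConfig(omega_u=0.9)).F
        assert hi >= lo

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            adjustment_factor(10, 5, 20, CFG)   # order violation
        with pytest.raises(ValueError):
            adjustment_factor(0, 0, 0, CFG)     # zero median


class TestAdjustedRaster:
    def _raster(self, p05, p50, p95):
        grid = GridSpec(west=0, south=0, ncols=p50.shape[1], nrows=p50.shape[0])
        return QuantileRaster(grid=grid, bands={"p05": p05, "p50": p50, "p95": p95})

    def test_zero_spread_identity(self):
        p = np.full((2, 3), 7.0)
        out = adjusted_raster(self._raster(p, p, p), CFG)
        np.testing.assert_allclose(out, p)

    def test_zero_median_passes_through_as_zero(self):
        z = np.zeros((1, 2))
        out = adjusted_raster(self._raster(z, z, z), CFG)
        np.testing.assert_allclose(out, 0.0)

    def test_cellwise_oracle_and_clamp(self, rng):
        p50 = rng.uniform(1, 100, (5, 5))
        p05 = p50 * rng.uniform(0, 1, (5, 5))
        p95 = p50 * rng.uniform(1, 20, (5, 5))
        out = adjusted_raster(self._raster(p05, p50, p95), CFG)
        for i in range(5):
            for j in range(5):
                F = _oracle_F(p05[i, j], p50[i, j], p95[i, j], CFG)
                assert out[i, j] == pytest.approx(F * p50[i, j], rel=1e-9)
                assert CFG.clamp[0] * p50[i, j] <= out[i, j] <= CFG.clamp[1] * p50[i, j]


class TestExposure:
    def test_all_population_one_zone(self):
        pop = np.array([[10.0, 20.0]])
        zones = np.array([[1.00, 1.00]])
        s = exposure_summary(pop, zones)
        assert s.percentages["high"] == pytest.approx(100.0)
        assert s.totals["low"] == 0.0

    def test_equal_thirds(self):
        pop = np.full((1, 3), 50.0)
        zones = np.array([[0.33, 0.66, 1.00]])
        s = exposure_summary(pop, zones)
        for z in ("low", "moderate", "high"):
            assert s.percentages[z] == pytest.approx(100 / 3)

    def test_totals_conserved_and_scale_invariant(self, rng):
        pop = rng.uniform(0, 100, (6, 6))
        zones = rng.choice([0.33, 0.66, 1.00], (6, 6))
        s1 = exposure_summary(pop, zones)
        assert sum(s1.totals.values()) == pytest.approx(pop.sum())
        s2 = exposure_summary(pop * 3.7, zones)
        for z in s1.percentages:
            assert s2.percentages[z] == pytest.approx(s1.percentages[z], rel=1e-9)


class TestSDM:
    def test_unit_risk_identity(self, rng):
        pop = rng.uniform(0, 10, (3, 3))
        np.testing.assert_allclose(sdm_scores(pop, np.ones((3, 3))), pop)

    def test_zero_population_zero_score(self):
        assert sdm_scores(np.zeros((2, 2)), np.full((2, 2), 0.66)).sum() == 0

    def test_elementwise_product_and_nodata(self, rng):
        pop = rng.uniform(0, 10, (4, 4))
        risk = rng.choice([0.33, 0.66, 1.0], (4, 4))
        pop[0, 0] = -1.0
        s = sdm_scores(pop, risk, nodata=-1.0)
        assert s[0, 0] == -1.0
        np.testing.assert_allclose(s[1:], pop[1:] * risk[1:])


class TestRankUnits:
    def test_two_units(self):
        grid = GridSpec(west=0, south=0, ncols=2, nrows=1, cellsize=1.0)
        scores = np.array([[3.0, 5.0]])
        units = [("L", box(0, 0, 1, 1)), ("R", box(1, 0, 2, 1))]
        df = rank_units(scores, grid, units)
        assert df.loc["R", "rank"] == 1.0
        assert df.loc["L", "rank"] == 2.0

    def test_tied_means_average_rank(self):
        grid = GridSpec(west=0, south=0, ncols=2, nrows=1, cellsize=1.0)
        scores = np.array([[4.0, 4.0]])
        units = [("A", box(0, 0, 1, 1)), ("B", box(1, 0, 2, 1))]
        df = rank_units(scores, grid, units)
        assert df["rank"].tolist() == [1.5, 1.5]

    def test_empty_unit_excluded(self):
        grid = GridSpec(west=0, south=0, ncols=1, nrows=1, cellsize=1.0)
        units = [("A", box(0, 0, 1, 1)), ("far", box(10, 10, 11, 11))]
        df = rank_units(np.array([[2.0]]), grid, units)
        assert np.isnan(df.loc["far", "rank"])
        assert df.loc["A", "rank"] == 1.0

    def test_many_units_against_sort_oracle(self, rng):
        n = 12
        grid = GridSpec(west=0, south=0, ncols=n, nrows=1, cellsize=1.0)
        scores = rng.uniform(0, 100, (1, n))
        units = [(f"u{i}", box(i, 0, i + 1, 1)) for i in range(n)]
        df = rank_units(scores, grid, units)
        order = np.argsort(-scores[0])
        for rank0, idx in enumerate(order):
            assert df.loc[f"u{idx}", "rank"] == rank0 + 1


class TestSpearman:
    def test_identical_rankings(self):
        assert spearman([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_exact_reversal(self):
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_thousand_permutations_match_scipy(self, rng):
        n = 50
        base = np.arange(1, n + 1)
        for _ in range(1000):
            a = rng.permutation(base).astype(float)
            b = rng.permutation(base).astype(float)
            assert spearman(a, b) == pytest.approx(spearmanr(a, b).statistic, abs=1e-12)

    def test_ties_match_scipy(self, rng):
        for _ in range(200):
            x = rng.integers(0, 8, 30).astype(float)
            y = rng.integers(0, 8, 30).astype(float)
            ra, rb = rank_scores(-x), rank_scores(-y)
            if np.std(ra) == 0 or np.std(rb) == 0:
                continue
            assert spearman(ra, rb) == pytest.approx(spearmanr(x, y).statistic, abs=1e-9)

    def test_symmetry_and_monotone_invariance(self, rng):
        x = rng.uniform(0, 1, 40)
        y = rng.uniform(0, 1, 40)
        ra, rb = rank_scores(x), rank_scores(y)
        assert spearman(ra, rb) == pytest.approx(spearman(rb, ra))
        assert spearman(rank_scores(np.exp(3 * x)), rb) == pytest.approx(spearman(ra, rb))


class TestInterpretation:
    @pytest.mark.parametrize("rho,band", [
        (0.8, "high"), (0.76, "high"), (0.75, "moderate"), (0.6, "moderate"),
        (0.5, "low"), (0.3, "low"), (0.25, "near-zero"), (-0.4, "near-zero"),
    ])
    def test_bands(self, rho, band):
        assert interpret_rho(rho) == band


class TestTopN:
    def _tables(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        units = [f"u{i}" for i in range(n)]
        base = rng.uniform(0, 100, n)
        jitter = base + rng.normal(0, 10, n)
        return {
            "a": pd.Series(rank_scores(base), index=units),
            "b": pd.Series(rank_scores(jitter), index=units),
        }

    def test_identical_datasets_rho_one(self):
        t = self._tables()
        t["b"] = t["a"].copy()
        out = topn_agreement(t, n_values=[10, 25])
        assert (out["rho"] == 1.0).all()

    def test_disjoint_topn_still_defined(self):
        units = [f"u{i}" for i in range(20)]
        a = pd.Series(np.arange(1, 21, dtype=float), index=units)
        b = pd.Series(np.arange(20, 0, -1, dtype=float), index=units)
        out = topn_agreement({"a": a, "b": b}, n_values=[5])
        assert len(out) == 1
        assert -1 <= out["rho"].iloc[0] <= 1

    def test_perturbation_against_direct_computation(self):
        t = self._tables(seed=3)
        out = topn_agreement(t, n_values=[15])
        union = set(t["a"][t["a"] <= 15].index) | set(t["b"][t["b"] <= 15].index)
        units = sorted(union)
        ra = rank_scores(-t["a"].loc[units].to_numpy())
        rb = rank_scores(-t["b"].loc[units].to_numpy())
        assert out["rho"].iloc[0] == pytest.approx(spearmanr(ra, rb).statistic, abs=1e-9)
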