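"""Facility-type occupancy rates as scaled Beta distributions.

Occupancy (people per 1000 ft^2 of floor space) for a facility type and
time period is modelled as ``Beta(alpha, beta) * O_max``, where O_max is a
practical ceiling on how many people fit in 1000 ft^2.  Three layers:

* point summaries (Beta quantiles) used by the deterministic baseline;
* Bayesian updating of (alpha, beta) on a discrete parameter grid from
  occupancy observations, which may themselves be produced by an
  observation model mapping reported facility properties (visitors, hours,
  staff, floor area) to latent occupancy samples;
* pooling of detailed facility types into one empirical sample set per
  broad use category, which the Monte Carlo population engine draws from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import betaln

#: Default number of Beta draws contributed by each facility type to a pool.
DEFAULT_POOL_DRAWS = 10_000


@dataclass(frozen=True)
class OccupancySpec:
    """Beta-distributed occupancy for one facility type and time period."""

    facility_type: str
    use_type: str
    time_period: str
    alpha: float
    beta: float
    o_max: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be strictly positive")
        if self.o_max <= 0:
            raise ValueError("O_max must be strictly positive")


def quantile(spec: OccupancySpec, q: float) -> float:
    """Occupancy-rate quantile: BetaQuantile(q; alpha, beta) * O_max."""
    if not 0 < q < 1:
        raise ValueError("quantile level must lie strictly between 0 and 1")
    return float(stats.beta.ppf(q, spec.alpha, spec.beta) * spec.o_max)


def median_rate(spec: OccupancySpec) -> float:
    """The 50th-percentile rate used as the deterministic representative value."""
    return quantile(spec, 0.5)


def lshd_category_rate(specs: Sequence[OccupancySpec]) -> float:
    """Deterministic broad-category rate: the mean of subcategory medians."""
    if not specs:
        raise ValueError("no occupancy specs supplied")
    return float(np.mean([median_rate(s) for s in specs]))


# ---------------------------------------------------------------------------
# Observation models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Quantity:
    """A scalar observable with a sampling distribution.

    dist is one of ``point`` (value), ``uniform`` (low, high) or
    ``normal`` (mean, sd).
    """

    dist: str
    params: tuple

    @classmethod
    def point(cls, value: float) -> "Quantity":
        return cls("point", (float(value),))

    @classmethod
    def uniform(cls, low: float, high: float) -> "Quantity":
        return cls("uniform", (float(low), float(high)))

    @classmethod
    def normal(cls, mean: float, sd: float) -> "Quantity":
        return cls("normal", (float(mean), float(sd)))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "point":
            return np.full(n, self.params[0])
        if self.dist == "uniform":
            return rng.uniform(self.params[0], self.params[1], n)
        if self.dist == "normal":
            return rng.normal(self.params[0], self.params[1], n)
        raise ValueError(f"unknown distribution kind {self.dist!r}")


@dataclass
class ObservationVector:
    """Observable facility properties feeding an occupancy observation model."""

    a: Quantity        # annual visitors
    v_bar: Quantity    # average visit time (hours)
    d: Quantity        # days open per year
    h_bar: Quantity    # average daily opening hours
    w: Quantity        # employees
    p_bar: Quantity    # average fraction of employees present, in [0, 1]
    A: Quantity        # floor area (ft^2)


def _museum_model(omega: ObservationVector, rng: np.random.Generator, n: int) -> np.ndarray:
    """Ambient museum occupancy: pdt = 1000/A * (a*v_bar/(d*h_bar) + w*p_bar).

    Draws with nonpositive A, d or h_bar are rejected and resampled.
    """
    out = np.empty(0)
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100:
            raise RuntimeError("observation model failed to produce valid draws")
        m = n - len(out)
        a = omega.a.sample(rng, m)
        v = omega.v_bar.sample(rng, m)
        d = omega.d.sample(rng, m)
        h = omega.h_bar.sample(rng, m)
        w = omega.w.sample(rng, m)
        p = omega.p_bar.sample(rng, m)
        A = omega.A.sample(rng, m)
        ok = (A > 0) & (d > 0) & (h > 0)
        pdt = 1000.0 / A[ok] * (a[ok] * v[ok] / (d[ok] * h[ok]) + w[ok] * p[ok])
        out = np.concatenate([out, pdt])
    return out[:n]


OBSERVATION_MODELS: dict[str, Callable] = {"museum": _museum_model}


def evaluate_observation_model(
    model_id: str,
    omega: ObservationVector,
    n_samples: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Sample latent occupancy-rate values from a registered observation model."""
    if model_id not in OBSERVATION_MODELS:
        raise KeyError(
            f"unknown observation model {model_id!r}; "
            f"registered: {sorted(OBSERVATION_MODELS)}"
        )
    rng = np.random.default_rng(seed)
    return OBSERVATION_MODELS[model_id](omega, rng, n_samples)


# ---------------------------------------------------------------------------
# Posterior over Beta shape parameters
# ---------------------------------------------------------------------------

@dataclass
class PosteriorGrid:
    """Discrete posterior over (alpha, beta) on a log-spaced grid."""

    alphas: np.ndarray     # (na,)
    betas: np.ndarray      # (nb,)
    mass: np.ndarray       # (na, nb), sums to 1

    def __post_init__(self) -> None:
        if np.any(self.alphas <= 0) or np.any(self.betas <= 0):
            raise ValueError("grid axes must be strictly positive")
        total = self.mass.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"posterior mass sums to {total}, not 1")

    @classmethod
    def flat(
        cls,
        lo: float = 0.1,
        hi: float = 100.0,
        n: int = 100,
    ) -> "PosteriorGrid":
        axis = np.logspace(math.log10(lo), math.log10(hi), n)
        mass = np.full((n, n), 1.0 / (n * n))
        return cls(alphas=axis.copy(), betas=axis.copy(), mass=mass)

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.alphas, self.betas, indexing="ij")


def _log_likelihood(grid: PosteriorGrid, x: np.ndarray) -> np.ndarray:
    """Sum over observations of log Beta(x; alpha, beta) on the grid."""
    A, B = grid.grid()
    s1 = np.log(x).sum()
    s2 = np.log1p(-x).sum()
    return (A - 1) * s1 + (B - 1) * s2 - len(x) * betaln(A, B)


def update_posterior(
    prior: PosteriorGrid, pdt_samples: Sequence[float], o_max: float
) -> PosteriorGrid:
    """Bayes update of the (alpha, beta) grid from occupancy observations.

    Each sample is an independent observation of the scaled-Beta occupancy
    rate; the posterior is prior times the product of Beta likelihoods at
    x = pdt/O_max, renormalized on the grid.  With no samples the posterior
    equals the prior; the update is order-invariant by construction.
    """
    x = np.asarray(pdt_samples, dtype=float)
    if len(x) == 0:
        return PosteriorGrid(prior.alphas.copy(), prior.betas.copy(), prior.mass.copy())
    if np.any((x <= 0) | (x >= o_max)):
        raise ValueError("samples must lie strictly inside (0, O_max)")
    ll = _log_likelihood(prior, x / o_max)
    with np.errstate(divide="ignore"):
        logpost = ll + np.log(prior.mass)
    finite = np.isfinite(logpost)
    if not finite.any():
        raise FloatingPointError("posterior underflow: no grid cell has support")
    logpost = logpost - logpost[finite].max()
    mass = np.where(finite, np.exp(logpost), 0.0)
    total = mass.sum()
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError("posterior underflow across the grid")
    return PosteriorGrid(prior.alphas.copy(), prior.betas.copy(), mass / total)


def jeffrey_update(
    prior: PosteriorGrid, pdt_samples: Sequence[float], o_max: float
) -> PosteriorGrid:
    """One Jeffrey-conditioning step for a single *uncertain* observation.

    The sample set is read as a Monte Carlo representation of p(pdt | omega)
    for one observation event; the output is the conflation
    integral p(a, b | pdt) p(pdt | omega) dpdt, i.e. the equally weighted
    mixture of the single-sample posteriors.
    """
    x = np.asarray(pdt_samples, dtype=float)
    if len(x) == 0:
        return PosteriorGrid(prior.alphas.copy(), prior.betas.copy(), prior.mass.copy())
    if np.any((x <= 0) | (x >= o_max)):
        raise ValueError("samples must lie strictly inside (0, O_max)")
    A, B = prior.grid()
    u = x / o_max
    mix = np.zeros_like(prior.mass)
    n_ok = 0
    for ui in u:
        like = stats.beta.pdf(ui, A, B) * prior.mass
        total = like.sum()
        if total > 0 and np.isfinite(total):
            mix += like / total
            n_ok += 1
    if n_ok == 0:
        raise FloatingPointError("all single-sample posteriors underflowed")
    mix /= mix.sum()
    return PosteriorGrid(prior.alphas.copy(), prior.betas.copy(), mix)


def summarize_posterior(post: PosteriorGrid) -> tuple[float, float]:
    """Posterior-mass-weighted means (alpha_bar, beta_bar)."""
    A, B = post.grid()
    return float((post.mass * A).sum()), float((post.mass * B).sum())


# ---------------------------------------------------------------------------
# Broad-category pools
# ---------------------------------------------------------------------------

@dataclass
class OccupancyPool:
    """Empirical occupancy sample set for a broad use type and time period."""

    use_type: str
    time_period: str
    samples: np.ndarray
    o_max: float
    n_per_facility: int = DEFAULT_POOL_DRAWS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) == 0:
            raise ValueError("occupancy pool must be nonempty")
        if np.any(self.samples <= 0) or np.any(self.samples > self.o_max):
            raise ValueError("pool samples must lie in (0, O_max]")

    def mean(self) -> float:
        return float(self.samples.mean())


def pool_broad_category(
    specs: Sequence[OccupancySpec],
    n_per_facility: int = DEFAULT_POOL_DRAWS,
    seed: int = 0,
) -> OccupancyPool:
    """Aggregate detailed facility types into one broad-category sample set.

    Each facility type contributes ``n_per_facility`` draws from its scaled
    Beta; the category O_max is the maximum of the contributing bounds.
    This replaces the deterministic practice of averaging subcategory
    medians.
    """
    if not specs:
        raise ValueError("no occupancy specs supplied")
    periods = {s.time_period for s in specs}
    if len(periods) != 1:
        raise ValueError(f"specs span multiple time periods: {sorted(periods)}")
    use_types = {s.use_type for s in specs}
    if len(use_types) != 1:
        raise ValueError(f"specs span multiple use types: {sorted(use_types)}")
    rng = np.random.default_rng(seed)
    draws = [
        rng.beta(s.alpha, s.beta, n_per_facility) * s.o_max for s in specs
    ]
    return OccupancyPool(
        use_type=specs[0].use_type,
        time_period=specs[0].time_period,
        samples=np.concatenate(draws),
        o_max=max(s.o_max for s in specs),
        n_per_facility=n_per_facility,
    )


def sample_occupancy(
    pool: OccupancyPool, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Uniform draws with replacement from the pool's empirical samples."""
    return rng.choice(pool.samples, size=size, replace=True)
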