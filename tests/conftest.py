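import numpy as np
import pytest

from mosaicpop.geometry import compute_feature_table
from mosaicpop.pipeline import build_pools
from mosaicpop.projection import ProjectionPolicy
from mosaicpop.synth import ScenarioConfig, end_to_end_fixture


@pytest.fixture(scope="session")
def policy():
    return ProjectionPolicy(lon0=121.025, lat0=14.025)


@pytest.fixture(scope="session")
def small_bundle():
    """A 400-building synthetic scenario shared across tests."""
    return end_to_end_fixture(ScenarioConfig(seed=123, n_buildings=400))


@pytest.fixture(scope="session")
def small_features(small_bundle):
    return compute_feature_table([r.footprint for r in small_bundle.buildings])


@pytest.fixture(scope="session")
def small_pools(small_bundle):
    return build_pools(small_bundle.catalogue, seed=99)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
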