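import numpy as np
import pytest

from patternpipe import coatsim as cs
from patternpipe.pipeline import PipelineConfig, catalog_to_crops


@pytest.fixture(scope="session")
def small_params():
    return cs.PopulationParams(name="testpop", n_individuals=4, seed=123)


@pytest.fixture(scope="session")
def small_catalog(small_params):
    return cs.generate_catalog(small_params)


@pytest.fixture(scope="session")
def small_crops(small_catalog):
    crops, _ = catalog_to_crops(small_catalog, PipelineConfig())
    return crops


@pytest.fixture(scope="session")
def individual():
    return cs.make_individual(cs.zimbabwe_like(seed=7), "fix-ind")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
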