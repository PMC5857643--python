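import numpy as np
import pytest

from atsplan import MassRatios, SynthConfig, GridSpec, fixture_small


@pytest.fixture(scope="session")
def ratios() -> MassRatios:
    """Default Redfield-type biomass mass fractions."""
    return MassRatios.from_composition()


@pytest.fixture(scope="session")
def fixture_world():
    """The shipped 10x10 hand-set grid and its two basins."""
    return fixture_small()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_synth_config() -> SynthConfig:
    """A 72x36 five-degree world: fast, but structured enough to aggregate."""
    return SynthConfig(
        grid=GridSpec(cell_arcmin=300.0, n_lat=36, n_lon=72),
        n_basins=12,
        seed=99,
    )
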