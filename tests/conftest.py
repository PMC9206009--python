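import numpy as np
import pytest

from heatstack.synth import SynthConfig, gen_counties, gen_meteo, write_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """A small, fast fixture config: 6×6 grid, one week, three counties."""
    return SynthConfig(n_lat=6, n_lon=6, n_days=7, seed=7)


@pytest.fixture(scope="session")
def small_meteo(small_cfg):
    return gen_meteo(small_cfg)


@pytest.fixture(scope="session")
def small_counties(small_cfg):
    return gen_counties(small_cfg)


@pytest.fixture(scope="session")
def small_fixture_dir(small_cfg, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return write_fixture(small_cfg, out)
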