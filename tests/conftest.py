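import numpy as np
import pytest

from unzipmap import (
    ElasticParams,
    ThermoParams,
    demo_construct,
    equilibrium_unzip_curve,
    make_schedule,
)
from unzipmap.elastic import ElasticTables


@pytest.fixture(scope="session")
def thermo():
    return ThermoParams()


@pytest.fixture(scope="session")
def elastic():
    return ElasticParams()


@pytest.fixture(scope="session")
def tables(elastic):
    return ElasticTables(elastic)


@pytest.fixture(scope="session")
def construct():
    return demo_construct()


@pytest.fixture(scope="session")
def theory(construct, thermo, elastic, tables):
    return equilibrium_unzip_curve(construct, thermo, elastic, tables=tables)


@pytest.fixture(scope="session")
def schedule(construct, elastic):
    return make_schedule(construct, elastic, n_points=1200)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
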