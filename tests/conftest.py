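import numpy as np
import pytest

from fawrisk import synthetic
from fawrisk.climex import run_grid
from fawrisk.params import SpeciesParameters


@pytest.fixture(scope="session")
def params():
    return SpeciesParameters()


@pytest.fixture(scope="session")
def world():
    """The default synthetic world: monthly climate, irrigation mask, zone truth."""
    return synthetic.gen_climate_grid(synthetic.SyntheticWorldSpec(seed=0))


@pytest.fixture(scope="session")
def suitability_rainfed(world):
    monthly, irrigation, _ = world
    return run_grid(monthly, irrigation, scenario="rainfed")


@pytest.fixture(scope="session")
def suitability_irrigated(world):
    monthly, irrigation, _ = world
    return run_grid(monthly, irrigation, scenario="irrigated")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def constant_weekly(tavg=25.0, prec=30.0, rh=70.0, diurnal=5.0):
    """A flat 52-week cell climate dict, handy for constructed profiles."""
    n = 52
    return {
        "tmin": np.full(n, tavg - diurnal),
        "tmax": np.full(n, tavg + diurnal),
        "prec": np.full(n, prec),
        "rh09": np.full(n, rh),
        "rh15": np.full(n, rh),
    }
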