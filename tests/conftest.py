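import numpy as np
import pytest
import xarray as xr

from hgdep import synth
from hgdep.drydep import LandCategoryTable


@pytest.fixture(scope="session")
def table():
    return LandCategoryTable.default()


@pytest.fixture(scope="session")
def synth_cfg():
    # small world: 8x8 grid, two weeks of hourly met, 50 sites
    return synth.SynthConfig(nlat=8, nlon=8, hours=24 * 14, n_sites=50,
                             seed=20150101)


@pytest.fixture(scope="session")
def met(synth_cfg):
    return synth.generate_met(synth_cfg)


@pytest.fixture(scope="session")
def surface(synth_cfg):
    return synth.generate_surface(synth_cfg)


@pytest.fixture(scope="session")
def conc(surface, synth_cfg):
    return synth.generate_concentration(surface, synth_cfg)


@pytest.fixture(scope="session")
def rainforest_mask(surface):
    return xr.DataArray(surface["rainforest_mask"].values.astype(bool),
                        coords={"lat": surface["lat"],
                                "lon": surface["lon"]},
                        dims=("lat", "lon"))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
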