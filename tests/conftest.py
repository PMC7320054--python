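import pytest

from achims.mass import ion_mz
from achims.imaging import MassWindow
from achims.simulate import DHB_MZ, SimulationConfig

#: Analyte mass-filter window: 146.117 ± 0.02 Da.
ACH_WINDOW = MassWindow(146.117, 0.02)
#: Internal-standard window around the protonated DHB ion.
DHB_WINDOW = MassWindow(DHB_MZ, 0.02)


@pytest.fixture
def spot_cfg_small():
    """Compact spot-series config: 10 levels x 4 replicates, radius-2 spots.

    Small enough for fast unit tests while keeping the full dilution
    range and every noise component at its default strength.
    """
    return SimulationConfig(seed=11, grid_shape=(60, 24), replicates=4,
                            spot_radius=2.0)


@pytest.fixture
def spot_cfg_noise_free(spot_cfg_small):
    return spot_cfg_small.with_(rep_sigma=0.0, pixel_sigma=0.0,
                                floor_sigma=0.0, chem_sigma=0.0)


@pytest.fixture
def lung_cfg_small():
    return SimulationConfig(seed=5, layout="lung_section",
                            grid_shape=(48, 48))


@pytest.fixture
def lung_cfg_noise_free(lung_cfg_small):
    return lung_cfg_small.with_(rep_sigma=0.0, pixel_sigma=0.0,
                                floor_sigma=0.0, chem_sigma=0.0)
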