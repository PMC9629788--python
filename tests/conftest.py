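import numpy as np
import pytest

from cropsail.coupling import RTMParams
from cropsail.datasets import build_cdata
from cropsail.rtm import builtin_micasense_bands
from cropsail.trajectory import TrajectoryConfig
from cropsail.workflow import coupled_campaign


def make_params(**overrides) -> RTMParams:
    """A mid-range valid parameter set with selective overrides."""
    base = dict(Ns=1.8, Cw=0.02, Cm=0.005, Cab=40.0, Car=0.216 * 40.0,
                LAI=3.0, hspot=0.2, SZA=30.0, RAA=0.0)
    base.update(overrides)
    return RTMParams(**base)


@pytest.fixture(scope="session")
def micasense_bands():
    return builtin_micasense_bands()


@pytest.fixture(scope="session")
def small_campaign():
    """~700 coupled records from 20 jittered trajectories (seed-fixed)."""
    params, meta = coupled_campaign(TrajectoryConfig(seed=42), 20)
    return params, meta


@pytest.fixture(scope="session")
def small_cdata(small_campaign, micasense_bands):
    params, meta = small_campaign
    return build_cdata(params, meta=meta, bands=micasense_bands)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
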