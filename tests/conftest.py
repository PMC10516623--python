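import numpy as np
import pytest

from rsfret.simulate import (KineticScheme, PhotophysicsConfig,
                             ScenarioConfig, StateModel)
from rsfret.trace_io import IntensityTrace, TraceEnsemble


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_photo():
    return PhotophysicsConfig()


@pytest.fixture
def quiet_photo():
    """Noise-free, crosstalk-free, bleach-free photophysics for exactness
    checks."""
    return PhotophysicsConfig(noise_sd=0.0, leakage_beta=0.0,
                              direct_excitation_delta=0.0,
                              donor_bleach_rate=0.0, acceptor_bleach_rate=0.0,
                              background_donor=0.0, background_acceptor=0.0)


@pytest.fixture
def crosstalk_photo():
    """Crosstalk and backgrounds on, but zero noise and no bleaching, for
    inversion-property checks."""
    return PhotophysicsConfig(noise_sd=0.0, donor_bleach_rate=0.0,
                              acceptor_bleach_rate=0.0)


@pytest.fixture
def short_scenario():
    return ScenarioConfig(mode="prefolded", duration=1.5)


@pytest.fixture
def minute_scenario():
    return ScenarioConfig(mode="prefolded", duration=60.0)


@pytest.fixture
def default_model():
    return StateModel.default()


def make_trace(donor, acceptor, molecule_id="m0", dt=0.075, **kw):
    return IntensityTrace(molecule_id, np.asarray(donor, float),
                          np.asarray(acceptor, float), dt, **kw)


@pytest.fixture
def tiny_ensemble():
    t0 = make_trace([100, 200, 300, 400], [10, 20, 30, 40], "a")
    t1 = make_trace([5, 6, 7, 8], [50, 60, 70, 80], "b")
    return TraceEnsemble([t0, t1], condition={"ligand_uM": 0.0})
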