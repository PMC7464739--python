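import numpy as np
import pytest

from hccseq import (
    GroundTruth,
    SimConfig,
    WeibullParams,
    gen_weibull_ipd,
    load_profiles,
)
from hccseq.cli_io import build_strategies
from hccseq.markov_model import zero_mortality_life_table


@pytest.fixture(scope="session")
def profiles():
    """Packaged therapy profiles (published Weibull medians/IQRs and SAE rates)."""
    return load_profiles()


@pytest.fixture(scope="session")
def strategy_for(profiles):
    def _make(first: str, second: str):
        return build_strategies(profiles, [(first, second)])[0]

    return _make


@pytest.fixture(scope="session")
def no_background_cfg():
    """Simulation config with background mortality switched off."""
    return SimConfig(life_table=zero_mortality_life_table())


@pytest.fixture()
def small_ipd():
    return gen_weibull_ipd(
        GroundTruth(weibull=WeibullParams(12.0, 1.17), censor_rate=0.2, n=200, seed=7)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
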