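import warnings

import numpy as np
import pytest

from nabstat import (
    HillParams,
    NeutralizationCurve,
    NoiseModel,
    TWOFOLD_SERIES,
    simulate_curve,
)
from nabstat.estimators import McmcSettings

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def truth_116() -> HillParams:
    """Generating Hill parameters with ND50 = 1/16, unit slope, zero floor."""
    return HillParams(midpoint=1 / 16, slope=1.0, bottom=0.0)


@pytest.fixture(scope="session")
def noiseless_curve(truth_116) -> NeutralizationCurve:
    return simulate_curve(truth_116, TWOFOLD_SERIES, 3, NoiseModel(0.0), seed=3)


@pytest.fixture(scope="session")
def noisy_curve(truth_116) -> NeutralizationCurve:
    return simulate_curve(truth_116, TWOFOLD_SERIES, 3, NoiseModel(0.10), seed=1)


@pytest.fixture(scope="session")
def fast_mcmc() -> McmcSettings:
    """Reduced sampler settings for unit tests; defaults are exercised in
    the acceptance suite."""
    return McmcSettings(draws=500, tune=300, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
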