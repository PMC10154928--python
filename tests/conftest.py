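import warnings

import numpy as np
import pytest

from flightpower.aero import Environment, Morphology, STUDY_MORPHOLOGY


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    """Statsmodels convergence chatter is asserted on where relevant, not logged."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        warnings.filterwarnings("ignore", message=".*not be nested.*")
        warnings.filterwarnings("ignore", message=".*not U-shaped.*")
        yield


@pytest.fixture(scope="session")
def bat() -> Morphology:
    """The study animal: 8.9 g bat, 0.23 m span."""
    return STUDY_MORPHOLOGY


@pytest.fixture(scope="session")
def env() -> Environment:
    return Environment()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230045)
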