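import numpy as np
import pytest

from trichofe import CaseConfig, Forcing, ParameterSet


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    """The shipped (calibrated) defaults."""
    return ParameterSet()


@pytest.fixture(scope="session")
def forcing_const() -> Forcing:
    return Forcing(mode="constant", I_const=90.0)


@pytest.fixture(scope="session")
def forcing_sin() -> Forcing:
    return Forcing(mode="sinusoidal")


@pytest.fixture
def case_dynamic() -> CaseConfig:
    return CaseConfig(mode="dynamic", fFe0PS=0.65, fFe0NF=0.15)


@pytest.fixture
def case_fixed() -> CaseConfig:
    return CaseConfig(mode="fixed", fFe0PS=0.65, fFe0NF=0.15)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230706)
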