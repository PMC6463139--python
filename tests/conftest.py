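import numpy as np
import pytest

from dualosc.params import CircuitConfig, InducerCondition, ParameterSet


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def reference_condition() -> InducerCondition:
    """High arabinose, low IPTG: the sustained-oscillation corner."""
    return InducerCondition(arabinose=1.0, iptg=0.01)


@pytest.fixture(scope="session")
def lac_ara_circuit() -> CircuitConfig:
    return CircuitConfig(reporter_kind="lac_ara")


def make_circuit(kind: str, retro: bool = True, share: bool = True) -> CircuitConfig:
    return CircuitConfig(
        reporter_kind=kind, retroactivity_on=retro, protease_sharing_on=share
    )
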