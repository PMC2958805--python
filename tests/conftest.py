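import pytest

from runfuel import (
    RunnerProfile,
    SubstratePartition,
    default_partition,
    load_default_anchors,
)


@pytest.fixture(scope="session")
def partition() -> SubstratePartition:
    return default_partition()


@pytest.fixture(scope="session")
def anchors():
    return load_default_anchors()


@pytest.fixture
def typical_male() -> RunnerProfile:
    """Typical trained male: 21.4% legs at 110 mmol/kg, liver 2.5% at 270."""
    return RunnerProfile()


@pytest.fixture
def fig3_male() -> RunnerProfile:
    """Typical male build with maximally loaded liver (360 kcal/kg)."""
    return RunnerProfile(liver_glycogen_density=500.0)
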