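import numpy as np
import pytest

from cgidp.model_core import (
    ProteinSpec,
    SolutionConditions,
    load_calvados,
    packaged_sequences,
)


@pytest.fixture(scope="session")
def calvados1():
    return load_calvados(1)


@pytest.fixture(scope="session")
def calvados2():
    return load_calvados(2)


@pytest.fixture(scope="session")
def sequences():
    return packaged_sequences()


@pytest.fixture(scope="session")
def conditions_room():
    return SolutionConditions(temperature=293.0, ionic_strength=0.15, pH=7.0)


@pytest.fixture(scope="session")
def spec24(conditions_room):
    """A 24-residue chain (the shortest training-set length)."""
    return ProteinSpec("t24", "MDVFMKGLSKAKEGVVAAAEKTKQ", conditions_room)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
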