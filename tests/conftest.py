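import pytest

from helitube import EnergyParams, TubuleIndices, ideal_dihedrals, ideal_embedding


@pytest.fixture(scope="session")
def target_10_0():
    return TubuleIndices(10, 0)


@pytest.fixture(scope="session")
def angles_10_0(target_10_0):
    return ideal_dihedrals(target_10_0)


@pytest.fixture(scope="session")
def params_10_0(angles_10_0):
    return EnergyParams(theta0=angles_10_0)


@pytest.fixture(scope="session")
def tube_10_0():
    return ideal_embedding(TubuleIndices(10, 0), rows=6)
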