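import numpy as np
import pytest

from kfluoro import materials as mat


@pytest.fixture(scope="session")
def fat():
    return mat.load_material("fat")


@pytest.fixture(scope="session")
def fibrous():
    return mat.load_material("fibrous")


@pytest.fixture(scope="session")
def tumor():
    return mat.load_material("tumor")


@pytest.fixture(scope="session")
def iodine():
    return mat.load_material("iodine")


@pytest.fixture(scope="session")
def silicon():
    return mat.load_material("silicon")


@pytest.fixture(scope="session")
def air():
    return mat.load_material("air")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
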