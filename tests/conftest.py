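import numpy as np
import pytest

from emgcs.bases import BasisMatrix, build_db4_basis, build_dct_basis, build_haar_basis


@pytest.fixture(scope="session")
def dct16() -> BasisMatrix:
    return build_dct_basis(16)


@pytest.fixture(scope="session")
def dct128() -> BasisMatrix:
    return build_dct_basis(128)


@pytest.fixture(scope="session")
def haar64() -> BasisMatrix:
    return build_haar_basis(64)


@pytest.fixture(scope="session")
def db4_64() -> BasisMatrix:
    return build_db4_basis(64)


@pytest.fixture(scope="session")
def db4_256() -> BasisMatrix:
    return build_db4_basis(256)


@pytest.fixture(scope="session")
def identity8() -> BasisMatrix:
    """Canonical (identity) basis: handy when coefficients should equal samples."""
    return BasisMatrix(matrix=np.eye(8), kind="identity")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
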