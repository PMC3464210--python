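import numpy as np
import pytest

from inversionkit.catalog import (
    ArrangementStates,
    build_segment_map,
    gambiae_complex_catalog,
    gambiae_complex_karyotypes,
)


@pytest.fixture(scope="session")
def catalog():
    return gambiae_complex_catalog()


@pytest.fixture(scope="session")
def complex_karyotypes():
    return gambiae_complex_karyotypes()


@pytest.fixture(scope="session")
def op_catalog(catalog):
    """The overlapping 2Ro/2Rp pair on a 5-segment 2R map."""
    return catalog.subset(["2Ro", "2Rp"])


@pytest.fixture(scope="session")
def op_map(op_catalog):
    return build_segment_map(op_catalog, "2R")


@pytest.fixture(scope="session")
def full_maps(catalog):
    return {arm: build_segment_map(catalog, arm) for arm in catalog.arms}


def op_states(name: str, o: str, p: str) -> ArrangementStates:
    return ArrangementStates(name, {"2Ro": o, "2Rp": p})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
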