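import numpy as np
import pytest

from shiftmatch import LibrarySpec, ShiftLibrary, ShiftRecord, generate_library


@pytest.fixture
def toy_records():
    """Two molecules: (3 C, 2 H) and (1 C, 0 H) — the minimal count-index case."""
    return [
        ShiftRecord("m1", (10.0, 20.0, 30.0), (1.0, 2.0)),
        ShiftRecord("m2", (170.5,), ()),
    ]


@pytest.fixture
def toy_library(toy_records):
    return ShiftLibrary(toy_records, solvent="water")


@pytest.fixture(scope="session")
def default_library():
    """The default 300-molecule synthetic study library."""
    return generate_library(LibrarySpec(n_molecules=300, seed=2))


@pytest.fixture(scope="session")
def small_library():
    """A 60-molecule synthetic library for mixture-scale experiments."""
    return generate_library(LibrarySpec(n_molecules=60, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
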