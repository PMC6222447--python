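import numpy as np
import pytest

from rdmpull.structure_io import ToyComplexSpec, generate_toy_complex


@pytest.fixture(scope="session")
def toy_complex():
    """Default bound toy complex (10+4 residues, 0.3 nm gap) + ground truth."""
    return generate_toy_complex(ToyComplexSpec(seed=1))


@pytest.fixture(scope="session")
def toy_structure(toy_complex):
    return toy_complex[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
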