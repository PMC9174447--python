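import numpy as np
import pytest

from molgenlm import molio, taskdata


@pytest.fixture(scope="session")
def druglike_pool() -> molio.MoleculeSet:
    """A small drug-like synthetic pool shared across tests."""
    return taskdata.make_synthetic_pool("druglike", 300, seed=42)


@pytest.fixture(scope="session")
def druglike_1000() -> molio.MoleculeSet:
    """A 1,000-molecule pool for round-trip sweeps."""
    return taskdata.make_synthetic_pool("druglike", 1000, seed=7)


@pytest.fixture(scope="session")
def peptide_pool() -> molio.MoleculeSet:
    return taskdata.make_synthetic_pool("peptide", 40, seed=3, length=19)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
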