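import numpy as np
import pytest

from fcptools.homology import SubstitutionMatrix, default_matrix
from fcptools.seqio import AMINO_ACIDS, ProteinRecord


@pytest.fixture(scope="session")
def blosum62() -> SubstitutionMatrix:
    return default_matrix()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_protein(rng: np.random.Generator, length: int, rec_id: str) -> ProteinRecord:
    seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
    return ProteinRecord(id=rec_id, sequence=seq)


@pytest.fixture(scope="session")
def small_panel():
    """A shared 3-family synthetic panel with held-out queries."""
    from fcptools.synthetic_data import SimulationSpec, simulate_classification_panel

    spec = SimulationSpec(n_families=3, seqs_per_family=10, root_length=150, seed=7)
    return simulate_classification_panel(spec, holdout=3)
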