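import numpy as np
import pytest

from ovolkit.core_io import AlignmentBlock, ProteinRecord
from ovolkit.simulate import SimulationConfig, simulate_family

AA = sorted("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture(scope="session")
def default_family():
    """One simulated six-taxon family at default rates."""
    return simulate_family(SimulationConfig(n_taxa=6, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1)


def random_protein(rng, length, rec_id="r"):
    return ProteinRecord(rec_id, "".join(rng.choice(AA, size=length)))


@pytest.fixture()
def tiny_block():
    return AlignmentBlock(["a", "b", "c"], ["AAAA", "AAAT", "TTTT"])
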