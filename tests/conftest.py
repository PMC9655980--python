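import numpy as np
import pytest

from qsarkit import fixtures
from qsarkit.molio import MoleculeTable


@pytest.fixture(scope="session")
def toy_table() -> MoleculeTable:
    return fixtures.toy_molecules()


@pytest.fixture(scope="session")
def polar_apolar():
    """Tiny two-class set: small polar molecules vs alkanes."""
    smiles = [
        "CCO", "CCN", "CCCO", "NCCO", "CCCN", "OCCO",
        "CCCC", "CCCCC", "CCCCCC", "CC(C)C", "CCC(C)C", "CCCCCCC",
    ]
    y = np.array(["BBB-"] * 6 + ["BBB+"] * 6)
    return MoleculeTable.from_smiles(smiles), y
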