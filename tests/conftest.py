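import pytest
from rdkit import Chem

from metachem.io import Metabolite
from metachem.synth import SynthConfig, generate_metabolite_sets


def met(smiles: str, mid: str = "m", set_label: str = "setA") -> Metabolite:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, f"bad test SMILES: {smiles}"
    return Metabolite(mid, mol, set_label)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A down-scaled generator configuration shared across tests."""
    return SynthConfig(
        n_setA=80,
        n_setB=60,
        n_shared_scaffolds=10,
        n_unique_scaffolds_A=15,
        n_unique_scaffolds_B=12,
        seed=20240915,
    )


@pytest.fixture(scope="session")
def small_sets(small_config):
    return generate_metabolite_sets(small_config)
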