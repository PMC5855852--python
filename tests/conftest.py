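import logging

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from qsar3d.chem import Molecule, assign_atom_parameters, assign_gasteiger_charges

# symmetry-equivalent-match notices are expected on the synthetic series
logging.getLogger("qsar3d.align").setLevel(logging.ERROR)


def mol_from_smiles(smiles: str, name: str = "mol", seed: int = 7) -> Molecule:
    """Embed a SMILES in 3D (explicit hydrogens) as a package Molecule."""
    rdmol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    assert AllChem.EmbedMolecule(rdmol, randomSeed=seed) == 0
    return Molecule.from_rdkit(rdmol, mol_id=name)


def prepared_mol(smiles: str, name: str = "mol", seed: int = 7) -> Molecule:
    """As above, plus Gasteiger charges and field parameters."""
    return assign_atom_parameters(assign_gasteiger_charges(mol_from_smiles(smiles, name, seed)))


@pytest.fixture
def methane():
    return mol_from_smiles("C", "methane")


@pytest.fixture
def rng():
    return np.random.default_rng(20180630)
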