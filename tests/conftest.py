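import random

import pytest

from structaudit import fixtures, labeling
from structaudit.mol import Atom, Bond, Molecule

WATER_SDF = """water
  struaudt          3D

  3  2  0  0  0  0  0  0  0  0999 V2000
   -0.0060    0.3872    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7940   -0.1958    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.8000   -0.1914    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
M  END
$$$$
"""


@pytest.fixture(scope="session")
def builtins():
    return fixtures.builtin_molecules()


@pytest.fixture(scope="session")
def builtin_inchis(builtins):
    return {name: labeling.generate_inchi(mol).inchi for name, mol in builtins.items()}


@pytest.fixture()
def water_sdf_text():
    return WATER_SDF


def permuted(mol: Molecule, seed: int) -> Molecule:
    """Rebuild a molecule with its atoms in a seeded random order."""
    rng = random.Random(seed)
    perm = list(range(1, mol.n_atoms + 1))
    rng.shuffle(perm)
    old_to_new = {old: new for new, old in enumerate(perm, start=1)}
    atoms = [
        Atom(
            element=mol.atoms[old - 1].element,
            formal_charge=mol.atoms[old - 1].formal_charge,
            isotope=mol.atoms[old - 1].isotope,
            x=mol.atoms[old - 1].x,
            y=mol.atoms[old - 1].y,
            z=mol.atoms[old - 1].z,
            index=new,
        )
        for new, old in enumerate(perm, start=1)
    ]
    bonds = [
        Bond(a1=old_to_new[b.a1], a2=old_to_new[b.a2], order=b.order) for b in mol.bonds
    ]
    return Molecule(cid=mol.cid, atoms=atoms, bonds=bonds, is_3d=mol.is_3d, name=mol.name)
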