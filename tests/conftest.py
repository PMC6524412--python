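import numpy as np
import pytest

from tifpscreen.structures import AtomRecord
from tifpscreen.synthetic import ComplexSpec, make_toy_complex

MINIMAL_MOL2 = """\
@<TRIPOS>MOLECULE
minimal
3 0 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
     1 CA     0.0000     0.0000     0.0000 C      1 ALA1   0.0000
     2 O      1.2500     0.0000     0.0000 O      1 ALA1   0.0000
     3 C1     3.0000     1.0000     0.0000 C      2 LIG1   0.0000
"""


@pytest.fixture
def minimal_mol2(tmp_path):
    p = tmp_path / "minimal.mol2"
    p.write_text(MINIMAL_MOL2)
    return p


@pytest.fixture
def mixed_complex():
    """A toy complex with one or two of every interaction class planted."""
    spec = ComplexSpec(n_hyd=2, n_hbd=1, n_hba=1, n_aro=1, n_ion=1, n_met=1,
                       decoy_atoms=8, seed=11)
    return make_toy_complex(spec)


def atom(atom_id, element, pos, role="protein", charge=0, aromatic=False,
         residue_name="UNK", residue_id=1):
    return AtomRecord(atom_id=atom_id, element=element, position=tuple(pos),
                      formal_charge=charge, is_aromatic=aromatic, role=role,
                      residue_name=residue_name, residue_id=residue_id)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def transform_complex(cx, rot, shift):
    from dataclasses import replace
    from tifpscreen.structures import ComplexStructure

    atoms = [
        replace(a, position=tuple(rot @ a.xyz + shift)) for a in cx.atoms
    ]
    return ComplexStructure(structure_id=cx.structure_id, atoms=atoms,
                            target_id=cx.target_id, bonds=cx.bonds)
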