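import numpy as np
import pytest

from ligqc.structure import Atom, LigandInstance, Residue, Structure
from ligqc.synthetic import PocketSpec, gen_pocket

MINIMAL_PDB = """\
HETATM    1  C1  LIG A   1       0.000   0.000   0.000  1.00 20.00           C
HETATM    2  C2  LIG A   1       1.500   0.000   0.000  1.00 20.00           C
HETATM    3  O1  LIG A   1       2.100   1.100   0.000  1.00 25.00           O
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def pocket_structure():
    """Five GLY stubs at a realized min heavy-atom distance of 4.40 Å."""
    return gen_pocket(PocketSpec(seed=7, n_residues=5, target_min_distance=4.40))


@pytest.fixture
def clash_structure():
    """Four pocket residues plus one injected 0.50 Å-overlap clash residue."""
    return gen_pocket(
        PocketSpec(seed=11, n_residues=4, target_min_distance=4.40, n_clashes=1, clash_overlap=0.50)
    )


def single_atom_ligand(element="C", position=(0.0, 0.0, 0.0), b_factor=20.0, occupancy=1.0):
    return LigandInstance(
        het_code="XXX",
        chain_id="L",
        residue_number=1,
        insertion_code="",
        atoms=[Atom("X1", element, np.asarray(position, float), occupancy, b_factor)],
        molecular_weight=12.011,
    )


def carbon_residue(number, positions, chain="A", b_factor=20.0):
    atoms = [
        Atom(f"C{i+1}", "C", np.asarray(p, float), 1.0, b_factor) for i, p in enumerate(positions)
    ]
    return Residue(chain, number, "", "GLY", atoms, is_polymer_amino_acid=True)
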