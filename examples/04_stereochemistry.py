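"""Stereochemical complementarity: clashes, energy, packing density.

Compares a well-packed apolar pose (a carbon ring inside a carbon cage at
comfortable contact distances) with a pocket carrying an injected 0.5 Å
van der Waals overlap.  A favorable pose has no bad clash and a negative
normalized interaction energy; a clash shows up both as a counted contact
and as a positive (repulsive) energy.
"""

import numpy as np

from ligqc import find_binding_site, select_ligands, stereo_report
from ligqc.structure import Atom, LigandInstance, Residue
from ligqc.synthetic import PocketSpec, gen_pocket


def _report(label, lig, site_residues):
    rep = stereo_report(lig, site_residues, grid_spacing=0.25)
    packing = "n/a" if rep.mean_packing_density is None else f"{rep.mean_packing_density:.2f}"
    print(f"{label}: bad clashes={rep.n_bad_clashes}  "
          f"norm. energy={rep.normalized_energy:+.2f} kcal/mol/atom  "
          f"mean packing={packing}  verdict={rep.verdict}")


# A six-carbon ring surrounded by twelve carbon probes at 5.2 Å (just outside
# van der Waals contact): purely dispersive, favorable interactions.
ring = LigandInstance(
    "BNZ", "L", 1, "",
    [Atom(f"C{i+1}", "C", (1.39 * np.cos(a), 1.39 * np.sin(a), 0.0))
     for i, a in enumerate(np.linspace(0, 2 * np.pi, 6, endpoint=False))],
    78.11,
)
cage_dirs = [
    (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0), (1, 0, 1), (1, 0, -1),
    (-1, 0, 1), (-1, 0, -1), (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
]
cage = [
    Residue("A", i + 1, "", "GLY", [Atom("CB", "C", np.array(v) / np.sqrt(2) * 5.2)], True)
    for i, v in enumerate(cage_dirs)
]
_report("well-packed pose", ring, cage)

# A generated pocket with one residue pushed into the ligand by 0.5 Å overlap.
structure = gen_pocket(PocketSpec(seed=11, n_residues=4, n_clashes=1, clash_overlap=0.50))
lig = select_ligands(structure)[0]
site = find_binding_site(structure, lig)
_report("clashing pose   ", lig, site.residues)
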