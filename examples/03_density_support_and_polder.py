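"""Interpret per-atom density-support scores and polder-map correlations.

EDIA values come from an external server and polder correlation triples from
a map-generation pipeline; this package interprets them: per-atom support
categories, the OPIA percentage of well-resolved interconnected atoms, and
the three-map correlation verdict.
"""

from ligqc import EdiaProfile, PolderCCs, compute_opia, edia_support_category, polder_verdict

# A ten-atom chain where half the atoms are well supported: OPIA counts only
# well-resolved atoms in connected fragments of at least two atoms.
atoms = {f"C{i}": (0.9 if i < 5 else 0.3) for i in range(10)}
bonds = [(f"C{i}", f"C{i+1}") for i in range(9)]
profile = EdiaProfile(per_atom_edia=atoms, bond_graph=bonds)
print(f"OPIA = {compute_opia(profile):.0f}%  (5 of 10 atoms in one well-resolved fragment)")

for value in (0.84, 0.40, 0.10):
    print(f"EDIA {value:.2f} -> {edia_support_category(value)}")

# Polder verdicts: cc13 compares the experimental polder map with the
# atoms-present model map; cc23 with the bulk-solvent map.
for ccs in (
    PolderCCs(cc12=0.60, cc13=0.95, cc23=0.55),  # density supports the atoms
    PolderCCs(cc12=0.65, cc13=0.74, cc23=0.65),  # below the 0.8 floor
    PolderCCs(cc12=0.80, cc13=0.82, cc23=0.79),  # dominance margin not met
):
    print(f"CC(1,3)={ccs.cc13:.2f} -> {polder_verdict(ccs).verdict}")
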