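"""Clash detection, surrogate interaction energy, packing density."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ligqc.structure import Atom, LigandInstance, Residue
from ligqc.stereochem import (
    RadiiTable,
    detect_clashes,
    interaction_energy,
    packing_density,
    stereo_report,
)

from .conftest import carbon_residue, single_atom_ligand

CUBOCTAHEDRON = [
    (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
    (1, 0, 1), (1, 0, -1), (-1, 0, 1), (-1, 0, -1),
    (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
]


def _benzene_ligand(b_factor=20.0):
    atoms = [
        Atom(f"C{i+1}", "C", (1.39 * np.cos(a), 1.39 * np.sin(a), 0.0), 1.0, b_factor)
        for i, a in enumerate(np.linspace(0, 2 * np.pi, 6, endpoint=False))
    ]
    return LigandInstance("BNZ", "L", 1, "", atoms, 78.11)


class TestDetectClashes:
    def test_exact_threshold_overlap_is_bad(self):
        lig = single_atom_ligand()
        site = [carbon_residue(1, [(3.00, 0, 0)])]
        records = detect_clashes(lig, site)
        assert len(records) == 1
        assert records[0].overlap == pytest.approx(0.40, abs=1e-9)
        assert records[0].is_bad

    def test_negative_overlap_is_no_clash(self):
        lig = single_atom_ligand()
        assert detect_clashes(lig, [carbon_residue(1, [(3.41, 0, 0)])]) == []

    def test_hbond_distance_donor_acceptor_is_excluded(self):
        lig = single_atom_ligand(element="O")
        res = Residue("A", 1, "", "GLY", [Atom("N", "N", (2.60, 0, 0))], True)
        records = detect_clashes(lig, [res])
        assert len(records) == 1
        rec = records[0]
        assert rec.overlap == pytest.approx(1.52 + 1.55 - 2.60)
        assert rec.hbond_excluded and not rec.is_bad

    def test_hbond_exclusion_can_be_disabled(self):
        lig = single_atom_ligand(element="O")
        res = Residue("A", 1, "", "GLY", [Atom("N", "N", (2.60, 0, 0))], True)
        rec = detect_clashes(lig, [res], exclude_hbonds=False)[0]
        assert rec.is_bad and not rec.hbond_excluded

    def test_carbon_pairs_never_hbond_excluded(self):
        lig = single_atom_ligand()
        rec = detect_clashes(lig, [carbon_residue(1, [(2.9, 0, 0)])])[0]
        assert rec.is_bad

    def test_rigid_motion_invariance(self):
        rot = Rotation.from_euler("zyx", [0.7, -0.2, 1.9]).as_matrix()
        shift = np.array([3.0, -8.0, 5.0])
        lig = single_atom_ligand()
        site = [carbon_residue(1, [(2.95, 0, 0)]), carbon_residue(2, [(0, 3.2, 0)])]
        base = detect_clashes(lig, site)
        lig2 = single_atom_ligand(position=rot @ np.zeros(3) + shift)
        site2 = [
            carbon_residue(r.residue_number, [rot @ a.position + shift for a in r.atoms])
            for r in site
        ]
        moved = detect_clashes(lig2, site2)
        assert [(c.overlap, c.is_bad) for c in base] == pytest.approx(
            [(c.overlap, c.is_bad) for c in moved]
        )

    @pytest.mark.parametrize("threshold", [0.0, 0.2, 0.4, 0.6, 1.0])
    def test_raising_threshold_never_adds_clashes(self, clash_structure, threshold):
        from ligqc.structure import find_binding_site, select_ligands

        lig = select_ligands(clash_structure)[0]
        site = find_binding_site(clash_structure, lig)
        n_low = sum(c.is_bad for c in detect_clashes(lig, site.residues, overlap_threshold=threshold))
        n_default = sum(c.is_bad for c in detect_clashes(lig, site.residues))
        if threshold <= 0.4:
            assert n_low >= n_default
        else:
            assert n_low <= n_default


class TestInteractionEnergy:
    def test_pair_at_lj_minimum(self):
        # C-C contact distance 3.4 Å is the 12-6 minimum: energy = -eps(C,C)
        lig = single_atom_ligand()
        e = interaction_energy(lig, [carbon_residue(1, [(3.4, 0, 0)])])
        assert e.vdw_energy == pytest.approx(-0.15, abs=1e-12)
        assert e.normalized == pytest.approx(-0.15, abs=1e-12)
        assert e.total == pytest.approx(e.vdw_energy + e.electrostatic_energy + e.hbond_energy)

    def test_beyond_cutoff_is_zero(self):
        lig = single_atom_ligand()
        e = interaction_energy(lig, [carbon_residue(1, [(9.0, 0, 0)])])
        assert e.total == 0.0 and e.normalized == 0.0

    def test_clash_pose_is_positive(self):
        lig = single_atom_ligand()
        e = interaction_energy(lig, [carbon_residue(1, [(2.9, 0, 0)])])
        assert e.normalized > 0

    def test_energy_vanishes_with_separation(self):
        lig = _benzene_ligand()
        values = []
        for d in (4.5, 6.0, 7.5, 20.0):
            site = [carbon_residue(1, [(d, 0, 0)])]
            values.append(abs(interaction_energy(lig, site).total))
        assert values == sorted(values, reverse=True)
        assert values[-1] == 0.0

    def test_normalization_by_heavy_atom_count(self):
        lig = _benzene_ligand()
        site = [carbon_residue(1, [(0, 0, 4.0)])]
        e = interaction_energy(lig, site)
        assert e.n_heavy_atoms == 6
        assert e.normalized * 6 == pytest.approx(e.total)

    def test_atom_order_invariance(self):
        lig = _benzene_ligand()
        site = [carbon_residue(1, [(0, 0, 4.0)])]
        e1 = interaction_energy(lig, site).total
        lig.atoms.reverse()
        assert interaction_energy(lig, site).total == pytest.approx(e1)

    def test_coincident_atoms_error(self):
        lig = single_atom_ligand()
        with pytest.raises(ValueError):
            interaction_energy(lig, [carbon_residue(1, [(0.0, 0.0, 0.0)])])

    def test_favorable_pose_in_plausible_band(self):
        # carbon cage around a benzene ring at near-contact distances:
        # normalized energy should land in the plausible [-1, 0] kcal/mol/atom band
        lig = _benzene_ligand()
        site = [
            carbon_residue(i + 1, [np.array(v) / np.sqrt(2) * 5.2 for _ in (0,)])
            for i, v in enumerate(CUBOCTAHEDRON)
        ]
        e = interaction_energy(lig, site)
        assert -1.0 <= e.normalized < 0.0


def _mc_density_oracle(center_r, neighbors, probe=1.4, n=200_000, seed=1234):
    """Monte-Carlo integration of the same cell definition (independent of
    the production grid integrator)."""
    rng = np.random.default_rng(seed)
    cap = center_r + 2 * probe
    pts = rng.uniform(-cap, cap, size=(n, 3))
    d = np.linalg.norm(pts, axis=1)
    keep = d <= cap
    pts, d = pts[keep], d[keep]
    in_cell = np.ones(len(pts), bool)
    for pos, r in neighbors:
        dj = np.linalg.norm(pts - np.asarray(pos), axis=1)
        in_cell &= (d - center_r) <= (dj - r)
    n_cell = in_cell.sum()
    n_vdw = (in_cell & (d <= center_r)).sum()
    return n_vdw / n_cell


class TestPackingDensity:
    def test_isolated_atom_matches_sphere_ratio(self):
        lig = single_atom_ligand()
        rep = packing_density(lig, [])
        closed_form = (1.70 / (1.70 + 2.8)) ** 3
        assert rep.per_atom_density[0][1] == pytest.approx(closed_form, abs=0.01)

    def test_twelve_neighbor_contact_shell(self):
        # carbon with 12 carbons at exact vdW contact (cuboctahedral shell):
        # analytic cell is the FCC Voronoi cell, density = V_sphere / (d^3/sqrt(2))
        lig = single_atom_ligand()
        env = [
            Atom(f"E{i}", "C", np.array(v) / np.sqrt(2) * 3.4)
            for i, v in enumerate(CUBOCTAHEDRON)
        ]
        value = packing_density(lig, env, grid_spacing=0.1).per_atom_density[0][1]
        analytic = (4.0 / 3.0 * np.pi * 1.7**3) / (3.4**3 / np.sqrt(2))
        oracle = _mc_density_oracle(1.7, [(np.array(v) / np.sqrt(2) * 3.4, 1.7) for v in CUBOCTAHEDRON])
        assert value == pytest.approx(analytic, abs=0.02)
        assert value == pytest.approx(oracle, abs=0.02)

    def test_density_in_unit_interval(self, pocket_structure):
        from ligqc.structure import find_binding_site, select_ligands

        lig = select_ligands(pocket_structure)[0]
        site = find_binding_site(pocket_structure, lig)
        env = [a for r in site.residues for a in r.heavy_atoms()]
        rep = packing_density(lig, env)
        for _, v in rep.per_atom_density:
            assert 0.0 < v <= 1.0

    def test_grid_convergence_under_halving(self, pocket_structure):
        from ligqc.structure import find_binding_site, select_ligands

        lig = select_ligands(pocket_structure)[0]
        site = find_binding_site(pocket_structure, lig)
        env = [a for r in site.residues for a in r.heavy_atoms()]
        coarse = dict(packing_density(lig, env, grid_spacing=0.2).per_atom_density)
        fine = dict(packing_density(lig, env, grid_spacing=0.1).per_atom_density)
        for name in coarse:
            assert abs(coarse[name] - fine[name]) < 0.02

    def test_monotone_as_neighbor_approaches(self):
        lig = single_atom_ligand()
        values = []
        for d in (8.0, 6.0, 5.0, 4.5, 4.1, 3.4):
            env = [Atom("E", "C", (d, 0, 0))]
            values.append(packing_density(lig, env).per_atom_density[0][1])
        assert values == sorted(values)

    def test_clashing_atoms_excluded_from_mean(self):
        lig = _benzene_ligand()
        rep = packing_density(lig, [], clashing_atoms={"C1", "C2"})
        assert rep.excluded_atoms == ["C1", "C2"]
        included = [v for name, v in rep.per_atom_density if name not in ("C1", "C2")]
        assert rep.ligand_mean == pytest.approx(float(np.mean(included)))

    def test_bad_grid_spacing(self):
        with pytest.raises(ValueError):
            packing_density(single_atom_ligand(), [], grid_spacing=0.0)


class TestStereoReport:
    def test_well_packed_pose_is_favorable(self):
        lig = _benzene_ligand()
        site = [
            carbon_residue(i + 1, [np.array(v) / np.sqrt(2) * 5.2])
            for i, v in enumerate(CUBOCTAHEDRON)
        ]
        rep = stereo_report(lig, site, grid_spacing=0.25)
        assert rep.n_bad_clashes == 0
        assert rep.normalized_energy < 0
        assert rep.verdict == "favorable"
        assert 0.0 < rep.mean_packing_density <= 1.0

    def test_clashing_pose_is_unfavorable(self, clash_structure):
        from ligqc.structure import find_binding_site, select_ligands

        lig = select_ligands(clash_structure)[0]
        site = find_binding_site(clash_structure, lig)
        rep = stereo_report(lig, site.residues, grid_spacing=0.25)
        assert rep.n_bad_clashes == 1
        assert rep.verdict == "unfavorable"
        assert rep.packing is not None and rep.packing.excluded_atoms

    def test_no_contact_pose(self):
        lig = _benzene_ligand()
        site = [carbon_residue(1, [(30.0, 0, 0)])]
        rep = stereo_report(lig, site, compute_packing=False)
        assert rep.verdict == "no_contact" and rep.normalized_energy == 0.0
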