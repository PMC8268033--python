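"""Technique-independent stereochemical complementarity of a ligand pose.

Three measures, all computed from coordinates alone (no density needed):

* **Bad clashes** — van der Waals overlap ``r_i + r_j - d >= 0.4 Å`` between
  ligand and protein heavy atoms, with donor–acceptor pairs at hydrogen-bond
  distance excluded (crystal inputs usually lack hydrogens, so an element
  pair + distance window stands in for explicit H-bond geometry).
* **Normalized interaction energy** — a pairwise 12-6 dispersion–repulsion
  term (Lorentz–Berthelot combination) plus screened Coulomb electrostatics
  with a distance-dependent dielectric eps(r) = 4r, summed over heavy-atom
  pairs within a cutoff and divided by the ligand heavy-atom count.  This is
  a deliberately simple surrogate with the same contracts as a full
  semi-empirical force field: negative = favorable, positive on steric
  clashes, reported per heavy atom in kcal/mol; parameter tables are
  pluggable so a full force field can be swapped in.
* **Packing density** — per-atom ratio in (0, 1] of van der Waals volume to
  the locally available volume, computed on a cubic grid using the
  additively-weighted (radius-offset) nearest-atom partition capped at
  ``r_atom + 2*probe``; atoms involved in bad clashes are excluded from the
  ligand mean because their densities are unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structure import Atom, LigandInstance, Residue

__all__ = [
    "RadiiTable",
    "ClashRecord",
    "EnergyBreakdown",
    "PackingReport",
    "StereoReport",
    "detect_clashes",
    "interaction_energy",
    "packing_density",
    "stereo_report",
]

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)

_DONOR_ACCEPTOR = {("N", "N"), ("N", "O"), ("O", "N"), ("O", "O"), ("S", "N"), ("S", "O")}
HBOND_WINDOW = (2.4, 3.5)  # Å, heavy-atom donor–acceptor distance


@dataclass
class RadiiTable:
    """Element-wise radii, well depths and fixture partial charges.

    The van der Waals set is a standard one (Bondi-style); the covalent set
    backs the link heuristic; ``epsilon`` (kcal/mol) are 12-6 well depths and
    ``charges`` the default per-element partial charges used only when the
    input carries none — a fixture convention, not chemistry.
    """

    vdw: dict[str, float] = field(
        default_factory=lambda: {
            "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
            "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
        }
    )
    covalent: dict[str, float] = field(
        default_factory=lambda: {"C": 0.77, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07}
    )
    epsilon: dict[str, float] = field(
        default_factory=lambda: {
            "H": 0.02, "C": 0.15, "N": 0.16, "O": 0.20, "S": 0.25,
            "P": 0.20, "F": 0.25, "CL": 0.30, "BR": 0.32, "I": 0.35,
        }
    )
    charges: dict[str, float] = field(
        default_factory=lambda: {"C": 0.0, "N": -0.35, "O": -0.45, "S": -0.15, "H": 0.0}
    )
    default_vdw: float = 1.70
    default_epsilon: float = 0.15

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.vdw.values()) or any(r <= 0 for r in self.covalent.values()):
            raise ValueError("radii must be positive")

    def vdw_radius(self, element: str) -> float:
        return self.vdw.get(element.upper(), self.default_vdw)

    def well_depth(self, element: str) -> float:
        return self.epsilon.get(element.upper(), self.default_epsilon)

    def charge(self, element: str) -> float:
        return self.charges.get(element.upper(), 0.0)


@dataclass
class ClashRecord:
    ligand_atom: str
    protein_atom: str
    distance: float
    overlap: float
    is_bad: bool
    hbond_excluded: bool = False


@dataclass
class EnergyBreakdown:
    vdw_energy: float
    electrostatic_energy: float
    hbond_energy: float
    total: float
    n_heavy_atoms: int
    normalized: float


@dataclass
class PackingReport:
    per_atom_density: list[tuple[str, float]]
    ligand_mean: Optional[float]
    excluded_atoms: list[str] = field(default_factory=list)


@dataclass
class StereoReport:
    n_bad_clashes: int
    normalized_energy: float
    mean_packing_density: Optional[float]
    verdict: str  # favorable | unfavorable | no_contact
    clashes: list[ClashRecord] = field(default_factory=list)
    energy: Optional[EnergyBreakdown] = None
    packing: Optional[PackingReport] = None


def _site_heavy_atoms(site_residues: Sequence[Residue]) -> list[tuple[str, Atom]]:
    out = []
    for res in site_residues:
        for a in res.heavy_atoms():
            out.append((f"{res.entity_key}:{a.name}", a))
    return out


def _is_donor_acceptor(el1: str, el2: str) -> bool:
    return (el1.upper(), el2.upper()) in _DONOR_ACCEPTOR or (el2.upper(), el1.upper()) in _DONOR_ACCEPTOR


def detect_clashes(
    ligand: LigandInstance,
    site_residues: Sequence[Residue],
    radii: Optional[RadiiTable] = None,
    overlap_threshold: float = 0.4,
    exclude_hbonds: bool = True,
) -> list[ClashRecord]:
    """All ligand-heavy/protein-heavy pairs with vdW overlap >= threshold.

    Donor–acceptor element pairs (N/O/S with N/O) at 2.4–3.5 Å are marked
    ``hbond_excluded`` and not reported as bad when ``exclude_hbonds``.
    """
    radii = radii or RadiiTable()
    records: list[ClashRecord] = []
    site_atoms = _site_heavy_atoms(site_residues)
    for lig_atom in ligand.heavy_atoms():
        r1 = radii.vdw_radius(lig_atom.element)
        for key, prot_atom in site_atoms:
            d = float(np.linalg.norm(lig_atom.position - prot_atom.position))
            overlap = r1 + radii.vdw_radius(prot_atom.element) - d
            # inclusive threshold with a guard against representation error
            if overlap < overlap_threshold - 1e-9:
                continue
            hbond = (
                exclude_hbonds
                and _is_donor_acceptor(lig_atom.element, prot_atom.element)
                and HBOND_WINDOW[0] <= d <= HBOND_WINDOW[1]
            )
            records.append(
                ClashRecord(
                    ligand_atom=lig_atom.name,
                    protein_atom=key,
                    distance=d,
                    overlap=overlap,
                    is_bad=not hbond,
                    hbond_excluded=hbond,
                )
            )
    records.sort(key=lambda r: (-r.overlap, r.ligand_atom, r.protein_atom))
    return records


def interaction_energy(
    ligand: LigandInstance,
    site_residues: Sequence[Residue],
    radii: Optional[RadiiTable] = None,
    cutoff: float = 8.0,
    charges: Optional[dict[str, float]] = None,
    include_hbond_term: bool = False,
    hbond_depth: float = 1.0,
    hbond_rmin: float = 2.9,
) -> EnergyBreakdown:
    """Surrogate ligand–site interaction energy, kcal/mol per heavy atom.

    12-6 dispersion–repulsion with r_min = r_i + r_j and eps_ij the geometric
    mean of well depths, plus Coulomb with eps(r) = 4r.  ``charges`` maps
    atom keys (``residue_key:atom`` for site atoms, atom name for the ligand)
    to partial charges; elements fall back to the table defaults.  With
    ``include_hbond_term``, donor–acceptor pairs use a 12-10 well instead of
    the 12-6 term.  Negative total means a favorable pose.
    """
    radii = radii or RadiiTable()
    charges = charges or {}
    site_atoms = _site_heavy_atoms(site_residues)
    lig_heavy = ligand.heavy_atoms()
    if not lig_heavy:
        raise ValueError("ligand has no heavy atoms")

    e_vdw = e_elec = e_hb = 0.0
    for lig_atom in lig_heavy:
        q1 = charges.get(lig_atom.name, radii.charge(lig_atom.element))
        r1 = radii.vdw_radius(lig_atom.element)
        eps1 = radii.well_depth(lig_atom.element)
        for key, prot_atom in site_atoms:
            d = float(np.linalg.norm(lig_atom.position - prot_atom.position))
            if d > cutoff:
                continue
            if d <= 1e-6:
                raise ValueError(
                    f"coincident atoms: ligand {lig_atom.name} / {key}"
                )
            q2 = charges.get(key, radii.charge(prot_atom.element))
            e_elec += COULOMB_CONSTANT * q1 * q2 / (4.0 * d * d)
            eps_ij = float(np.sqrt(eps1 * radii.well_depth(prot_atom.element)))
            is_hb_pair = include_hbond_term and _is_donor_acceptor(lig_atom.element, prot_atom.element)
            if is_hb_pair:
                x = hbond_rmin / d
                e_hb += hbond_depth * (5.0 * x**12 - 6.0 * x**10)
            else:
                rm = r1 + radii.vdw_radius(prot_atom.element)
                x = rm / d
                e_vdw += eps_ij * (x**12 - 2.0 * x**6)
    total = e_vdw + e_elec + e_hb
    n = len(lig_heavy)
    return EnergyBreakdown(
        vdw_energy=e_vdw,
        electrostatic_energy=e_elec,
        hbond_energy=e_hb,
        total=total,
        n_heavy_atoms=n,
        normalized=total / n,
    )


def packing_density(
    ligand: LigandInstance,
    environment_atoms: Sequence[Atom] | Sequence[tuple[str, Atom]],
    radii: Optional[RadiiTable] = None,
    probe: float = 1.4,
    grid_spacing: float = 0.2,
    exclude_clashing: bool = True,
    clashing_atoms: Optional[set[str]] = None,
) -> PackingReport:
    """Per-atom local packing density in (0, 1], grid-integrated.

    For each included ligand heavy atom, space within ``r_atom + 2*probe``
    of the atom is assigned to it where the radius-offset distance ``d - r``
    to this atom is smallest among all atoms (additively weighted Voronoi
    partition); the density is (volume inside the vdW sphere and in the
    cell) / (volume of the cell).  Both volumes are integrated on a cubic
    grid with linear anti-aliasing of the boundary surfaces, so the error
    falls off roughly quadratically in the spacing.  An isolated atom's
    density is the closed-form sphere-volume ratio
    ``(r / (r + 2*probe))**3`` up to grid error.  ``clashing_atoms`` (ligand
    atom names from clash records) are excluded from the mean when
    ``exclude_clashing``.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    h = grid_spacing
    radii = radii or RadiiTable()
    lig_heavy = ligand.heavy_atoms()
    if not lig_heavy:
        raise ValueError("ligand has no heavy atoms")

    env: list[Atom] = []
    for item in environment_atoms:
        atom = item[1] if isinstance(item, tuple) else item
        if not atom.is_hydrogen:
            env.append(atom)

    all_atoms = lig_heavy + env
    all_pos = np.array([a.position for a in all_atoms], dtype=float)
    all_r = np.array([radii.vdw_radius(a.element) for a in all_atoms], dtype=float)

    excluded = set(clashing_atoms or ()) if exclude_clashing else set()
    per_atom: list[tuple[str, float]] = []
    included_values: list[float] = []
    for i, atom in enumerate(lig_heavy):
        r = all_r[i]
        cap = r + 2.0 * probe
        # cubic grid centred on the atom, one guard layer past the cap
        n_steps = int(np.floor(cap / h)) + 1
        axis = np.arange(-n_steps, n_steps + 1) * h
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1) + atom.position
        d_self = np.linalg.norm(pts - atom.position, axis=1)
        keep = d_self <= cap + h
        pts = pts[keep]
        d_self = d_self[keep]
        safe_d = np.maximum(d_self, 1e-9)
        u_self = (pts - atom.position) / safe_d[:, None]
        # fractional occupancy across each boundary surface (anti-aliasing)
        w_cell = np.clip(0.5 + (cap - d_self) / h, 0.0, 1.0)
        offset_self = d_self - r
        for j in range(len(all_atoms)):
            if j == i:
                continue
            sep = np.linalg.norm(all_pos[j] - atom.position)
            if sep > cap + all_r[j] + r:
                continue
            d_j = np.maximum(np.linalg.norm(pts - all_pos[j], axis=1), 1e-9)
            margin = (d_j - all_r[j]) - offset_self
            u_j = (pts - all_pos[j]) / d_j[:, None]
            grad = np.maximum(np.linalg.norm(u_j - u_self, axis=1), 1e-6)
            w_cell *= np.clip(0.5 + margin / (grad * h), 0.0, 1.0)
        w_vdw = np.clip(0.5 + (r - d_self) / h, 0.0, 1.0) * w_cell
        v_cell = float(w_cell.sum())
        if v_cell <= 0:
            value = 1.0  # degenerate: cell vanished entirely inside neighbors
        else:
            value = min(max(float(w_vdw.sum()) / v_cell, 1e-9), 1.0)
        per_atom.append((atom.name, value))
        if atom.name not in excluded:
            included_values.append(value)
    mean = float(np.mean(included_values)) if included_values else None
    return PackingReport(
        per_atom_density=per_atom,
        ligand_mean=mean,
        excluded_atoms=sorted(a.name for a in lig_heavy if a.name in excluded),
    )


def stereo_report(
    ligand: LigandInstance,
    site_residues: Sequence[Residue],
    radii: Optional[RadiiTable] = None,
    overlap_threshold: float = 0.4,
    cutoff: float = 8.0,
    grid_spacing: float = 0.2,
    compute_packing: bool = True,
) -> StereoReport:
    """Combined stereochemistry record for one ligand pose.

    The verdict is ``favorable`` iff there is no bad clash and the normalized
    energy is below zero, ``no_contact`` when no site atom lies within the
    energy cutoff, else ``unfavorable``.
    """
    radii = radii or RadiiTable()
    clashes = detect_clashes(ligand, site_residues, radii, overlap_threshold)
    bad = [c for c in clashes if c.is_bad]
    energy = interaction_energy(ligand, site_residues, radii, cutoff=cutoff)
    packing = None
    mean_density = None
    if compute_packing:
        env = [a for (_, a) in _site_heavy_atoms(site_residues)]
        packing = packing_density(
            ligand,
            env,
            radii,
            grid_spacing=grid_spacing,
            clashing_atoms={c.ligand_atom for c in bad},
        )
        mean_density = packing.ligand_mean

    site_atoms = _site_heavy_atoms(site_residues)
    any_contact = any(
        np.linalg.norm(lig.position - prot.position) <= cutoff
        for lig in ligand.heavy_atoms()
        for _, prot in site_atoms
    )
    if not any_contact:
        verdict = "no_contact"
    elif not bad and energy.normalized < 0:
        verdict = "favorable"
    else:
        verdict = "unfavorable"
    return StereoReport(
        n_bad_clashes=len(bad),
        normalized_energy=energy.normalized,
        mean_packing_density=mean_density,
        verdict=verdict,
        clashes=clashes,
        energy=energy,
        packing=packing,
    )
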