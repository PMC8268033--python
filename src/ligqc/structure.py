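"""Structure data model, file I/O, ligand selection and binding-site extraction.

The quality checks operate on small-molecule ligands bound to protein chains
in a crystal structure.  A *ligand* here is any non-polymer component with at
least one carbon atom and a molecular weight between 70 and 800 Da that is not
on the solvent exclusion list; the *binding site* is the set of polymer
amino-acid residues with at least one heavy atom within 4.5 Å of any ligand
heavy atom.  Covalently bound ligands are detected (connectivity records take
precedence over a covalent-radius distance heuristic) and flagged so that
downstream scoring can report them as not assessable.

Reading and writing of PDB / mmCIF files is delegated to gemmi; this module
only maps gemmi's hierarchy onto the light-weight dataclasses the rest of the
package consumes.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

import gemmi

__all__ = [
    "Atom",
    "Residue",
    "LigandInstance",
    "BindingSite",
    "Connection",
    "Structure",
    "DEFAULT_EXCLUSION_CODES",
    "DEFAULT_COVALENT_RADII",
    "make_entity_key",
    "read_structure",
    "write_structure",
    "compute_molecular_weight",
    "select_ligands",
    "find_binding_site",
    "detect_covalent_link",
]

#: Water plus common carbon-containing cryo-solvents and buffer components.
#: Metal ions and carbon-free anions are removed by the carbon rule instead.
DEFAULT_EXCLUSION_CODES = frozenset(
    {"HOH", "DOD", "EDO", "GOL", "PEG", "PGE", "DMS", "ACT", "MPD", "EOH", "IPA"}
)

#: Single-bond covalent radii (Å) for the covalent-link heuristic.
DEFAULT_COVALENT_RADII = {
    "C": 0.77,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
    "H": 0.37,
    "F": 0.64,
    "CL": 0.99,
    "BR": 1.14,
    "I": 1.33,
    "SE": 1.17,
    "B": 0.82,
}

DEFAULT_COVALENT_TOLERANCE = 0.45  # Å added to the radius sum


def make_entity_key(chain_id: str, residue_number: int, insertion_code: str = "") -> str:
    """Canonical ``chain:resnum[:icode]`` key shared with the metrics tables."""
    icode = (insertion_code or "").strip()
    key = f"{chain_id}:{residue_number}"
    return f"{key}:{icode}" if icode else key


@dataclass
class Atom:
    """One atom site (or alternate location) with its refinement parameters."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0.0:
            raise ValueError(f"atom {self.name}: negative B-factor {self.b_factor}")
        self.element = self.element.upper()
        if self.element == "H" or self.element == "D":
            self.is_hydrogen = True


@dataclass
class Residue:
    chain_id: str
    residue_number: int
    insertion_code: str
    name: str
    atoms: list[Atom]
    is_polymer_amino_acid: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.name} {self.key}: no atoms")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def entity_key(self) -> str:
        return make_entity_key(self.chain_id, self.residue_number, self.insertion_code)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.heavy_atoms()], dtype=float)

    def mean_heavy_b(self) -> float:
        heavy = self.heavy_atoms()
        if not heavy:
            raise ValueError(f"residue {self.entity_key}: no heavy atoms")
        return float(np.mean([a.b_factor for a in heavy]))


@dataclass
class LigandInstance:
    """A selected non-polymer component instance, the unit of assessment."""

    het_code: str
    chain_id: str
    residue_number: int
    insertion_code: str
    atoms: list[Atom]
    molecular_weight: float
    covalent_flag: bool = False
    covalent_partners: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"ligand {self.het_code}: non-positive molecular weight")
        if not self.heavy_atoms():
            raise ValueError(f"ligand {self.het_code}: no heavy atoms")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def entity_key(self) -> str:
        return make_entity_key(self.chain_id, self.residue_number, self.insertion_code)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.heavy_atoms()], dtype=float)

    def mean_heavy_b(self) -> float:
        return float(np.mean([a.b_factor for a in self.heavy_atoms()]))

    def site_occupancies(self) -> dict[str, float]:
        """Total occupancy per atom site, alternate locations summed."""
        totals: dict[str, float] = {}
        for a in self.heavy_atoms():
            totals[a.name] = totals.get(a.name, 0.0) + a.occupancy
        return totals

    def n_atoms_below_full_occupancy(self, tol: float = 1e-9) -> int:
        return sum(1 for occ in self.site_occupancies().values() if occ < 1.0 - tol)


@dataclass
class BindingSite:
    ligand: LigandInstance
    residues: list[Residue]
    radius: float


@dataclass
class Connection:
    """An explicit inter-residue link record (LINK / struct_conn)."""

    kind: str  # e.g. "covale", "metalc", "link"
    partner1: tuple[str, int, str, str]  # chain, resnum, icode, atom name
    partner2: tuple[str, int, str, str]


@dataclass
class Structure:
    entry_id: str
    models: list[list[Residue]]
    deposition_year: Optional[int] = None
    experimental_method: str = ""
    connections: list[Connection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entry_id:
            raise ValueError("entry_id must be non-empty")
        if not self.models:
            raise ValueError("structure has no models")

    def residues(self, model: int = 0) -> list[Residue]:
        return self.models[model]

    def find_residue(self, key: tuple[str, int, str], model: int = 0) -> Optional[Residue]:
        for res in self.models[model]:
            if res.key == key:
                return res
        return None


# ---------------------------------------------------------------------------
# Reading and writing (gemmi-backed)


def _altloc_str(c: str) -> str:
    return "" if c in ("\0", "\x00", "", " ") else c


def _from_gemmi(st: gemmi.Structure) -> Structure:
    models: list[list[Residue]] = []
    n_atoms = 0
    for model in st:
        residues: list[Residue] = []
        for chain in model:
            for res in chain:
                atoms = []
                for a in res:
                    atoms.append(
                        Atom(
                            name=a.name,
                            element=a.element.name,
                            position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                            occupancy=min(max(a.occ, 0.0), 1.0),
                            b_factor=max(a.b_iso, 0.0),
                            altloc=_altloc_str(a.altloc),
                        )
                    )
                n_atoms += len(atoms)
                info = gemmi.find_tabulated_residue(res.name)
                is_aa = bool(info and info.is_amino_acid()) and res.het_flag != "H"
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=_altloc_str(res.seqid.icode),
                        name=res.name,
                        atoms=atoms,
                        is_polymer_amino_acid=is_aa,
                    )
                )
        models.append(residues)
    if n_atoms == 0:
        raise ValueError(f"structure {st.name or '<unnamed>'}: zero atoms")

    connections = []
    for conn in st.connections:
        try:
            p1 = (
                conn.partner1.chain_name,
                conn.partner1.res_id.seqid.num,
                _altloc_str(conn.partner1.res_id.seqid.icode),
                conn.partner1.atom_name,
            )
            p2 = (
                conn.partner2.chain_name,
                conn.partner2.res_id.seqid.num,
                _altloc_str(conn.partner2.res_id.seqid.icode),
                conn.partner2.atom_name,
            )
        except AttributeError:
            continue
        connections.append(Connection(kind=str(conn.type).split(".")[-1].lower(), partner1=p1, partner2=p2))

    info = dict(st.info)
    year = None
    date = info.get("_pdbx_database_status.recvd_initial_deposition_date", "")
    m = re.match(r"(\d{4})", date or "")
    if m:
        year = int(m.group(1))

    return Structure(
        entry_id=st.name or "UNKNOWN",
        models=models,
        deposition_year=year,
        experimental_method=info.get("_exptl.method", ""),
        connections=connections,
    )


def read_structure(path: str | Path, format: Optional[str] = None) -> Structure:
    """Read a PDB or mmCIF file into the package's structure model.

    ``format`` may be ``"pdb"`` or ``"mmcif"``; by default it is detected from
    the file contents/extension.  Occupancies, B-factors and alternate
    locations are preserved; model 1 is the default scope downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        None: gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "cif": gemmi.CoorFormat.Mmcif,
    }.get(format if format is None else format.lower())
    if fmt is None:
        raise ValueError(f"unknown structure format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    return _from_gemmi(st)


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.entry_id
    for i, residues in enumerate(structure.models, start=1):
        model = gemmi.Model(str(i))
        chains: dict[str, gemmi.Chain] = {}
        for res in residues:
            ch = chains.get(res.chain_id)
            if ch is None:
                ch = gemmi.Chain(res.chain_id)
                chains[res.chain_id] = ch
            g_res = gemmi.Residue()
            g_res.name = res.name
            g_res.seqid = gemmi.SeqId(res.residue_number, res.insertion_code or " ")
            g_res.het_flag = "A" if res.is_polymer_amino_acid else "H"
            for a in res.atoms:
                g_at = gemmi.Atom()
                g_at.name = a.name
                g_at.element = gemmi.Element(a.element.capitalize())
                g_at.pos = gemmi.Position(*a.position)
                g_at.occ = a.occupancy
                g_at.b_iso = a.b_factor
                g_at.altloc = a.altloc if a.altloc else "\0"
                g_res.add_atom(g_at)
            ch.add_residue(g_res)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write the structure as fixed-column PDB or mmCIF (via gemmi)."""
    st = _to_gemmi(structure)
    path = Path(path)
    if format.lower() == "pdb":
        st.write_pdb(str(path))
    elif format.lower() in ("mmcif", "cif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown structure format {format!r}")


# ---------------------------------------------------------------------------
# Ligand selection

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _element_mass(symbol: str) -> float:
    el = gemmi.Element(symbol.capitalize())
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol {symbol!r}")
    return el.weight


def compute_molecular_weight(
    atoms: Sequence[Atom], component_formula: Optional[str] = None
) -> float:
    """Molecular weight in Da.

    With a component formula (e.g. ``"C2 H6 O2"``), the formula mass is used,
    which accounts for hydrogens implicit in the model.  Otherwise the masses
    of the atoms actually present are summed, counting each atom site once
    (alternate locations of the same site do not double-count).
    """
    if component_formula:
        total = 0.0
        seen = False
        for sym, count in _FORMULA_TOKEN.findall(component_formula.replace(" ", "")):
            if not sym:
                continue
            seen = True
            total += _element_mass(sym) * (int(count) if count else 1)
        if not seen:
            raise ValueError(f"unparseable formula {component_formula!r}")
        return total
    sites: dict[str, str] = {}
    for a in atoms:
        sites.setdefault(a.name, a.element)
    return sum(_element_mass(el) for el in sites.values())


def select_ligands(
    structure: Structure,
    mw_min: float = 70.0,
    mw_max: float = 800.0,
    require_carbon: bool = True,
    exclusion_codes: Optional[Iterable[str]] = None,
    model: int = 0,
    formulas: Optional[dict[str, str]] = None,
    detect_covalent: bool = True,
) -> list[LigandInstance]:
    """Select assessable small-molecule ligands from one model.

    A residue qualifies when it is not a polymer amino acid, its component
    code is not excluded, it contains at least one carbon atom (when
    ``require_carbon``) and its molecular weight lies inside the inclusive
    bounds ``[mw_min, mw_max]``.  Waters and carbon-free ions fail the carbon
    rule; common solvents fall to the exclusion list.
    """
    excl = DEFAULT_EXCLUSION_CODES if exclusion_codes is None else {c.upper() for c in exclusion_codes}
    formulas = formulas or {}
    out: list[LigandInstance] = []
    for res in structure.residues(model):
        if res.is_polymer_amino_acid:
            continue
        if res.name.upper() in excl:
            continue
        if not res.heavy_atoms():
            continue
        formula = formulas.get(res.name)
        has_carbon = any(a.element == "C" for a in res.atoms) or (
            formula is not None and re.search(r"C(?![a-z])", formula) is not None
        )
        if require_carbon and not has_carbon:
            continue
        mw = compute_molecular_weight(res.atoms, formula)
        if not (mw_min <= mw <= mw_max):
            continue
        lig = LigandInstance(
            het_code=res.name,
            chain_id=res.chain_id,
            residue_number=res.residue_number,
            insertion_code=res.insertion_code,
            atoms=list(res.atoms),
            molecular_weight=mw,
        )
        if detect_covalent:
            flag, partners = detect_covalent_link(structure, lig, model=model)
            lig.covalent_flag = flag
            lig.covalent_partners = partners
        out.append(lig)
    out.sort(key=lambda l: l.key)
    return out


# ---------------------------------------------------------------------------
# Binding-site extraction and covalent-link detection


def find_binding_site(
    structure: Structure,
    ligand: LigandInstance,
    radius: float = 4.5,
    model: int = 0,
) -> BindingSite:
    """Polymer amino-acid residues with a heavy atom within ``radius`` of the
    ligand (inclusive, heavy atoms only; the ligand's own residue excluded).
    """
    if structure.find_residue(ligand.key, model) is None:
        raise ValueError(f"ligand {ligand.entity_key} not found in structure {structure.entry_id}")
    lig_xyz = ligand.heavy_coords()
    members: list[Residue] = []
    for res in structure.residues(model):
        if not res.is_polymer_amino_acid or res.key == ligand.key:
            continue
        xyz = res.heavy_coords()
        if xyz.size and cdist(xyz, lig_xyz).min() <= radius:
            members.append(res)
    members.sort(key=lambda r: r.key)
    return BindingSite(ligand=ligand, residues=members, radius=radius)


def detect_covalent_link(
    structure: Structure,
    ligand: LigandInstance,
    tolerance: float = DEFAULT_COVALENT_TOLERANCE,
    covalent_radii: Optional[dict[str, float]] = None,
    model: int = 0,
) -> tuple[bool, list[tuple[str, str, float]]]:
    """Flag ligands covalently bonded to the polymer.

    Explicit connectivity records (LINK / struct_conn) linking the ligand to a
    polymer residue take precedence; otherwise any ligand heavy atom within
    (covalent-radius sum + ``tolerance``) of a polymer heavy atom triggers the
    flag.  Returns ``(flag, partners)`` with partners as
    ``(ligand atom, residue_key:atom, distance Å)``.
    """
    radii = covalent_radii or DEFAULT_COVALENT_RADII
    partners: list[tuple[str, str, float]] = []

    residues_by_key = {res.key: res for res in structure.residues(model)}

    def _distance(p1: tuple, p2: tuple) -> float:
        out = math.nan
        r1, r2 = residues_by_key.get(p1[:3]), residues_by_key.get(p2[:3])
        if r1 and r2:
            a1 = next((a for a in r1.atoms if a.name == p1[3]), None)
            a2 = next((a for a in r2.atoms if a.name == p2[3]), None)
            if a1 is not None and a2 is not None:
                out = float(np.linalg.norm(a1.position - a2.position))
        return out

    for conn in structure.connections:
        if conn.kind in ("metalc", "hydrog"):
            continue
        for lig_p, other_p in ((conn.partner1, conn.partner2), (conn.partner2, conn.partner1)):
            if lig_p[:3] == ligand.key:
                other_res = residues_by_key.get(other_p[:3])
                if other_res is not None and other_res.is_polymer_amino_acid:
                    partners.append(
                        (
                            lig_p[3],
                            f"{make_entity_key(*other_p[:3])}:{other_p[3]}",
                            _distance(lig_p, other_p),
                        )
                    )
    if partners:
        return True, partners

    lig_heavy = ligand.heavy_atoms()
    for res in structure.residues(model):
        if not res.is_polymer_amino_acid:
            continue
        for prot_atom in res.heavy_atoms():
            r2 = radii.get(prot_atom.element)
            if r2 is None:
                continue
            for lig_atom in lig_heavy:
                r1 = radii.get(lig_atom.element)
                if r1 is None:
                    continue
                d = float(np.linalg.norm(lig_atom.position - prot_atom.position))
                if d <= r1 + r2 + tolerance:
                    partners.append((lig_atom.name, f"{res.entity_key}:{prot_atom.name}", d))
    return (len(partners) > 0), partners
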