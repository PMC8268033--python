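"""Per-entity and global crystallographic metrics: data model, readers, and
derived quantities (OWAB, average occupancy, OPIA, EDIA categories, polder
correlation verdicts).

Local fit metrics come either from a wwPDB-style validation-report XML or
from a simple tab-separated dialect with header
``entity_key rsr rscc avg_occupancy owab resolution r_work r_free year``
(empty cell = metric unavailable).  A metric that is unavailable never
manufactures a penalty downstream; the entity is flagged incomplete instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree

from .structure import Atom

__all__ = [
    "EntityMetrics",
    "GlobalMetrics",
    "MetricsRecord",
    "EdiaProfile",
    "PolderCCs",
    "PolderVerdict",
    "compute_owab",
    "compute_avg_occupancy",
    "read_validation_xml",
    "read_metrics_tsv",
    "write_metrics_tsv",
    "compute_opia",
    "edia_support_category",
    "polder_verdict",
    "TSV_COLUMNS",
]

TSV_COLUMNS = [
    "entity_key",
    "rsr",
    "rscc",
    "avg_occupancy",
    "owab",
    "resolution",
    "r_work",
    "r_free",
    "year",
]


@dataclass
class EntityMetrics:
    """Per-entity (ligand or residue) local fit metrics.

    ``None`` means the metric is unavailable; availability drives the
    incomplete flag in scoring.
    """

    entity_key: str
    rsr: Optional[float] = None
    rscc: Optional[float] = None
    avg_occupancy: Optional[float] = None
    owab: Optional[float] = None
    per_atom: Optional[list[tuple[float, float]]] = None  # (occupancy, B)

    def __post_init__(self) -> None:
        if self.rscc is not None and not -1.0 <= self.rscc <= 1.0:
            raise ValueError(f"{self.entity_key}: RSCC {self.rscc} outside [-1, 1]")

    @property
    def available(self) -> dict[str, bool]:
        return {
            "rsr": self.rsr is not None,
            "rscc": self.rscc is not None,
            "avg_occupancy": self.avg_occupancy is not None,
            "owab": self.owab is not None,
        }


@dataclass
class GlobalMetrics:
    """Entry-level metrics shared by every entity of a structure."""

    resolution: Optional[float] = None
    r_work: Optional[float] = None
    r_free: Optional[float] = None
    deposition_year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError(f"non-positive resolution {self.resolution}")

    @property
    def r_free_minus_r_work(self) -> Optional[float]:
        if self.r_free is None or self.r_work is None:
            return None
        return self.r_free - self.r_work


@dataclass
class MetricsRecord:
    entity: EntityMetrics
    global_metrics: GlobalMetrics


# ---------------------------------------------------------------------------
# Derived per-entity quantities


def compute_owab(per_atom: Sequence[tuple[float, float]]) -> float:
    """Occupancy-weighted average B-factor: sum(occ*B)/sum(occ) over atoms."""
    if not per_atom:
        raise ValueError("no atoms")
    occ = np.asarray([p[0] for p in per_atom], dtype=float)
    b = np.asarray([p[1] for p in per_atom], dtype=float)
    total = occ.sum()
    if total <= 0:
        raise ValueError("all occupancies zero; OWAB undefined")
    return float((occ * b).sum() / total)


def compute_avg_occupancy(atoms: Iterable) -> float:
    """Mean occupancy over atom sites, summing alternate locations per site.

    Accepts either :class:`~ligqc.structure.Atom` objects (sites keyed by atom
    name) or ``(site_key, occupancy)`` pairs.  Full-occupancy disorder (A 0.5
    + B 0.5) therefore counts as occupancy 1.0, not 0.5.
    """
    totals: dict[object, float] = {}
    n = 0
    for item in atoms:
        if isinstance(item, Atom):
            key, occ = item.name, item.occupancy
        else:
            key, occ = item
        if key not in totals:
            n += 1
        totals[key] = totals.get(key, 0.0) + float(occ)
    if n == 0:
        raise ValueError("no atoms")
    return float(sum(totals.values()) / n)


# ---------------------------------------------------------------------------
# Readers


def _opt_float(text: Optional[str]) -> Optional[float]:
    if text is None or str(text).strip() in ("", "NaN", "nan", "?", "."):
        return None
    return float(text)


def read_validation_xml(path: str | Path) -> dict[str, MetricsRecord]:
    """Read entity metrics from a wwPDB-style validation report XML.

    Per-residue/per-ligand records come from ``ModelledSubgroup`` elements
    (attributes ``chain``, ``resnum``, ``icode``, ``rscc``, ``rsr``, ``owab``,
    ``avgoccu``); entry-level metrics from the ``Entry`` element
    (``PDB-resolution``, ``PDB-R``, ``PDB-Rfree``, and optionally
    ``PDB-deposition-date``).  Missing attributes simply leave the metric
    unavailable.
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ValueError(f"cannot parse validation XML {path}: {exc}") from exc
    root = tree.getroot()
    entry = root if root.tag == "Entry" else root.find(".//Entry")
    if entry is None:
        raise ValueError(f"{path}: no <Entry> element")

    year = None
    date = entry.get("PDB-deposition-date")
    if date:
        year = int(date[:4])
    gm = GlobalMetrics(
        resolution=_opt_float(entry.get("PDB-resolution")),
        r_work=_opt_float(entry.get("PDB-R")),
        r_free=_opt_float(entry.get("PDB-Rfree")),
        deposition_year=year,
    )

    records: dict[str, MetricsRecord] = {}
    for sub in root.iter("ModelledSubgroup"):
        chain = sub.get("chain")
        resnum = sub.get("resnum")
        if chain is None or resnum is None:
            continue
        icode = (sub.get("icode") or "").strip()
        key = f"{chain}:{int(resnum)}" + (f":{icode}" if icode else "")
        em = EntityMetrics(
            entity_key=key,
            rsr=_opt_float(sub.get("rsr")),
            rscc=_opt_float(sub.get("rscc")),
            avg_occupancy=_opt_float(sub.get("avgoccu")),
            owab=_opt_float(sub.get("owab")),
        )
        records[key] = MetricsRecord(entity=em, global_metrics=gm)
    if not records:
        raise ValueError(f"{path}: no entities found")
    return records


def read_metrics_tsv(path: str | Path) -> dict[str, MetricsRecord]:
    """Read the tab-separated metrics dialect.

    Mandatory column: ``entity_key``.  Empty cells mark unavailable metrics.
    Unknown columns are ignored with a warning.  Each row carries its own
    entry-level values so mixed-entry tables are representable.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "entity_key" not in df.columns:
        raise ValueError(f"{path}: mandatory column 'entity_key' missing")
    unknown = [c for c in df.columns if c not in TSV_COLUMNS]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
    records: dict[str, MetricsRecord] = {}
    for _, row in df.iterrows():
        def get(col: str) -> Optional[float]:
            if col not in df.columns:
                return None
            val = row[col]
            if pd.isna(val):
                return None
            return _opt_float(val)

        key = str(row["entity_key"])
        year = get("year")
        em = EntityMetrics(
            entity_key=key,
            rsr=get("rsr"),
            rscc=get("rscc"),
            avg_occupancy=get("avg_occupancy"),
            owab=get("owab"),
        )
        gm = GlobalMetrics(
            resolution=get("resolution"),
            r_work=get("r_work"),
            r_free=get("r_free"),
            deposition_year=int(year) if year is not None else None,
        )
        records[key] = MetricsRecord(entity=em, global_metrics=gm)
    return records


def write_metrics_tsv(records: dict[str, MetricsRecord], path: str | Path) -> None:
    rows = []
    for key, rec in records.items():
        gm = rec.global_metrics
        rows.append(
            {
                "entity_key": key,
                "rsr": rec.entity.rsr,
                "rscc": rec.entity.rscc,
                "avg_occupancy": rec.entity.avg_occupancy,
                "owab": rec.entity.owab,
                "resolution": gm.resolution,
                "r_work": gm.r_work,
                "r_free": gm.r_free,
                "year": gm.deposition_year,
            }
        )
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Electron-density support scores (consumed, not computed from maps)


@dataclass
class EdiaProfile:
    """Per-atom density-support scores with the ligand's heavy-atom bond graph."""

    per_atom_edia: dict[str, float]
    bond_graph: list[tuple[str, str]] = field(default_factory=list)
    ediam: Optional[float] = None
    opia: Optional[float] = None

    def __post_init__(self) -> None:
        if self.opia is not None and not 0.0 <= self.opia <= 100.0:
            raise ValueError(f"OPIA {self.opia} outside [0, 100]")


def compute_opia(
    profile: EdiaProfile,
    well_resolved_threshold: float = 0.8,
    min_component_size: int = 2,
) -> float:
    """Overall percentage of well-resolved interconnected atoms.

    Atoms with EDIA >= threshold are well-resolved; only those lying in
    connected components (of the bond graph restricted to well-resolved
    atoms) of size >= ``min_component_size`` count.  Distinguishes overall
    poorly supported ligands from ligands with unsupported substructures.
    """
    atoms = profile.per_atom_edia
    if not atoms:
        raise ValueError("empty atom set")
    unknown = {a for edge in profile.bond_graph for a in edge} - set(atoms)
    if unknown:
        raise ValueError(f"bond graph references atoms without EDIA values: {sorted(unknown)}")
    good = {a for a, v in atoms.items() if v >= well_resolved_threshold}
    g = nx.Graph()
    g.add_nodes_from(good)
    g.add_edges_from((u, v) for u, v in profile.bond_graph if u in good and v in good)
    counted = sum(len(c) for c in nx.connected_components(g) if len(c) >= min_component_size)
    return 100.0 * counted / len(atoms)


def edia_support_category(value: float) -> str:
    """Map an EDIA/EDIAm value to its support category.

    >= 0.8 satisfactory; 0.4 <= value < 0.8 medium; < 0.4 poor.
    """
    if not np.isfinite(value):
        raise ValueError(f"non-finite EDIA value {value}")
    if value >= 0.8:
        return "satisfactory"
    if value >= 0.4:
        return "medium"
    return "poor"


# ---------------------------------------------------------------------------
# Polder OMIT-map correlation interpretation


@dataclass
class PolderCCs:
    """Correlations between the three polder-procedure maps.

    m1: calculated assuming the omitted atoms present; m2: assuming them
    absent (bulk solvent); m3: the polder map from experimental data.
    """

    cc12: float
    cc13: float
    cc23: float

    def __post_init__(self) -> None:
        for name in ("cc12", "cc13", "cc23"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [-1, 1]")


@dataclass
class PolderVerdict:
    verdict: str  # omitted_atoms_supported | bulk_solvent_or_noise | ambiguous
    mobile_atom_caveat: bool = False

    def __str__(self) -> str:
        if self.mobile_atom_caveat:
            return f"{self.verdict} (caveat: high ligand B-factor, map may be smeared)"
        return self.verdict


def polder_verdict(
    ccs: PolderCCs,
    margin: float = 0.05,
    floor: float = 0.8,
    b_ratio: Optional[float] = None,
    flag_ratio: float = 1.5,
) -> PolderVerdict:
    """Interpret the three map correlations.

    The omitted atoms are supported when the experimental polder map
    correlates with the atoms-present map sufficiently better than either
    other pair (dominance >= ``margin``) and CC(1,3) clears ``floor``.
    A CC(1,3) below the floor, or the bulk-solvent map correlating better by
    the margin, indicates bulk solvent or noise; anything else is ambiguous.
    When the ligand's mean B-factor exceeds the site mean by ``flag_ratio``
    (pass ``b_ratio``), the verdict carries a mobile-atom smearing caveat.
    """
    dominance = ccs.cc13 - max(ccs.cc12, ccs.cc23)
    if dominance >= margin and ccs.cc13 >= floor:
        verdict = "omitted_atoms_supported"
    elif ccs.cc13 < floor or (ccs.cc23 - ccs.cc13) >= margin:
        verdict = "bulk_solvent_or_noise"
    else:
        verdict = "ambiguous"
    caveat = b_ratio is not None and b_ratio >= flag_ratio
    return PolderVerdict(verdict=verdict, mobile_atom_caveat=caveat)
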