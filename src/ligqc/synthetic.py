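"""Seeded generators for every input the pipeline consumes.

Three generator families, each a pure function of its spec (one explicit
seed, numpy's PCG64 generator, no global state):

* :func:`gen_pocket` — toy binding pockets: a rigid small-molecule template
  at the origin surrounded by glycine-like residue stubs (N, CA, C, O, CB)
  placed on a shell so the realized minimum ligand–residue heavy-atom
  distance matches a target to within 0.01 Å, with optional injected steric
  clashes of prescribed overlap.
* :func:`gen_metrics` — per-entity metric tables realizing a prescribed
  violation subset of the seven checks (or Good/Dubious/Bad category
  quotas), with every value sampled strictly on the intended side of its
  limit by a margin of at least 5% of the limit's magnitude, plus a sidecar
  of expected scores.
* :func:`gen_survey` — survey record sets drawn from prescribed pair-category
  probabilities with a sidecar of exact realized counts.

These emulate the *structure* of real inputs (keys, dialects, violation
patterns), not crystallographic physics; see the methods note for what that
implies about test coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import EntityMetrics, GlobalMetrics, MetricsRecord, write_metrics_tsv
from .quality import CheckLimits, categorize
from .structure import Atom, Residue, Structure
from .survey import SurveyRecord, write_survey_tsv

__all__ = [
    "PocketSpec",
    "MetricsSpec",
    "SurveySpec",
    "MetricsDataset",
    "SurveyDataset",
    "DEFAULT_PAIR_PROBABILITIES",
    "gen_pocket",
    "gen_metrics",
    "gen_survey",
    "feasible_violation_sets",
]

# ---------------------------------------------------------------------------
# Pockets

#: Rigid default ligand template: a six-carbon ring plus one exocyclic oxygen
#: (88.06 Da — inside the 70-800 Da selection window, carbon rule satisfied).
DEFAULT_LIGAND_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    ("C1", "C", (1.390, 0.000, 0.0)),
    ("C2", "C", (0.695, 1.204, 0.0)),
    ("C3", "C", (-0.695, 1.204, 0.0)),
    ("C4", "C", (-1.390, 0.000, 0.0)),
    ("C5", "C", (-0.695, -1.204, 0.0)),
    ("C6", "C", (0.695, -1.204, 0.0)),
    ("O1", "O", (2.620, 0.000, 0.0)),
]

# Glycine-like stub in local coordinates (N, CA, C, O backbone + one CB).
_STUB_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    ("N", "N", (0.0, 0.0, 0.0)),
    ("CA", "C", (1.46, 0.0, 0.0)),
    ("C", "C", (2.00, 1.35, 0.0)),
    ("O", "O", (3.22, 1.45, 0.0)),
    ("CB", "C", (1.95, -0.75, 1.15)),
]

_VDW_C = 1.70  # matches the default RadiiTable carbon radius


@dataclass
class PocketSpec:
    seed: int = 0
    n_residues: int = 5
    ligand_template: list[tuple[str, str, tuple[float, float, float]]] = field(
        default_factory=lambda: list(DEFAULT_LIGAND_TEMPLATE)
    )
    target_min_distance: float = 4.4  # Å, realized to within 0.01
    n_clashes: int = 0
    clash_overlap: float = 0.5  # Å vdW overlap of each injected clash
    radius_jitter: float = 0.0  # Å added (uniformly) to residues after the first
    entry_id: str = "SYN1"


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (golden-spiral points on the sphere)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _min_distance(stub_local: np.ndarray, direction: np.ndarray, t: float, lig_xyz: np.ndarray) -> float:
    pts = stub_local + direction * t
    diff = pts[:, None, :] - lig_xyz[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def gen_pocket(spec: PocketSpec) -> Structure:
    """Deterministic toy pocket with controlled geometry.

    The ligand template sits at the origin; each residue stub is pushed out
    along its own shell direction until the minimum heavy-atom distance to
    the ligand equals the target (plus jitter for residues after the first),
    found by bisection to 1e-4 Å.  Injected clash residues place their CB
    carbon at ``r_CB + r_target - overlap`` from a ligand atom.
    """
    if spec.n_residues < 1:
        raise ValueError("need at least one residue")
    if spec.n_clashes and not 0.0 < spec.clash_overlap < 2 * _VDW_C:
        raise ValueError(
            f"clash overlap {spec.clash_overlap} infeasible (must be in (0, {2*_VDW_C}))"
        )
    rng = np.random.default_rng(spec.seed)

    lig_atoms = [
        Atom(name=n, element=el, position=np.array(xyz), occupancy=1.0, b_factor=20.0)
        for n, el, xyz in spec.ligand_template
    ]
    lig_xyz = np.array([a.position for a in lig_atoms if not a.is_hydrogen])

    residues: list[Residue] = [
        Residue(
            chain_id="L",
            residue_number=1,
            insertion_code="",
            name="LIG",
            atoms=lig_atoms,
            is_polymer_amino_acid=False,
        )
    ]

    stub_local = np.array([xyz for _, _, xyz in _STUB_TEMPLATE], dtype=float)
    stub_local -= stub_local.mean(axis=0)
    directions = _fibonacci_directions(spec.n_residues + spec.n_clashes)

    resnum = 0
    for i in range(spec.n_residues):
        resnum += 1
        u = directions[i]
        target = spec.target_min_distance
        if i > 0 and spec.radius_jitter > 0:
            target += spec.radius_jitter * rng.random()
        lo, hi = 0.0, 60.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _min_distance(stub_local, u, mid, lig_xyz) < target:
                lo = mid
            else:
                hi = mid
        t = 0.5 * (lo + hi)
        atoms = [
            Atom(
                name=name,
                element=el,
                position=stub_local[k] + u * t,
                occupancy=1.0,
                b_factor=float(15.0 + 10.0 * rng.random()),
            )
            for k, (name, el, _) in enumerate(_STUB_TEMPLATE)
        ]
        residues.append(
            Residue(
                chain_id="A",
                residue_number=resnum,
                insertion_code="",
                name="GLY",
                atoms=atoms,
                is_polymer_amino_acid=True,
            )
        )

    vdw = {"C": 1.70, "N": 1.55, "O": 1.52}
    for j in range(spec.n_clashes):
        resnum += 1
        u = directions[spec.n_residues + j]
        # ligand heavy atom pointing most along this shell direction
        proj = lig_xyz @ u
        target_idx = int(np.argmax(proj))
        target_atom = lig_atoms[target_idx]
        d_clash = vdw["C"] + vdw[target_atom.element] - spec.clash_overlap
        cb_pos = lig_xyz[target_idx] + u * d_clash
        offsets = {"CB": 0.0, "CA": 1.5, "N": 2.4, "C": 2.9, "O": 4.0}
        atoms = [
            Atom(
                name=name,
                element=el,
                position=cb_pos + u * offsets[name],
                occupancy=1.0,
                b_factor=float(15.0 + 10.0 * rng.random()),
            )
            for name, el, _ in _STUB_TEMPLATE
        ]
        residues.append(
            Residue(
                chain_id="A",
                residue_number=resnum,
                insertion_code="",
                name="GLY",
                atoms=atoms,
                is_polymer_amino_acid=True,
            )
        )

    return Structure(entry_id=spec.entry_id, models=[residues])


# ---------------------------------------------------------------------------
# Metric tables

_ALL_CHECKS = ("a", "b", "c", "d", "e", "f", "g")


def feasible_violation_sets() -> list[frozenset[str]]:
    """Every violation subset realizable by a single metrics record.

    Check (a) (RSR > 0.4) implies check (b) (RSR > 0.24), so subsets with
    'a' but not 'b' cannot be realized; 96 of the 128 subsets remain.
    """
    out = []
    for mask in range(128):
        s = frozenset(c for k, c in enumerate(_ALL_CHECKS) if mask >> k & 1)
        if "a" in s and "b" not in s:
            continue
        out.append(s)
    return out


@dataclass
class MetricsSpec:
    seed: int = 0
    n_entities: int = 10
    prescriptions: Optional[Sequence[frozenset[str] | set[str]]] = None
    quotas: Optional[dict[str, float]] = None  # Good/Dubious/Bad proportions
    margin_frac: float = 0.05
    limits: CheckLimits = field(default_factory=CheckLimits)
    entity_keys: Optional[Sequence[str]] = None


@dataclass
class MetricsDataset:
    records: dict[str, MetricsRecord]
    expected: pd.DataFrame  # entity_key, score, violated, category

    def write_tsv(self, path: str | Path) -> None:
        write_metrics_tsv(self.records, path)

    def write_sidecar(self, path: str | Path) -> None:
        self.expected.to_csv(path, sep="\t", index=False)


def _sample_record(
    key: str,
    violations: frozenset[str],
    limits: CheckLimits,
    margin_frac: float,
    rng: np.random.Generator,
) -> MetricsRecord:
    m = margin_frac
    u = rng.uniform

    if "a" in violations:
        rsr = u(limits.max_rsr * (1 + m), limits.max_rsr * 1.5)
    elif "b" in violations:
        rsr = u(limits.max_good_rsr * (1 + m), limits.max_rsr * (1 - m))
    else:
        rsr = u(0.05, limits.max_good_rsr * (1 - m))

    if "c" in violations:
        rscc = u(0.2, limits.min_good_rscc * (1 - m))
    else:
        rscc = u(min(limits.min_good_rscc * (1 + m), 1.0), 1.0)

    occ = u(0.3, limits.required_avg_occupancy * (1 - m)) if "d" in violations else limits.required_avg_occupancy

    if "e" in violations:
        owab = u(limits.max_owab * (1 + m), limits.max_owab * 2)
    else:
        owab = u(10.0, limits.max_owab * (1 - m))

    if "f" in violations:
        r_free = u(limits.max_r_free * (1 + m), limits.max_r_free * 1.4)
    else:
        r_free = u(0.15, limits.max_r_free * (1 - m))

    d_lim = limits.max_r_free_minus_r_work
    delta = u(d_lim * (1 + m), d_lim * 2) if "g" in violations else u(d_lim * 0.1, d_lim * (1 - m))

    return MetricsRecord(
        entity=EntityMetrics(
            entity_key=key,
            rsr=float(rsr),
            rscc=float(rscc),
            avg_occupancy=float(occ),
            owab=float(owab),
        ),
        global_metrics=GlobalMetrics(
            resolution=float(u(1.0, 3.0)),
            r_work=float(r_free - delta),
            r_free=float(r_free),
            deposition_year=int(rng.integers(2000, 2020)),
        ),
    )


def _largest_remainder(proportions: Sequence[float], n: int) -> list[int]:
    raw = np.asarray(proportions, dtype=float)
    raw = raw / raw.sum() * n
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for i in order[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def gen_metrics(spec: MetricsSpec) -> MetricsDataset:
    """Metric table realizing prescribed violation sets (or category quotas).

    Every generated record, when scored against ``spec.limits``, reproduces
    exactly its prescribed violated-check set; the sidecar lists expected
    score, violated set and category per entity.  Prescriptions with 'a' but
    not 'b' are rejected as unrealizable (a single RSR value above 0.4 is
    necessarily above 0.24).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.prescriptions is not None:
        prescriptions = [frozenset(s) for s in spec.prescriptions]
        if not prescriptions:
            raise ValueError("empty prescription list")
        n = len(prescriptions)
    elif spec.quotas is not None:
        cats = ("Good", "Dubious", "Bad")
        unknown = set(spec.quotas) - set(cats)
        if unknown:
            raise ValueError(f"unknown quota categories {sorted(unknown)}")
        counts = _largest_remainder([spec.quotas.get(c, 0.0) for c in cats], spec.n_entities)
        feasible = feasible_violation_sets()
        by_score: dict[int, list[frozenset[str]]] = {}
        for s in feasible:
            by_score.setdefault(len(s), []).append(s)
        for k in by_score:
            by_score[k].sort(key=sorted)
        pool = {
            "Good": [frozenset()],
            "Dubious": by_score[1] + by_score[2],
            "Bad": [s for k in range(3, 8) for s in by_score.get(k, [])],
        }
        prescriptions = []
        for cat, count in zip(cats, counts):
            options = pool[cat]
            idx = rng.integers(0, len(options), size=count)
            prescriptions.extend(options[i] for i in idx)
        n = spec.n_entities
    else:
        raise ValueError("spec must carry prescriptions or quotas")

    bad = [s for s in prescriptions if "a" in s and "b" not in s]
    if bad:
        raise ValueError(f"unrealizable prescriptions (a without b): {[sorted(s) for s in bad]}")

    keys = list(spec.entity_keys) if spec.entity_keys else [f"E{i+1}" for i in range(n)]
    if len(keys) != n:
        raise ValueError("entity_keys length must match the number of prescriptions")

    records: dict[str, MetricsRecord] = {}
    expected_rows = []
    for key, viol in zip(keys, prescriptions):
        records[key] = _sample_record(key, viol, spec.limits, spec.margin_frac, rng)
        expected_rows.append(
            {
                "entity_key": key,
                "score": len(viol),
                "violated": "".join(sorted(viol)),
                "category": categorize(len(viol)),
            }
        )
    return MetricsDataset(records=records, expected=pd.DataFrame(expected_rows))


# ---------------------------------------------------------------------------
# Survey record sets

#: Default pair-category mix shaped like a realistic archive-wide survey
#: (ligand margins 27/51/22, low-attention rollup about two thirds).
DEFAULT_PAIR_PROBABILITIES: dict[str, float] = {
    "GG": 0.11, "GD": 0.14, "GB": 0.02,
    "DG": 0.14, "DD": 0.28, "DB": 0.09,
    "BG": 0.02, "BD": 0.09, "BB": 0.11,
}


@dataclass
class SurveySpec:
    seed: int = 0
    n_records: int = 1000
    year_range: tuple[int, int] = (2000, 2019)
    resolution_mean: float = 2.1
    resolution_sd: float = 0.6
    resolution_bounds: tuple[float, float] = (0.8, 4.5)
    pair_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_PROBABILITIES)
    )

    def __post_init__(self) -> None:
        total = sum(self.pair_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pair probabilities sum to {total}, expected 1")


@dataclass
class SurveyDataset:
    records: list[SurveyRecord]
    counts_by_code: dict[str, int]
    counts_by_year_code: dict[str, dict[str, int]]  # year -> code -> count

    def write_tsv(self, path: str | Path) -> None:
        write_survey_tsv(self.records, path)

    def write_sidecar(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_records": len(self.records),
                    "counts_by_code": self.counts_by_code,
                    "counts_by_year_code": self.counts_by_year_code,
                },
                indent=1,
                sort_keys=True,
            )
        )


def _score_for_category(cat: str, rng: np.random.Generator) -> int:
    if cat == "G":
        return 0
    if cat == "D":
        return int(rng.integers(1, 3))
    return int(rng.integers(3, 8))


def gen_survey(spec: SurveySpec) -> SurveyDataset:
    """Survey records drawn per the prescribed pair-category probabilities."""
    rng = np.random.default_rng(spec.seed)
    codes = sorted(spec.pair_probabilities)
    probs = np.array([spec.pair_probabilities[c] for c in codes])
    draws = rng.choice(len(codes), size=spec.n_records, p=probs)
    lo, hi = spec.resolution_bounds
    records: list[SurveyRecord] = []
    counts: dict[str, int] = {c: 0 for c in codes}
    by_year: dict[str, dict[str, int]] = {}
    for i, k in enumerate(draws):
        code = codes[k]
        year = int(rng.integers(spec.year_range[0], spec.year_range[1] + 1))
        resolution = float(np.clip(rng.normal(spec.resolution_mean, spec.resolution_sd), lo, hi))
        rec = SurveyRecord(
            entry_id=f"S{i+1:05d}",
            deposition_year=year,
            resolution=round(resolution, 2),
            ligand_score=_score_for_category(code[0], rng),
            site_score=_score_for_category(code[1], rng),
            pair_code=code,
        )
        records.append(rec)
        counts[code] += 1
        by_year.setdefault(str(year), {}).setdefault(code, 0)
        by_year[str(year)][code] += 1
    return SurveyDataset(records=records, counts_by_code=counts, counts_by_year_code=by_year)
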