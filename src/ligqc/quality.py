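"""Seven-check penalty scoring of ligands and binding-site residues.

Each entity (ligand or site residue) is checked against seven limits:

    (a) RSR <= 0.4            (c) RSCC >= 0.9        (f) R_free <= 0.3
    (b) RSR <= 0.24 ('Good')  (d) avg occupancy = 1  (g) R_free - R_work <= 0.05
                              (e) OWAB <= 50 Å²

Every violated check adds one penalty point; equality at a limit passes.
An RSR above 0.4 violates both (a) and (b) — the two RSR limits are distinct
parameters, and only that reading makes the maximum single-entity score of 7
attainable.  The global checks (f) and (g) contribute to every entity of the
entry for the same reason.  Scores map to categories as Good (0),
Dubious (1-2), Bad (>2).  A binding site inherits the worst residue score;
the ligand and site categories combine into the nine-class pair code
(GG ... BB).  Checks whose inputs are unavailable are skipped and flag the
entity incomplete — absence of evidence never manufactures a penalty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import EntityMetrics, GlobalMetrics, MetricsRecord
from .structure import BindingSite, LigandInstance, Residue, Structure, find_binding_site, select_ligands

__all__ = [
    "CheckLimits",
    "QualityResult",
    "PairClassification",
    "BFactorFlag",
    "CATEGORIES",
    "PAIR_CODES",
    "categorize",
    "score_entity",
    "score_binding_site",
    "classify_pair",
    "bfactor_flag",
    "assess_complex",
    "ReportRow",
    "AssessmentReport",
]

CATEGORIES = ("Good", "Dubious", "Bad")
PAIR_CODES = ("GG", "GD", "GB", "DG", "DD", "DB", "BG", "BD", "BB")
CHECK_IDS = ("a", "b", "c", "d", "e", "f", "g")


@dataclass(frozen=True)
class CheckLimits:
    """The seven default limits; equality at a limit is never a violation."""

    max_rsr: float = 0.4
    max_good_rsr: float = 0.24
    min_good_rscc: float = 0.9
    required_avg_occupancy: float = 1.0
    max_owab: float = 50.0
    max_r_free: float = 0.3
    max_r_free_minus_r_work: float = 0.05

    def __post_init__(self) -> None:
        if self.max_good_rsr > self.max_rsr:
            raise ValueError("max_good_rsr must not exceed max_rsr")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "CheckLimits":
        names = {f.name for f in fields(cls)}
        kwargs = {k: float(v) for k, v in mapping.items() if k in names}
        return cls(**kwargs)


@dataclass
class QualityResult:
    entity_key: str
    score: int
    violated_checks: frozenset[str]
    category: str
    incomplete_flag: bool = False
    worst_residues: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.score != len(self.violated_checks) and self.worst_residues is None:
            raise ValueError("score must equal the number of violated checks")


@dataclass
class PairClassification:
    ligand_result: QualityResult
    site_result: QualityResult
    pair_code: str
    worst_residues: list[str]


@dataclass
class BFactorFlag:
    """Ligand-vs-site mean B-factor comparison (Table-style flag).

    ``site_mean_b`` is the mean over site residues of each residue's mean
    heavy-atom B-factor; the flag fires when the ligand mean is at least
    ``flag_ratio`` times the site mean.
    """

    ligand_mean_b: float
    site_mean_b: float
    ratio: float
    flagged: bool
    flag_ratio: float = 1.5


def categorize(score: int) -> str:
    """Good (score = 0), Dubious (0 < score <= 2), Bad (score > 2)."""
    if score < 0:
        raise ValueError(f"negative score {score}")
    if score == 0:
        return "Good"
    if score <= 2:
        return "Dubious"
    return "Bad"


def score_entity(
    metrics: EntityMetrics,
    global_metrics: Optional[GlobalMetrics] = None,
    limits: CheckLimits = CheckLimits(),
) -> QualityResult:
    """Score one entity against the seven limits.

    Unavailable metrics skip their checks and set the incomplete flag.
    Raises if no metric at all is available.
    """
    gm = global_metrics or GlobalMetrics()
    violated: set[str] = set()
    skipped = False

    if metrics.rsr is not None:
        if metrics.rsr > limits.max_rsr:
            violated.add("a")
        if metrics.rsr > limits.max_good_rsr:
            violated.add("b")
    else:
        skipped = True
    if metrics.rscc is not None:
        if metrics.rscc < limits.min_good_rscc:
            violated.add("c")
    else:
        skipped = True
    if metrics.avg_occupancy is not None:
        if metrics.avg_occupancy < limits.required_avg_occupancy:
            violated.add("d")
        elif metrics.avg_occupancy > limits.required_avg_occupancy + 1e-9:
            warnings.warn(
                f"{metrics.entity_key}: average occupancy {metrics.avg_occupancy} > 1 "
                "after altloc summation; data-quality issue, not penalized",
                stacklevel=2,
            )
    else:
        skipped = True
    if metrics.owab is not None:
        if metrics.owab > limits.max_owab:
            violated.add("e")
    else:
        skipped = True
    if gm.r_free is not None:
        if gm.r_free > limits.max_r_free:
            violated.add("f")
    else:
        skipped = True
    delta = gm.r_free_minus_r_work
    if delta is not None:
        if delta > limits.max_r_free_minus_r_work:
            violated.add("g")
    else:
        skipped = True

    n_available = sum(metrics.available.values()) + sum(
        v is not None for v in (gm.r_free, delta)
    )
    if n_available == 0:
        raise ValueError(f"{metrics.entity_key}: no metrics available, cannot score")

    score = len(violated)
    return QualityResult(
        entity_key=metrics.entity_key,
        score=score,
        violated_checks=frozenset(violated),
        category=categorize(score),
        incomplete_flag=skipped,
    )


def score_binding_site(residue_results: Sequence[QualityResult]) -> QualityResult:
    """Site score = the worst (maximum) residue score; ties all reported."""
    if not residue_results:
        raise ValueError("binding site with no residue results cannot be labeled")
    worst = max(r.score for r in residue_results)
    worst_keys = sorted(r.entity_key for r in residue_results if r.score == worst)
    exemplar = next(r for r in residue_results if r.score == worst)
    return QualityResult(
        entity_key="site",
        score=worst,
        violated_checks=exemplar.violated_checks,
        category=categorize(worst),
        incomplete_flag=any(r.incomplete_flag for r in residue_results),
        worst_residues=worst_keys,
    )


def classify_pair(
    ligand_result: QualityResult,
    site_result: QualityResult,
    covalent: bool = False,
) -> PairClassification:
    """Two-letter pair code from the category initials (ligand first)."""
    if covalent:
        raise ValueError(
            f"{ligand_result.entity_key}: covalently bound ligand is not assessable"
        )
    code = ligand_result.category[0] + site_result.category[0]
    return PairClassification(
        ligand_result=ligand_result,
        site_result=site_result,
        pair_code=code,
        worst_residues=list(site_result.worst_residues or []),
    )


def bfactor_flag(
    ligand: LigandInstance,
    site_residues: Sequence[Residue],
    flag_ratio: float = 1.5,
) -> BFactorFlag:
    if not site_residues:
        raise ValueError("empty binding site")
    ligand_mean = ligand.mean_heavy_b()
    site_mean = float(np.mean([r.mean_heavy_b() for r in site_residues]))
    if site_mean <= 0:
        raise ValueError("site mean B-factor must be positive")
    ratio = ligand_mean / site_mean
    return BFactorFlag(
        ligand_mean_b=ligand_mean,
        site_mean_b=site_mean,
        ratio=ratio,
        flagged=ratio >= flag_ratio,
        flag_ratio=flag_ratio,
    )


# ---------------------------------------------------------------------------
# End-to-end assessment of one structure


@dataclass
class ReportRow:
    """One report line per selected ligand, mirroring the assessment tables."""

    entity_key: str
    het_code: str
    ligand_score: Optional[int]
    site_score: Optional[int]
    pair_code: Optional[str]
    ligand_category: Optional[str]
    site_category: Optional[str]
    ligand_mean_b: Optional[float]
    site_mean_b: Optional[float]
    b_ratio: Optional[float]
    b_flagged: Optional[bool]
    n_atoms_occ_lt1: int
    n_heavy_atoms: int
    rscc: Optional[float]
    n_site_residues: int
    worst_residues: list[str] = field(default_factory=list)
    incomplete: bool = False
    covalent: bool = False
    note: str = ""


@dataclass
class AssessmentReport:
    rows: list[ReportRow]
    pairs: list[PairClassification]
    radius: float
    limits: CheckLimits

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            d = r.__dict__.copy()
            d["worst_residues"] = ";".join(r.worst_residues)
            records.append(d)
        return pd.DataFrame(records)

    def config_header(self) -> list[str]:
        lim = "; ".join(f"{f.name}={getattr(self.limits, f.name)}" for f in fields(CheckLimits))
        return [f"# site_radius={self.radius}", f"# limits: {lim}"]

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            for line in self.config_header():
                fh.write(line + "\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.4g")

    def write_json(self, path: str | Path) -> None:
        payload = {
            "site_radius": self.radius,
            "limits": {f.name: getattr(self.limits, f.name) for f in fields(CheckLimits)},
            "rows": [
                {**row.__dict__} for row in self.rows
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def assess_complex(
    structure: Structure,
    metrics: dict[str, MetricsRecord],
    limits: CheckLimits = CheckLimits(),
    radius: float = 4.5,
    flag_ratio: float = 1.5,
    exclude_incomplete: bool = False,
    model: int = 0,
    **select_kwargs,
) -> AssessmentReport:
    """Run the full single-structure pipeline.

    Selects ligands, extracts each binding site, scores ligand and residues
    from the supplied metrics, and emits one report row per ligand with the
    pair code, worst residues, occupancy-deficit count and the B-factor
    comparison.  Covalently flagged ligands yield a not-assessable row; a
    ligand without metrics yields an incomplete row (dropped entirely when
    ``exclude_incomplete``).
    """
    rows: list[ReportRow] = []
    pairs: list[PairClassification] = []
    for ligand in select_ligands(structure, model=model, **select_kwargs):
        site = find_binding_site(structure, ligand, radius=radius, model=model)
        n_occ_deficit = ligand.n_atoms_below_full_occupancy()
        base = dict(
            entity_key=ligand.entity_key,
            het_code=ligand.het_code,
            n_atoms_occ_lt1=n_occ_deficit,
            n_heavy_atoms=len(ligand.heavy_atoms()),
            n_site_residues=len(site.residues),
        )
        bf = None
        if site.residues:
            bf = bfactor_flag(ligand, site.residues, flag_ratio=flag_ratio)
        b_fields = dict(
            ligand_mean_b=ligand.mean_heavy_b(),
            site_mean_b=bf.site_mean_b if bf else None,
            b_ratio=bf.ratio if bf else None,
            b_flagged=bf.flagged if bf else None,
        )

        if ligand.covalent_flag:
            rows.append(
                ReportRow(
                    **base,
                    **b_fields,
                    ligand_score=None,
                    site_score=None,
                    pair_code=None,
                    ligand_category=None,
                    site_category=None,
                    rscc=None,
                    covalent=True,
                    note="covalently bound; not assessable",
                )
            )
            continue

        lig_rec = metrics.get(ligand.entity_key)
        res_results = []
        residues_missing = False
        for res in site.residues:
            rec = metrics.get(res.entity_key)
            if rec is None:
                residues_missing = True
                continue
            res_results.append(
                QualityResult(
                    **{
                        **score_entity(rec.entity, rec.global_metrics, limits).__dict__,
                        "entity_key": res.entity_key,
                    }
                )
            )

        if lig_rec is None or not res_results:
            row = ReportRow(
                **base,
                **b_fields,
                ligand_score=None,
                site_score=None,
                pair_code=None,
                ligand_category=None,
                site_category=None,
                rscc=lig_rec.entity.rscc if lig_rec else None,
                incomplete=True,
                note="metrics missing for ligand" if lig_rec is None else "metrics missing for all site residues",
            )
            if not exclude_incomplete:
                rows.append(row)
            continue

        lig_result = score_entity(lig_rec.entity, lig_rec.global_metrics, limits)
        site_result = score_binding_site(res_results)
        pair = classify_pair(lig_result, site_result)
        pairs.append(pair)
        incomplete = lig_result.incomplete_flag or site_result.incomplete_flag or residues_missing
        row = ReportRow(
            **base,
            **b_fields,
            ligand_score=lig_result.score,
            site_score=site_result.score,
            pair_code=pair.pair_code,
            ligand_category=lig_result.category,
            site_category=site_result.category,
            rscc=lig_rec.entity.rscc,
            worst_residues=pair.worst_residues,
            incomplete=incomplete,
            note="some site residues lack metrics" if residues_missing else "",
        )
        if incomplete and exclude_incomplete:
            pairs.pop()
            continue
        rows.append(row)
    return AssessmentReport(rows=rows, pairs=pairs, radius=radius, limits=limits)
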