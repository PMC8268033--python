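"""Dataset-level aggregation of pair quality records.

Takes per-pair survey records (entry, deposition year, resolution, ligand and
site scores, pair code) and produces the standard dataset views: category
distributions for ligands / sites / pairs, year-wise percentages where each
cell is normalized by the *whole-dataset* pair count, and resolution
stratification ("2.5 Å or better" = resolution <= 2.5; smaller is better).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .quality import CATEGORIES, PAIR_CODES, categorize

__all__ = [
    "SurveyRecord",
    "DistributionTable",
    "StrataResult",
    "read_survey_tsv",
    "write_survey_tsv",
    "records_to_dataframe",
    "category_distribution",
    "yearwise_percent",
    "resolution_strata",
    "score_vs_resolution",
]

SURVEY_COLUMNS = ["entry_id", "year", "resolution", "ligand_score", "site_score", "pair_code"]

#: Pair codes whose members need little or no attention (no 'Bad' partner
#: other than... precisely: neither partner rated Bad).
LOW_ATTENTION_CODES = ("GG", "GD", "DG", "DD")


@dataclass
class SurveyRecord:
    entry_id: str
    deposition_year: Optional[int]
    resolution: float
    ligand_score: int
    site_score: int
    pair_code: str

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"{self.entry_id}: non-positive resolution")
        expected = categorize(self.ligand_score)[0] + categorize(self.site_score)[0]
        if self.pair_code != expected:
            raise ValueError(
                f"{self.entry_id}: pair code {self.pair_code} inconsistent with scores "
                f"({self.ligand_score}, {self.site_score}) -> {expected}"
            )


@dataclass
class DistributionTable:
    """Counts and percentages per category for one view."""

    view: str  # ligand | site | pair
    counts: dict[str, int]
    percentages: dict[str, float]
    total: int
    low_attention_percent: Optional[float] = None  # pair view only

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [self.percentages[c] for c in self.counts],
            }
        )


@dataclass
class StrataResult:
    category: str
    scope: str
    cutoff: float
    n_category: int
    n_at_or_better: int
    fraction: Optional[float]  # None when the category is absent


def records_to_dataframe(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "entry_id": [r.entry_id for r in records],
            "year": [r.deposition_year for r in records],
            "resolution": [r.resolution for r in records],
            "ligand_score": [r.ligand_score for r in records],
            "site_score": [r.site_score for r in records],
            "pair_code": [r.pair_code for r in records],
        }
    )


def read_survey_tsv(path: str | Path) -> list[SurveyRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        year = row["year"]
        out.append(
            SurveyRecord(
                entry_id=str(row["entry_id"]),
                deposition_year=None if pd.isna(year) else int(year),
                resolution=float(row["resolution"]),
                ligand_score=int(row["ligand_score"]),
                site_score=int(row["site_score"]),
                pair_code=str(row["pair_code"]),
            )
        )
    return out


def write_survey_tsv(records: Sequence[SurveyRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, sep="\t", index=False)


def _percent(count: int, total: int) -> float:
    return 100.0 * count / total


def category_distribution(records: Sequence[SurveyRecord]) -> dict[str, DistributionTable]:
    """Ligand, site and pair category distributions plus the low-attention
    rollup (GG+GD+DG+DD share of all pairs)."""
    if not records:
        raise ValueError("empty record set")
    total = len(records)
    views: dict[str, DistributionTable] = {}

    for view, labels, getter in (
        ("ligand", CATEGORIES, lambda r: categorize(r.ligand_score)),
        ("site", CATEGORIES, lambda r: categorize(r.site_score)),
        ("pair", PAIR_CODES, lambda r: r.pair_code),
    ):
        counts = {label: 0 for label in labels}
        for r in records:
            counts[getter(r)] += 1
        table = DistributionTable(
            view=view,
            counts=counts,
            percentages={c: _percent(n, total) for c, n in counts.items()},
            total=total,
        )
        if view == "pair":
            low = sum(counts[c] for c in LOW_ATTENTION_CODES)
            table.low_attention_percent = _percent(low, total)
        views[view] = table
    return views


def yearwise_percent(records: Sequence[SurveyRecord], category: str) -> pd.DataFrame:
    """Year-wise percentage of pairs of one pair category.

    Each cell is 100 x (pairs of the category in that year) / (total pairs in
    the whole dataset) — the denominator is the dataset, not the year, so the
    cells of all categories and years sum to 100.  Records without a year are
    excluded (they aggregate under the 'unknown' bucket of the count column).
    """
    if category not in PAIR_CODES:
        raise ValueError(f"unknown pair category {category!r}")
    total = len(records)
    dated = [r for r in records if r.deposition_year is not None]
    rows = []
    for year in sorted({r.deposition_year for r in dated}):
        n = sum(1 for r in dated if r.deposition_year == year and r.pair_code == category)
        rows.append({"year": year, "category": category, "count": n, "percent": _percent(n, total)})
    return pd.DataFrame(rows, columns=["year", "category", "count", "percent"])


def resolution_strata(
    records: Sequence[SurveyRecord],
    cutoff: float = 2.5,
    category: str = "Bad",
    scope: str = "ligand",
) -> StrataResult:
    """Fraction of one category's records at ``cutoff`` Å or better.

    ``scope`` selects which partner's category is stratified ("ligand" or
    "site").  "Or better" is inclusive: resolution <= cutoff.  When the
    category is absent the fraction is undefined (None).
    """
    if scope not in ("ligand", "site"):
        raise ValueError(f"scope must be 'ligand' or 'site', got {scope!r}")
    getter = (lambda r: categorize(r.ligand_score)) if scope == "ligand" else (
        lambda r: categorize(r.site_score)
    )
    selected = [r for r in records if getter(r) == category]
    n_at = sum(1 for r in selected if r.resolution <= cutoff)
    return StrataResult(
        category=category,
        scope=scope,
        cutoff=cutoff,
        n_category=len(selected),
        n_at_or_better=n_at,
        fraction=(n_at / len(selected)) if selected else None,
    )


def score_vs_resolution(
    records: Sequence[SurveyRecord],
    flag_cutoff: float = 2.5,
) -> pd.DataFrame:
    """Tidy (view, score, resolution, category, flagged) scatter table.

    A point is flagged when it attains the maximal score of its view at a
    resolution of ``flag_cutoff`` Å or better — the worst offenders among
    nominally high-resolution structures.
    """
    rows = []
    if not records:
        return pd.DataFrame(columns=["view", "entry_id", "score", "resolution", "category", "flagged"])
    for view, getter in (("ligand", lambda r: r.ligand_score), ("site", lambda r: r.site_score)):
        max_score = max(getter(r) for r in records)
        for r in records:
            s = getter(r)
            rows.append(
                {
                    "view": view,
                    "entry_id": r.entry_id,
                    "score": s,
                    "resolution": r.resolution,
                    "category": categorize(s),
                    "flagged": s == max_score and r.resolution <= flag_cutoff,
                }
            )
    return pd.DataFrame(rows)


def plot_survey(records: Sequence[SurveyRecord], out_dir: str | Path) -> list[Path]:
    """Optional scatter and stacked-bar plots (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    scatter = score_vs_resolution(records)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    colors = {"Good": "tab:green", "Dubious": "gold", "Bad": "tab:red"}
    for ax, view in zip(axes, ("ligand", "site")):
        sub = scatter[scatter["view"] == view]
        ax.scatter(sub["resolution"], sub["score"], c=sub["category"].map(colors), s=12, alpha=0.6)
        ax.axvline(2.5, ls="--", c="k", lw=0.8)
        ax.set_xlabel("resolution (Å)")
        ax.set_title(view)
    axes[0].set_ylabel("quality score")
    path = out_dir / "score_vs_resolution.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    dist = category_distribution(records)["pair"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(list(dist.counts), [dist.percentages[c] for c in dist.counts])
    ax.set_ylabel("% of pairs")
    path = out_dir / "pair_distribution.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
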