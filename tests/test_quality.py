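"""Penalty scoring, categorization, site aggregation, pair taxonomy."""

import itertools

import numpy as np
import pytest

from ligqc.metrics import EntityMetrics, GlobalMetrics, MetricsRecord
from ligqc.quality import (
    CheckLimits,
    QualityResult,
    assess_complex,
    bfactor_flag,
    categorize,
    classify_pair,
    score_binding_site,
    score_entity,
)
from ligqc.structure import Atom, LigandInstance, Residue, Structure
from ligqc.synthetic import feasible_violation_sets

from .conftest import carbon_residue


def _metrics(key="E", rsr=0.20, rscc=0.95, occ=1.0, owab=30.0):
    return EntityMetrics(entity_key=key, rsr=rsr, rscc=rscc, avg_occupancy=occ, owab=owab)


def _globals(r_work=0.22, r_free=0.25):
    return GlobalMetrics(resolution=2.0, r_work=r_work, r_free=r_free)


def brute_force_score(rsr, rscc, occ, owab, r_free, r_work):
    """Independent literal restatement of the seven checks (oracle)."""
    violations = set()
    if rsr > 0.4:
        violations.add("a")
    if rsr > 0.24:
        violations.add("b")
    if rscc < 0.9:
        violations.add("c")
    if occ < 1.0:
        violations.add("d")
    if owab > 50.0:
        violations.add("e")
    if r_free > 0.3:
        violations.add("f")
    if (r_free - r_work) > 0.05:
        violations.add("g")
    score = len(violations)
    cat = "Good" if score == 0 else ("Dubious" if score <= 2 else "Bad")
    return violations, score, cat


# value choices on each side of each limit (equality cases included separately)
RSR_ZONES = [0.20, 0.30, 0.50]  # pass both / violate b / violate a+b
RSCC_ZONES = [0.95, 0.60]
OCC_ZONES = [1.0, 0.5]
OWAB_ZONES = [30.0, 75.0]
RFACTOR_ZONES = [(0.25, 0.22), (0.25, 0.19), (0.35, 0.31), (0.35, 0.25)]


class TestScoreEntity:
    def test_fully_compliant_scores_zero(self):
        res = score_entity(_metrics(), _globals())
        assert res.score == 0 and res.category == "Good" and not res.incomplete_flag

    def test_worst_case_scores_seven(self):
        res = score_entity(
            _metrics(rsr=0.50, rscc=0.60, occ=0.5, owab=75.0),
            _globals(r_work=0.28, r_free=0.35),
        )
        assert res.score == 7
        assert res.violated_checks == frozenset("abcdefg")
        assert res.category == "Bad"

    def test_intermediate_rsr_violates_only_good_bound(self):
        res = score_entity(_metrics(rsr=0.30), _globals())
        assert res.violated_checks == frozenset("b")
        assert res.category == "Dubious"

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(rsr=0.40), frozenset("b")),  # equality passes (a) but still exceeds the 'Good' bound
            (dict(rsr=0.24), frozenset()),  # equality at 'Good' RSR
            (dict(rscc=0.90), frozenset()),
            (dict(owab=50.0), frozenset()),
        ],
    )
    def test_equality_at_limits_passes(self, kwargs, expected):
        res = score_entity(_metrics(**{**dict(rsr=0.2), **kwargs}), _globals())
        assert res.violated_checks == expected

    def test_equality_at_global_limits_passes(self):
        res = score_entity(_metrics(), _globals(r_work=0.25, r_free=0.30))
        assert res.score == 0

    def test_exhaustive_oracle_equivalence(self):
        """Scorer matches the brute-force oracle over every realizable
        violation pattern (all subsets of the seven checks with a implying b)."""
        realized = set()
        for rsr, rscc, occ, owab, (r_free, r_work) in itertools.product(
            RSR_ZONES, RSCC_ZONES, OCC_ZONES, OWAB_ZONES, RFACTOR_ZONES
        ):
            expect_viol, expect_score, expect_cat = brute_force_score(
                rsr, rscc, occ, owab, r_free, r_work
            )
            res = score_entity(
                _metrics(rsr=rsr, rscc=rscc, occ=occ, owab=owab),
                _globals(r_work=r_work, r_free=r_free),
            )
            assert res.violated_checks == frozenset(expect_viol)
            assert res.score == expect_score
            assert res.category == expect_cat
            realized.add(frozenset(expect_viol))
        assert realized == set(feasible_violation_sets())
        assert len(realized) == 96

    def test_unavailable_metric_skips_and_flags(self):
        res = score_entity(EntityMetrics(entity_key="E", rsr=0.5), GlobalMetrics())
        assert res.violated_checks == frozenset("ab")
        assert res.incomplete_flag

    def test_no_metrics_at_all(self):
        with pytest.raises(ValueError):
            score_entity(EntityMetrics(entity_key="E"), GlobalMetrics())

    def test_overfull_occupancy_warns_without_penalty(self):
        with pytest.warns(UserWarning):
            res = score_entity(_metrics(occ=1.2), _globals())
        assert "d" not in res.violated_checks


class TestCategorize:
    @pytest.mark.parametrize(
        "score,expected",
        [(0, "Good"), (1, "Dubious"), (2, "Dubious"), (3, "Bad"), (7, "Bad")],
    )
    def test_thresholds(self, score, expected):
        assert categorize(score) == expected

    def test_negative_score(self):
        with pytest.raises(ValueError):
            categorize(-1)


def _result(key, score):
    checks = frozenset(list("abcdefg")[:score])
    return QualityResult(entity_key=key, score=score, violated_checks=checks, category=categorize(score))


class TestBindingSiteScore:
    def test_all_good(self):
        site = score_binding_site([_result("A:1", 0), _result("A:2", 0), _result("A:3", 0)])
        assert site.score == 0 and site.category == "Good"

    def test_single_bad_residue_makes_site_bad(self):
        site = score_binding_site([_result("A:1", 0), _result("A:2", 1), _result("A:3", 4)])
        assert site.score == 4 and site.category == "Bad"
        assert site.worst_residues == ["A:3"]

    def test_ties_all_reported_sorted(self):
        site = score_binding_site([_result("A:9", 2), _result("A:2", 2)])
        assert site.score == 2 and site.worst_residues == ["A:2", "A:9"]

    def test_empty_site_is_an_error(self):
        with pytest.raises(ValueError):
            score_binding_site([])

    def test_adding_a_residue_never_lowers_the_score(self):
        base = [_result("A:1", 1), _result("A:2", 2)]
        s0 = score_binding_site(base).score
        for extra in range(8):
            s1 = score_binding_site(base + [_result("A:3", extra)]).score
            assert s1 >= s0

    def test_permutation_invariance(self):
        results = [_result(f"A:{i}", s) for i, s in enumerate([0, 3, 1, 3, 2])]
        a = score_binding_site(results)
        b = score_binding_site(list(reversed(results)))
        assert (a.score, a.worst_residues) == (b.score, b.worst_residues)


class TestPairClassification:
    @pytest.mark.parametrize(
        "lig,site,code",
        [(0, 0, "GG"), (7, 4, "BB"), (2, 5, "DB"), (0, 1, "GD"), (4, 0, "BG")],
    )
    def test_codes(self, lig, site, code):
        pair = classify_pair(_result("L", lig), score_binding_site([_result("A:1", site)]))
        assert pair.pair_code == code

    def test_covalent_is_not_assessable(self):
        with pytest.raises(ValueError):
            classify_pair(_result("L", 0), score_binding_site([_result("A:1", 0)]), covalent=True)


def _ligand_with_b(mean_b, n=4):
    atoms = [Atom(f"C{i+1}", "C", (1.5 * i, 0, 0), 1.0, mean_b) for i in range(n)]
    return LigandInstance("XXX", "L", 1, "", atoms, 48.0)


class TestBFactorFlag:
    def test_worked_ratio_below_threshold(self):
        lig = _ligand_with_b(75.01)
        site = [carbon_residue(1, [(0, 5, 0)], b_factor=53.41)]
        flag = bfactor_flag(lig, site)
        assert round(flag.ratio, 1) == 1.4
        assert not flag.flagged

    def test_worked_ratio_twice_site_flags(self):
        lig = _ligand_with_b(64.07)
        site = [carbon_residue(1, [(0, 5, 0)], b_factor=32.05)]
        flag = bfactor_flag(lig, site)
        assert flag.ratio == pytest.approx(2.0, abs=0.005)
        assert flag.flagged

    def test_equal_means_not_flagged(self):
        lig = _ligand_with_b(30.0)
        site = [carbon_residue(1, [(0, 5, 0)], b_factor=30.0)]
        flag = bfactor_flag(lig, site)
        assert flag.ratio == pytest.approx(1.0) and not flag.flagged

    def test_site_mean_is_mean_of_residue_means(self):
        lig = _ligand_with_b(40.0)
        site = [
            carbon_residue(1, [(0, 5, 0), (0, 6, 0)], b_factor=20.0),
            carbon_residue(2, [(5, 0, 0)], b_factor=60.0),
        ]
        flag = bfactor_flag(lig, site)
        assert flag.site_mean_b == pytest.approx(40.0)  # (20 + 60) / 2, not atom-weighted

    def test_empty_site(self):
        with pytest.raises(ValueError):
            bfactor_flag(_ligand_with_b(30.0), [])


class TestAssessComplex:
    def _complex(self, lig_occ=1.0, covalent_distance=None):
        lig_atoms = [Atom(f"C{i+1}", "C", (1.4 * i, 0.0, 0.0), lig_occ, 25.0) for i in range(7)]
        residues = [Residue("L", 1, "", "LIG", lig_atoms, False)]
        residues.append(carbon_residue(1, [(0.0, 4.2, 0.0)], b_factor=30.0))
        residues.append(carbon_residue(2, [(0.0, -4.2, 0.0)], b_factor=30.0))
        if covalent_distance is not None:
            residues.append(carbon_residue(3, [(0.0, 0.0, covalent_distance)]))
        return Structure(entry_id="CPLX", models=[residues])

    def _metrics_for(self, structure, **lig_overrides):
        records = {}
        for res in structure.residues():
            key = res.entity_key
            em = _metrics(key=key)
            records[key] = MetricsRecord(entity=em, global_metrics=_globals())
        if lig_overrides:
            records["L:1"] = MetricsRecord(
                entity=_metrics(key="L:1", **lig_overrides), global_metrics=_globals()
            )
        return records

    def test_compliant_complex_yields_gg(self):
        st = self._complex()
        report = assess_complex(st, self._metrics_for(st))
        assert len(report.rows) == 1
        row = report.rows[0]
        assert row.pair_code == "GG" and not row.incomplete and row.n_atoms_occ_lt1 == 0

    def test_occupancy_deficit_count(self):
        st = self._complex(lig_occ=0.5)
        report = assess_complex(st, self._metrics_for(st, occ=0.5))
        row = report.rows[0]
        assert row.n_atoms_occ_lt1 == row.n_heavy_atoms == 7
        assert row.ligand_score == 1  # only check (d)

    def test_covalent_ligand_reported_not_assessed(self):
        st = self._complex(covalent_distance=1.6)
        report = assess_complex(st, self._metrics_for(st))
        row = report.rows[0]
        assert row.covalent and row.pair_code is None and "covalent" in row.note
        assert report.pairs == []

    def test_missing_ligand_metrics_flags_incomplete(self):
        st = self._complex()
        records = self._metrics_for(st)
        records.pop("L:1")
        report = assess_complex(st, records)
        assert report.rows[0].incomplete and report.rows[0].pair_code is None
        assert assess_complex(st, records, exclude_incomplete=True).rows == []

    def test_report_tsv_embeds_config(self, tmp_path):
        st = self._complex()
        report = assess_complex(st, self._metrics_for(st))
        out = tmp_path / "report.tsv"
        report.write_tsv(out)
        text = out.read_text()
        assert text.startswith("# site_radius=4.5")
        assert "max_rsr=0.4" in text
        assert "GG" in text
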