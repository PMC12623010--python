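"""Relationship taxonomy, kinship recursion and pedigree metrics."""

import itertools

import pytest
from helpers import ancestor_depths, brute_force_classify, gene_drop_kinship

from famrisk.errors import PersonLookupError
from famrisk.pedigree import (KinshipCalculator, classify_pair, kinship,
                              pedigree_metrics, relatives_of, spouses_of)
from famrisk.types import CONVERSE, RELATIONSHIP_DEGREE


class TestKinship:
    @pytest.mark.parametrize("i,j,expected", [
        ("C1", "A2", 0.25),      # parent-offspring
        ("C1", "C2", 0.25),      # full siblings
        ("F1", "N1", 0.125),     # half siblings
        ("F1", "A1", 0.125),     # grandchild
        ("F1", "G1", 0.0625),    # first cousins
        ("A1", "J1", 0.0625),    # great-grandparent
        ("A1", "B1", 0.0),       # unrelated founders
        ("A1", "A2", 0.0),       # spouses
        ("F2", "J1", 0.03125),   # first cousins once removed
    ])
    def test_closed_forms(self, toy20, i, j, expected):
        assert kinship(toy20, i, j) == pytest.approx(expected, abs=1e-12)

    def test_self_kinship_outbred(self, toy20):
        assert kinship(toy20, "J1", "J1") == 0.5

    def test_symmetry_and_memo_independence(self, toy20):
        ids = toy20.ids()
        shared = KinshipCalculator(toy20)
        for i, j in itertools.combinations(ids, 2):
            fresh = kinship(toy20, i, j)
            assert fresh == kinship(toy20, j, i)
            assert fresh == shared(i, j)
            assert 0.0 <= fresh <= 0.5

    def test_gene_drop_agreement_for_cousins(self, toy20):
        est = gene_drop_kinship(toy20, "F1", "G1", n_rep=100_000, seed=11)
        assert est == pytest.approx(0.0625, abs=0.003)

    def test_gene_drop_agreement_for_half_sibs_and_avuncular(self, toy20):
        assert gene_drop_kinship(toy20, "F1", "N1", n_rep=60_000, seed=5) == \
            pytest.approx(0.125, abs=0.005)
        assert gene_drop_kinship(toy20, "J1", "H2", n_rep=60_000, seed=6) == \
            pytest.approx(0.125, abs=0.005)

    def test_unknown_id_raises(self, toy20):
        with pytest.raises(PersonLookupError):
            kinship(toy20, "A1", "nobody")


class TestClassifyPair:
    @pytest.mark.parametrize("index,relative,relationship,degree", [
        ("F1", "D1", "parent", 1),
        ("D1", "F1", "child", 1),
        ("C1", "C3", "sibling", 1),
        ("F1", "N1", "half_sibling", 2),
        ("F1", "A1", "grandparent", 2),
        ("A1", "F1", "grandchild", 2),
        ("F1", "C3", "aunt_uncle", 2),
        ("C3", "F1", "niece_nephew", 2),
        ("F1", "G1", "first_cousin", 3),
        ("N1", "H1", "first_cousin", 3),
        ("J1", "C1", "great_aunt_uncle", 3),
        ("C1", "J1", "grand_niece_nephew", 3),
        ("J1", "A1", "great_grandparent", 3),
        ("A1", "J1", "great_grandchild", 3),
        ("A1", "A2", "spouse", None),
        ("D2", "M1", "spouse", None),     # childless couple link
        ("F2", "J1", "other", None),      # first cousin once removed
        ("A1", "B1", "unrelated", None),
        ("N1", "D1", "unrelated", None),  # stepmother, no blood, no link
    ])
    def test_taxonomy(self, toy20, index, relative, relationship, degree):
        pair = classify_pair(toy20, index, relative)
        assert pair.relationship == relationship
        assert pair.degree == degree
        if degree is not None:
            assert pair.kinship == pytest.approx(2.0 ** -(degree + 1))

    def test_self_pair_rejected(self, toy20):
        with pytest.raises(ValueError):
            classify_pair(toy20, "A1", "A1")

    def test_agrees_with_ancestor_depth_oracle(self, toy20):
        for i, j in itertools.permutations(toy20.ids(), 2):
            assert classify_pair(toy20, i, j).relationship == \
                brute_force_classify(toy20, i, j), (i, j)

    def test_converse_under_role_reversal(self, toy20):
        for i, j in itertools.combinations(toy20.ids(), 2):
            ij = classify_pair(toy20, i, j)
            ji = classify_pair(toy20, j, i)
            assert ij.degree == ji.degree
            assert CONVERSE[ij.relationship] == ji.relationship


class TestRelativesOf:
    def test_founder_with_three_children(self, toy20):
        # B1's blood relatives: D1, D2 (children), F1, F2 (grandchildren)
        rels = {p.relative_id: p.relationship for p in relatives_of(toy20, "B1")}
        assert rels == {"D1": "child", "D2": "child",
                        "F1": "grandchild", "F2": "grandchild"}

    def test_isolated_person_has_no_relatives(self, trio):
        lone = trio.__class__([type(trio.person("dad"))(person_id="x", sex="male",
                                                        birth_year=1900)])
        assert relatives_of(lone, "x") == []

    def test_spouses_never_listed(self, toy20):
        for pid in toy20.ids():
            listed = {p.relative_id for p in relatives_of(toy20, pid)}
            for sp in spouses_of(toy20, pid):
                assert sp not in listed

    def test_matches_exhaustive_classification(self, toy20):
        """Enumeration equals brute-force classification of all C(20,2) pairs."""
        for pid in toy20.ids():
            expected = {}
            for other in toy20.ids():
                if other == pid:
                    continue
                rel = brute_force_classify(toy20, pid, other)
                if rel in RELATIONSHIP_DEGREE:
                    expected[other] = (rel, RELATIONSHIP_DEGREE[rel])
            got = {p.relative_id: (p.relationship, p.degree)
                   for p in relatives_of(toy20, pid)}
            assert got == expected, pid

    def test_each_relative_listed_once_sorted(self, toy20):
        for pid in toy20.ids():
            rels = relatives_of(toy20, pid)
            ids = [p.relative_id for p in rels]
            assert ids == sorted(ids)
            assert len(ids) == len(set(ids))

    def test_degree_kinship_identity(self, toy20):
        for pid in toy20.ids():
            for p in relatives_of(toy20, pid):
                assert p.kinship == pytest.approx(2.0 ** -(p.degree + 1)), p


def test_simulated_outbred_pairs_have_canonical_kinship():
    """In simulated (non-consanguineous) genealogies, every enumerated
    degree-d pair has kinship exactly 2^-(d+1)."""
    from famrisk.pedigree import KinshipCalculator
    from famrisk.simulate import SimulationParams, simulate_pedigree

    g = simulate_pedigree(SimulationParams(
        n_founder_couples=40, n_generations=4, seed=17))
    kin = KinshipCalculator(g)
    checked = 0
    for pid in g.ids():
        for pair in relatives_of(g, pid, max_degree=3, _kin=kin):
            assert pair.kinship == 2.0 ** -(pair.degree + 1), pair
            checked += 1
    assert checked > 1000


class TestSpousesOf:
    def test_coparents_are_spouses(self, trio):
        assert spouses_of(trio, "dad") == ["mom"]
        assert spouses_of(trio, "mom") == ["dad"]

    def test_childless_founder_has_none(self, toy20):
        # I1f married H1 (has child J1); E1f married C3; but A1's co-founder
        # B1 never married into the A line
        assert spouses_of(toy20, "B1") == ["B2"]

    def test_childless_couple_link_counts(self, toy20):
        assert "M1" in spouses_of(toy20, "D2")

    def test_consanguineous_partner_skipped_with_warning(self, toy20, caplog):
        g = toy20
        g.couples.add(frozenset(("F1", "G1")))  # first cousins marrying
        g._partners = None
        import logging
        with caplog.at_level(logging.WARNING, logger="famrisk.pedigree"):
            assert "G1" not in spouses_of(g, "F1")
        assert any("blood-related" in r.message for r in caplog.records)


class TestPedigreeMetrics:
    def test_isolated_person(self):
        from famrisk.genealogy import Genealogy
        from famrisk.types import Person
        g = Genealogy([Person(person_id="x", sex="male", birth_year=1900)])
        m = pedigree_metrics(g, "x")
        assert (m.pedigree_size, m.max_degree, m.size_stratum) == (0, 0, "0-4")

    def test_two_parents_two_grandparents(self):
        from famrisk.genealogy import Genealogy
        from famrisk.types import FEMALE, MALE, Person

        def p(pid, sex, by, f=None, m=None):
            return Person(person_id=pid, father_id=f, mother_id=m, sex=sex,
                          birth_year=by)

        g = Genealogy([
            p("gf", MALE, 1900), p("gm", FEMALE, 1900),
            p("f", MALE, 1930, "gf", "gm"), p("m", FEMALE, 1932),
            p("kid", FEMALE, 1960, "f", "m"),
        ])
        met = pedigree_metrics(g, "kid")
        assert (met.pedigree_size, met.max_degree) == (4, 2)

    def test_sizes_double_count_unordered_pairs(self, toy20):
        """Sum of pedigree sizes = 2 x number of unordered degree<=3 pairs."""
        total = sum(pedigree_metrics(toy20, pid).pedigree_size
                    for pid in toy20.ids())
        n_pairs = sum(
            1 for i, j in itertools.combinations(toy20.ids(), 2)
            if brute_force_classify(toy20, i, j) in RELATIONSHIP_DEGREE
        )
        assert total == 2 * n_pairs

    def test_max_degree_zero_iff_empty(self, toy20):
        for pid in toy20.ids():
            m = pedigree_metrics(toy20, pid)
            assert (m.max_degree == 0) == (m.pedigree_size == 0)
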