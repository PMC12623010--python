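"""Odds-ratio estimation: oracle equivalences, strata, demographics."""

import numpy as np
import pandas as pd
import pytest

from famrisk.errors import DegenerateFitError, UndefinedORError
from famrisk.genealogy import Genealogy
from famrisk.stats import (build_relative_table, demographics_report,
                           fit_clustered_logistic, format_percent, or_from_2x2,
                           spousal_analysis, stratified_fdr_analysis)
from famrisk.types import FEMALE, MALE, MatchSet, Person


def rows_from_2x2(a, b, c, d, own_cluster=True):
    """Expand a 2x2 table into a relative-row frame (one row per person)."""
    recs = []
    i = 0
    for is_case, affected, n in ((True, True, a), (True, False, b),
                                 (False, True, c), (False, False, d)):
        for _ in range(int(n)):
            recs.append((f"idx{i}" if own_cluster else ("case" if is_case else "ctrl"),
                         is_case, FEMALE, f"rel{i}", FEMALE, affected, 1, "child"))
            i += 1
    return pd.DataFrame(recs, columns=["index_id", "index_is_case", "index_sex",
                                       "relative_id", "relative_sex",
                                       "relative_affected", "degree", "relationship"])


class TestTwoByTwoOracle:
    def test_balanced_table_gives_unit_or(self):
        assert or_from_2x2(10, 10, 10, 10).odds_ratio == pytest.approx(1.0)

    def test_cross_product(self):
        assert or_from_2x2(20, 10, 10, 20).odds_ratio == pytest.approx(4.0)

    def test_woolf_interval(self):
        est = or_from_2x2(20, 80, 10, 90)
        se = np.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90)
        log_or = np.log(20 * 90 / (80 * 10))
        assert est.odds_ratio == pytest.approx(np.exp(log_or))
        assert est.ci_low == pytest.approx(np.exp(log_or - 1.959963985 * se), rel=1e-6)
        assert est.ci_high == pytest.approx(np.exp(log_or + 1.959963985 * se), rel=1e-6)

    def test_haldane_correction_applied_only_with_zero_cell(self):
        est = or_from_2x2(0, 10, 5, 10)
        assert est.odds_ratio == pytest.approx((0.5 * 10.5) / (10.5 * 5.5))

    def test_empty_margin_is_undefined(self):
        with pytest.raises(UndefinedORError):
            or_from_2x2(0, 0, 5, 10)
        with pytest.raises(UndefinedORError):
            or_from_2x2(0, 10, 0, 10)


class TestClusteredLogistic:
    def test_saturated_fit_equals_cross_product_or(self):
        rows = rows_from_2x2(20, 80, 10, 90)
        est = fit_clustered_logistic(rows, include_sex=False)[0]
        assert est.odds_ratio == pytest.approx(2.25, abs=1e-9)
        assert (est.n_case_relatives, est.n_control_relatives) == (100, 100)

    def test_own_cluster_robust_se_equals_woolf(self):
        """With every row its own cluster the sandwich SE collapses to the
        classical Woolf SE on the 2x2 at the logistic MLE."""
        rows = rows_from_2x2(20, 80, 10, 90)
        est = fit_clustered_logistic(rows, include_sex=False)[0]
        woolf = or_from_2x2(20, 80, 10, 90)
        for attr in ("ci_low", "ci_high", "p_value"):
            assert getattr(est, attr) == pytest.approx(getattr(woolf, attr), abs=1e-8)

    def test_matches_statsmodels_cluster_robust(self):
        """Independent route: statsmodels GLM with clustered covariance."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n_idx = 60
        recs = []
        for i in range(n_idx):
            is_case = i < n_idx // 2
            u = rng.normal(0, 0.5)
            for j in range(int(rng.integers(2, 6))):
                sex = FEMALE if rng.random() < 0.5 else MALE
                eta = -2.0 + 0.7 * is_case + 0.5 * (sex == FEMALE) + u
                y = rng.random() < 1 / (1 + np.exp(-eta))
                recs.append((f"i{i}", is_case, FEMALE, f"r{i}_{j}", sex, y, 1, "child"))
        rows = pd.DataFrame(recs, columns=["index_id", "index_is_case", "index_sex",
                                           "relative_id", "relative_sex",
                                           "relative_affected", "degree",
                                           "relationship"])
        ours = {e.term: e for e in fit_clustered_logistic(rows, include_sex=True)}
        X = sm.add_constant(np.column_stack([
            rows["index_is_case"].astype(float),
            (rows["relative_sex"] == FEMALE).astype(float)]))
        fit = sm.GLM(rows["relative_affected"].astype(float), X,
                     family=sm.families.Binomial()).fit(
            cov_type="cluster",
            cov_kwds={"groups": pd.factorize(rows["index_id"])[0],
                      "use_correction": False})
        params = np.asarray(fit.params)
        se = np.sqrt(np.diag(fit.cov_params()))
        assert ours["relative_of_case"].odds_ratio == pytest.approx(
            np.exp(params[1]), rel=1e-6)
        assert ours["relative_of_case"].ci_low == pytest.approx(
            np.exp(params[1] - 1.959963985 * se[1]), rel=1e-4)
        assert ours["female"].ci_high == pytest.approx(
            np.exp(params[2] + 1.959963985 * se[2]), rel=1e-4)

    def test_single_class_outcome_is_degenerate(self):
        rows = rows_from_2x2(0, 50, 0, 50)
        with pytest.raises(DegenerateFitError):
            fit_clustered_logistic(rows, include_sex=False)

    def test_random_tables_agree_with_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            a, b, c, d = rng.integers(3, 40, size=4)
            est = fit_clustered_logistic(rows_from_2x2(a, b, c, d),
                                         include_sex=False)[0]
            assert est.odds_ratio == pytest.approx(
                or_from_2x2(a, b, c, d).odds_ratio, abs=1e-8)


def _two_family_setup():
    """A case with 2 children, two controls with 1 child each."""
    def p(pid, sex, by, f=None, m=None):
        return Person(person_id=pid, father_id=f, mother_id=m, sex=sex, birth_year=by)

    g = Genealogy([
        p("case", FEMALE, 1950), p("caseH", MALE, 1948),
        p("ck1", MALE, 1975, "caseH", "case"), p("ck2", FEMALE, 1978, "caseH", "case"),
        p("ctl1", FEMALE, 1950), p("ctl1H", MALE, 1949),
        p("tk1", FEMALE, 1976, "ctl1H", "ctl1"),
        p("ctl2", FEMALE, 1951), p("ctl2H", MALE, 1950),
        p("tk2", MALE, 1977, "ctl2H", "ctl2"),
    ])
    ms = [MatchSet(case_id="case", control_ids=("ctl1", "ctl2"))]
    return g, ms


class TestBuildRelativeTable:
    def test_fdr_row_counts(self):
        g, ms = _two_family_setup()
        rows = build_relative_table(g, ms, {}, 1)
        assert len(rows) == 4
        assert int(rows["index_is_case"].sum()) == 2
        assert set(rows.loc[rows["index_is_case"], "relative_id"]) == {"ck1", "ck2"}

    def test_degree_partition_identity(self, default_study):
        from famrisk.stats import _relative_rows
        res = default_study
        ms = res.matchsets[:40]
        full = _relative_rows(res.genealogy, ms, res.relative_flags)
        parts = [build_relative_table(res.genealogy, ms, res.relative_flags, d)
                 for d in (1, 2, 3)]
        assert sum(len(p) for p in parts) == len(full)

    def test_index_never_own_relative(self, default_study):
        res = default_study
        rows = build_relative_table(res.genealogy, res.matchsets[:40],
                                    res.relative_flags, 1)
        assert not (rows["index_id"] == rows["relative_id"]).any()

    def test_toy_pedigree_rows_match_brute_force(self, toy20):
        from helpers import brute_force_classify
        from famrisk.types import RELATIONSHIP_DEGREE
        ms = [MatchSet(case_id="F1", control_ids=("H1", "N1"))]
        rows = build_relative_table(toy20, ms, {}, 2)
        expected = set()
        for idx in ("F1", "H1", "N1"):
            for other in toy20.ids():
                if other != idx and RELATIONSHIP_DEGREE.get(
                        brute_force_classify(toy20, idx, other)) == 2:
                    expected.add((idx, other))
        assert set(zip(rows["index_id"], rows["relative_id"])) == expected

    def test_invalid_degree_filter_rejected(self, toy20):
        with pytest.raises(ValueError):
            build_relative_table(toy20, [], {}, 4)


class TestStratifiedFdr:
    def test_son_of_father_stratum_labeled(self, default_study):
        res = default_study
        ests, skipped = stratified_fdr_analysis(
            res.genealogy, res.matchsets, res.relative_flags)
        labels = {e.term for e in ests} | set(skipped)
        assert "son|father-index" in labels

    def test_strata_partition_degree1_rows(self, default_study):
        res = default_study
        rows = build_relative_table(res.genealogy, res.matchsets,
                                    res.relative_flags, 1)
        ests, skipped = stratified_fdr_analysis(
            res.genealogy, res.matchsets, res.relative_flags, rows=rows)
        fitted = sum(e.n_case_relatives + e.n_control_relatives for e in ests)
        skipped_rows = len(rows) - fitted
        assert skipped_rows >= 0
        if not skipped:
            assert fitted == len(rows)


class TestSpousal:
    def test_no_couples_reports_reason(self):
        g = Genealogy([Person(person_id="a", sex=FEMALE, birth_year=1950),
                       Person(person_id="b", sex=FEMALE, birth_year=1950)])
        ests, skipped = spousal_analysis(
            g, [MatchSet(case_id="a", control_ids=("b",))], {})
        assert ests == []
        assert skipped == {"husband_of_index_wife": "no spouse pairs",
                           "wife_of_index_husband": "no spouse pairs"}

    def test_spousal_terms_split_by_index_sex(self, default_study):
        res = default_study
        ests, skipped = spousal_analysis(res.genealogy, res.matchsets,
                                         res.relative_flags)
        assert {e.term for e in ests} | set(skipped) == {
            "husband_of_index_wife", "wife_of_index_husband"}


class TestDemographics:
    def test_percent_rounding_matches_cohort_convention(self):
        assert format_percent(67_549, 92_405) == "73%"
        assert format_percent(4_736, 92_405) == "5.1%"
        assert format_percent(8_022, 92_405) == "8.7%"

    def test_exact_matching_yields_balanced_table(self, default_study):
        res = default_study
        table, pvals = demographics_report(res.matched_cases, res.controls,
                                           res.genealogy, metrics=res.metrics)
        # variables matched exactly on stratum labels are balanced
        for var in ("sex", "birth_place", "pedigree_size", "max_degree"):
            assert pvals[var] > 0.05, var
        assert set(table["variable"]) == {"sex", "birth_year", "birth_place",
                                          "pedigree_size", "max_degree"}

    def test_empty_level_shown_but_not_tested(self):
        g = Genealogy([Person(person_id=f"p{i}", sex=FEMALE, birth_year=1950)
                       for i in range(6)])
        table, pvals = demographics_report(["p0", "p1"], ["p2", "p3"], g)
        sex_rows = table[table["variable"] == "sex"].set_index("level")
        assert sex_rows.loc[MALE, "case_n"] == 0
        assert np.isnan(pvals["sex"])  # single non-empty level


class TestRandomIntercept:
    def test_recovers_conditional_effect_direction(self):
        from famrisk.stats import fit_random_intercept_logistic
        rng = np.random.default_rng(11)
        recs = []
        for i in range(80):
            is_case = i % 2 == 0
            u = rng.normal(0, 1.0)
            for j in range(4):
                eta = -1.5 + 0.8 * is_case + u
                y = rng.random() < 1 / (1 + np.exp(-eta))
                recs.append((f"i{i}", is_case, FEMALE, f"r{i}_{j}", FEMALE, y,
                             1, "child"))
        rows = pd.DataFrame(recs, columns=["index_id", "index_is_case", "index_sex",
                                           "relative_id", "relative_sex",
                                           "relative_affected", "degree",
                                           "relationship"])
        ests, tau = fit_random_intercept_logistic(rows, include_sex=False)
        assert tau > 0.3
        assert ests[0].odds_ratio > 1.0
        assert ests[0].ci_low < ests[0].odds_ratio < ests[0].ci_high
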