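"""Case/control eligibility rules over coded diagnosis records.

A case must show qualifying codes in at least two distinct calendar years
(screening out people who were tested once but never confirmed), carry no
exclusionary code in any year, be an adult at the reference year, and have
at least three relatives of degree <= 3 in the genealogy.  Controls must be
code-free entirely — one single-year qualifying code is enough to fall out
of both pools.  Age is reference_year - birth_year; records are
year-resolution so no finer rule is possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Optional, Set, Tuple

import pandas as pd

from .errors import ConfigurationError
from .genealogy import Genealogy
from .pedigree import pedigree_metrics_all
from .simulate import DEFAULT_EXCLUSIONARY_CODES, DEFAULT_QUALIFYING_CODES
from .types import PedigreeMetrics

#: codes for the autoimmune-thyroiditis family specifically
AUTOIMMUNE_CODES = frozenset({"245.2", "E06.3"})


@dataclass(frozen=True)
class CodePolicy:
    """Configurable phenotype-ascertainment rule.

    ``distinct_year_codes`` chooses which qualifying codes count toward the
    two-distinct-years rule: ``"any_qualifying"`` (default) lets either code
    family contribute; ``"autoimmune_only"`` requires the autoimmune-
    thyroiditis codes themselves in >= min_distinct_years years.
    """

    qualifying_codes: FrozenSet[str] = frozenset(DEFAULT_QUALIFYING_CODES)
    exclusionary_codes: FrozenSet[str] = frozenset(DEFAULT_EXCLUSIONARY_CODES)
    min_distinct_years: int = 2
    min_age: int = 18
    min_relatives: int = 3
    distinct_year_codes: str = "any_qualifying"

    def __post_init__(self):
        if self.qualifying_codes & self.exclusionary_codes:
            raise ConfigurationError(
                "qualifying_codes: overlaps exclusionary_codes: "
                f"{sorted(self.qualifying_codes & self.exclusionary_codes)}"
            )
        if self.min_distinct_years < 1:
            raise ConfigurationError("min_distinct_years: must be >= 1")
        if self.distinct_year_codes not in ("any_qualifying", "autoimmune_only"):
            raise ConfigurationError(
                f"distinct_year_codes: unknown option {self.distinct_year_codes!r}"
            )

    @property
    def year_rule_codes(self) -> FrozenSet[str]:
        if self.distinct_year_codes == "autoimmune_only":
            return frozenset(self.qualifying_codes) & AUTOIMMUNE_CODES
        return frozenset(self.qualifying_codes)


@dataclass
class CohortResult:
    """Ascertained cases plus per-filter attrition counts."""

    case_ids: Set[str]
    excluded_counts: Dict[str, int]
    control_eligible_ids: Set[str]


def _check_records(records: pd.DataFrame, genealogy: Genealogy) -> None:
    known = set(genealogy.people)
    unknown = set(records["person_id"]) - known
    if unknown:
        from .errors import ReferentialIntegrityError

        raise ReferentialIntegrityError(
            f"records reference unknown person ids: {sorted(unknown)[:5]}"
        )


def diagnosis_flags(records: pd.DataFrame, genealogy: Genealogy, policy: CodePolicy,
                    reference_year: int) -> Dict[str, bool]:
    """Per-person phenotype flag from the diagnosis rule alone: qualifying
    codes in >= min_distinct_years distinct years, no exclusionary code
    ever, adult at the reference year.  No pedigree-size requirement — this
    is the rule applied to relatives."""
    _check_records(records, genealogy)
    year_ok = _distinct_year_pass(records, policy)
    excluded = _ever_excluded(records, policy)
    out: Dict[str, bool] = {}
    for pid in year_ok:
        if pid in excluded:
            continue
        if reference_year - genealogy.people[pid].birth_year < policy.min_age:
            continue
        out[pid] = True
    return out


def _distinct_year_pass(records: pd.DataFrame, policy: CodePolicy) -> Set[str]:
    q = records[records["code"].isin(policy.year_rule_codes)]
    if q.empty:
        return set()
    n_years = q.groupby("person_id")["year"].nunique()
    return set(n_years[n_years >= policy.min_distinct_years].index)


def _ever_excluded(records: pd.DataFrame, policy: CodePolicy) -> Set[str]:
    return set(records.loc[records["code"].isin(policy.exclusionary_codes), "person_id"])


def identify_cases(records: pd.DataFrame, genealogy: Genealogy, policy: CodePolicy,
                   reference_year: int,
                   metrics: Optional[Dict[str, PedigreeMetrics]] = None) -> CohortResult:
    """Apply the four case filters in fixed order (distinct years ->
    exclusionary codes -> age -> pedigree size) to everyone with at least
    one qualifying record; attrition counts reflect that order, membership
    does not depend on it."""
    _check_records(records, genealogy)
    candidates = set(records.loc[records["code"].isin(policy.qualifying_codes), "person_id"])
    year_ok = _distinct_year_pass(records, policy)
    excluded_ever = _ever_excluded(records, policy)
    counts = {"distinct_years": 0, "exclusionary_code": 0, "age": 0, "pedigree_size": 0}
    survivors = set()
    for pid in candidates:
        if pid not in year_ok:
            counts["distinct_years"] += 1
            continue
        if pid in excluded_ever:
            counts["exclusionary_code"] += 1
            continue
        if reference_year - genealogy.people[pid].birth_year < policy.min_age:
            counts["age"] += 1
            continue
        survivors.add(pid)
    if survivors:
        if metrics is None:
            metrics = pedigree_metrics_all(genealogy)
        cases = {pid for pid in survivors
                 if metrics[pid].pedigree_size >= policy.min_relatives}
        counts["pedigree_size"] = len(survivors) - len(cases)
    else:
        cases = set()
    controls = eligible_controls(records, genealogy, policy, reference_year)
    return CohortResult(case_ids=cases, excluded_counts=counts,
                        control_eligible_ids=controls)


def eligible_controls(records: pd.DataFrame, genealogy: Genealogy, policy: CodePolicy,
                      reference_year: int) -> Set[str]:
    """Adults with no qualifying and no exclusionary code in any year.
    Pedigree constraints are applied at matching time, not here."""
    _check_records(records, genealogy)
    flagged = set(records.loc[
        records["code"].isin(policy.qualifying_codes | policy.exclusionary_codes),
        "person_id"])
    return {
        pid for pid, p in genealogy.people.items()
        if pid not in flagged and reference_year - p.birth_year >= policy.min_age
    }


@dataclass(frozen=True)
class PrevalenceResult:
    single_rate: float
    confirmed_rate: float
    n_single: int
    n_confirmed: int
    n_population: int


def estimate_prevalence(records: pd.DataFrame, population_ids: Iterable[str],
                        census_year: int,
                        policy: Optional[CodePolicy] = None) -> PrevalenceResult:
    """Single- and confirmed-diagnosis prevalence at a census year.

    single: >= 1 qualifying code in any year <= census_year;
    confirmed: a member of the single cohort with a qualifying code in a
    second, different year <= census_year.
    """
    pop = set(population_ids)
    if not pop:
        raise ValueError("population_ids must be nonempty")
    policy = policy or CodePolicy()
    q = records[records["code"].isin(policy.qualifying_codes)
                & (records["year"] <= census_year)
                & records["person_id"].isin(pop)]
    if q.empty:
        n_years = pd.Series(dtype=int)
    else:
        n_years = q.groupby("person_id")["year"].nunique()
    n_single = int((n_years >= 1).sum())
    n_confirmed = int((n_years >= 2).sum())
    n_pop = len(pop)
    return PrevalenceResult(n_single / n_pop, n_confirmed / n_pop,
                            n_single, n_confirmed, n_pop)
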