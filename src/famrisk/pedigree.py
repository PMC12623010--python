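"""Relationship classification, kinship coefficients and pedigree metrics.

Degree is assigned from a named relationship taxonomy (parent/child/sibling
= first degree; grandparent/grandchild, avuncular, half-sibling = second;
first cousins, great-avuncular, great-grandparental = third) rather than
from raw meiosis counts, which keeps spouses out of the degree system and
matches how genealogical relative-risk studies enumerate FDR/SDR/TDR.

In an outbred pedigree every degree-d pair has kinship exactly 2^-(d+1):
1/4 for first degree, 1/8 for second, 1/16 for third.  The kinship
coefficient itself is computed by the standard recursion on the later-born
member of the pair, with founders mutually unrelated.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Tuple

from .errors import PersonLookupError
from .genealogy import Genealogy
from .types import (
    CONVERSE,
    RELATIONSHIP_DEGREE,
    PedigreeMetrics,
    RelativePair,
    size_stratum,
)

log = logging.getLogger(__name__)


# -- kinship ---------------------------------------------------------------


def kinship(genealogy: Genealogy, i: str, j: str,
            _memo: Optional[Dict[Tuple[str, str], float]] = None) -> float:
    """Kinship coefficient phi(i, j).

    phi(i,i) = (1 + phi(father_i, mother_i)) / 2; for distinct i, j the
    recursion descends through the parents of the later-born member (which
    guarantees termination and never skips a shared ancestor).  Founders are
    mutually unrelated.  Symmetric; memoized per call unless a shared memo
    dict is supplied.
    """
    genealogy.person(i)
    genealogy.person(j)
    memo = _memo if _memo is not None else {}
    return _kinship(genealogy, i, j, memo)


def _kinship(g: Genealogy, i: str, j: str, memo: Dict[Tuple[str, str], float]) -> float:
    key = (i, j) if i <= j else (j, i)
    hit = memo.get(key)
    if hit is not None:
        return hit
    pi = g.people[i]
    if i == j:
        if pi.father_id is not None and pi.mother_id is not None:
            val = 0.5 * (1.0 + _kinship(g, pi.father_id, pi.mother_id, memo))
        else:
            val = 0.5
        memo[key] = val
        return val
    pj = g.people[j]
    # recurse on the later-born member; ties broken by id so the choice is
    # deterministic (either choice is valid when neither is an ancestor of
    # the other, and equal birth years preclude ancestry).
    if (pj.birth_year, j) > (pi.birth_year, i):
        younger, other = pj, i
    else:
        younger, other = pi, j
    if younger.father_id is None and younger.mother_id is None:
        val = 0.0
    else:
        val = 0.0
        if younger.father_id is not None:
            val += 0.5 * _kinship(g, younger.father_id, other, memo)
        if younger.mother_id is not None:
            val += 0.5 * _kinship(g, younger.mother_id, other, memo)
    memo[key] = val
    return val


class KinshipCalculator:
    """Memoized kinship over one genealogy, shared across many queries."""

    def __init__(self, genealogy: Genealogy):
        self.genealogy = genealogy
        self._memo: Dict[Tuple[str, str], float] = {}

    def __call__(self, i: str, j: str) -> float:
        self.genealogy.person(i)
        self.genealogy.person(j)
        return _kinship(self.genealogy, i, j, self._memo)


# -- pattern tests ---------------------------------------------------------


def _grandparents(g: Genealogy, pid: str) -> Tuple[str, ...]:
    out = []
    for par in g._parent_ids(pid):
        out.extend(g._parent_ids(par))
    return tuple(out)


def _great_grandparents(g: Genealogy, pid: str) -> Tuple[str, ...]:
    out = []
    for gp in _grandparents(g, pid):
        out.extend(g._parent_ids(gp))
    return tuple(out)


def _full_sibs_of_any(g: Genealogy, pids) -> set:
    out = set()
    for pid in pids:
        out.update(g.full_siblings_of(pid))
    return out


def _relationship_of(g: Genealogy, index_id: str, relative_id: str) -> str:
    """Label of `relative_id`'s relationship to `index_id` ('the relative is
    the index's ...'), checked in degree order with ties broken by the
    taxonomy listing; 'other' for more distant blood relatives, 'spouse'
    for non-blood partners, else 'unrelated'."""
    i, r = index_id, relative_id
    if r in g._parent_ids(i):
        return "parent"
    if i in g._parent_ids(r):
        return "child"
    pi, pr = g.people[i], g.people[r]
    shared = set(g._parent_ids(i)) & set(g._parent_ids(r))
    both = (
        pi.father_id is not None
        and pi.mother_id is not None
        and pi.father_id == pr.father_id
        and pi.mother_id == pr.mother_id
    )
    if both:
        return "sibling"
    if shared:
        return "half_sibling"
    if r in _grandparents(g, i):
        return "grandparent"
    if i in _grandparents(g, r):
        return "grandchild"
    if r in _full_sibs_of_any(g, g._parent_ids(i)):
        return "aunt_uncle"
    if i in _full_sibs_of_any(g, g._parent_ids(r)):
        return "niece_nephew"
    if set(g._parent_ids(i)) & _full_sibs_of_any(g, g._parent_ids(r)) or \
            set(g._parent_ids(r)) & _full_sibs_of_any(g, g._parent_ids(i)):
        return "first_cousin"
    if r in _full_sibs_of_any(g, _grandparents(g, i)):
        return "great_aunt_uncle"
    if i in _full_sibs_of_any(g, _grandparents(g, r)):
        return "grand_niece_nephew"
    if r in _great_grandparents(g, i):
        return "great_grandparent"
    if i in _great_grandparents(g, r):
        return "great_grandchild"
    return "_none"


def classify_pair(genealogy: Genealogy, index_id: str, relative_id: str,
                  _kin: Optional[KinshipCalculator] = None) -> RelativePair:
    """Classify one (index, relative) pair into its closest relationship.

    When several relationships coexist (possible only under consanguinity,
    which the simulator forbids) the smallest degree wins; such pairs are
    logged.  Partners with no blood relation classify as ``spouse``; blood
    relatives beyond the third degree as ``other``.
    """
    if index_id == relative_id:
        raise ValueError("index and relative must be distinct persons")
    genealogy.person(index_id)
    genealogy.person(relative_id)
    kin = _kin if _kin is not None else KinshipCalculator(genealogy)
    phi = kin(index_id, relative_id)
    rel = _relationship_of(genealogy, index_id, relative_id)
    if rel != "_none":
        degree = RELATIONSHIP_DEGREE[rel]
        if abs(phi - 2.0 ** -(degree + 1)) > 1e-12:
            log.info(
                "pair (%s, %s): %s with kinship %.6g != 2^-(%d+1); "
                "multiple relationships coexist, closest degree kept",
                index_id, relative_id, rel, phi, degree,
            )
        return RelativePair(index_id, relative_id, rel, degree, phi)
    is_partner = relative_id in genealogy.partners_of(index_id)
    if is_partner and phi == 0.0:
        return RelativePair(index_id, relative_id, "spouse", None, phi)
    if phi > 0.0:
        return RelativePair(index_id, relative_id, "other", None, phi)
    return RelativePair(index_id, relative_id, "unrelated", None, 0.0)


# -- enumeration -----------------------------------------------------------

_PATTERNS_BY_DEGREE = {
    1: ("parent", "child", "sibling"),
    2: ("half_sibling", "grandparent", "grandchild", "aunt_uncle", "niece_nephew"),
    3: ("first_cousin", "great_aunt_uncle", "grand_niece_nephew",
        "great_grandparent", "great_grandchild"),
}


def _candidates(g: Genealogy, pid: str, relationship: str) -> set:
    parents = g._parent_ids(pid)
    if relationship == "parent":
        return set(parents)
    if relationship == "child":
        return set(g.children_of(pid))
    if relationship == "sibling":
        return set(g.full_siblings_of(pid))
    if relationship == "half_sibling":
        out = set()
        for par in parents:
            out.update(g.children_of(par))
        out.discard(pid)
        return out - set(g.full_siblings_of(pid))
    if relationship == "grandparent":
        return set(_grandparents(g, pid))
    if relationship == "grandchild":
        out = set()
        for c in g.children_of(pid):
            out.update(g.children_of(c))
        return out
    if relationship == "aunt_uncle":
        return _full_sibs_of_any(g, parents)
    if relationship == "niece_nephew":
        out = set()
        for s in g.full_siblings_of(pid):
            out.update(g.children_of(s))
        return out
    if relationship == "first_cousin":
        out = set()
        for au in _full_sibs_of_any(g, parents):
            out.update(g.children_of(au))
        return out
    if relationship == "great_aunt_uncle":
        return _full_sibs_of_any(g, _grandparents(g, pid))
    if relationship == "grand_niece_nephew":
        out = set()
        for s in g.full_siblings_of(pid):
            for c in g.children_of(s):
                out.update(g.children_of(c))
        return out
    if relationship == "great_grandparent":
        return set(_great_grandparents(g, pid))
    if relationship == "great_grandchild":
        out = set()
        for c in g.children_of(pid):
            for gc in g.children_of(c):
                out.update(g.children_of(gc))
        return out
    raise ValueError(relationship)


def relatives_of(genealogy: Genealogy, index_id: str, max_degree: int = 3,
                 _kin: Optional[KinshipCalculator] = None) -> List[RelativePair]:
    """All relatives of ``index_id`` at degree 1..max_degree, each listed
    once under its closest relationship; spouses excluded; sorted by
    relative id."""
    genealogy.person(index_id)
    kin = _kin if _kin is not None else KinshipCalculator(genealogy)
    seen = {index_id}
    pairs: List[RelativePair] = []
    for degree in (1, 2, 3):
        if degree > max_degree:
            break
        for rel in _PATTERNS_BY_DEGREE[degree]:
            for rid in sorted(_candidates(genealogy, index_id, rel)):
                if rid in seen:
                    continue
                seen.add(rid)
                pairs.append(RelativePair(index_id, rid, rel, degree, kin(index_id, rid)))
    pairs.sort(key=lambda p: p.relative_id)
    return pairs


def spouses_of(genealogy: Genealogy, index_id: str) -> List[str]:
    """Partners (couple link or shared offspring) with no blood relation to
    the index; consanguineous partners are skipped with a warning."""
    kin = KinshipCalculator(genealogy)
    out = []
    for pid in genealogy.partners_of(index_id):
        if kin(index_id, pid) > 0.0:
            log.warning(
                "partner pair (%s, %s) is blood-related (kinship %.4g); skipped",
                index_id, pid, kin(index_id, pid),
            )
            continue
        out.append(pid)
    return out


def pedigree_metrics(genealogy: Genealogy, index_id: str) -> PedigreeMetrics:
    """Pedigree size (count of degree<=3 relatives) and maximum degree."""
    rels = relatives_of(genealogy, index_id, max_degree=3)
    max_deg = max((p.degree for p in rels), default=0)
    return PedigreeMetrics(index_id, len(rels), max_deg)


def pedigree_metrics_all(genealogy: Genealogy) -> Dict[str, PedigreeMetrics]:
    """Metrics for every person, sharing one kinship memo for speed."""
    kin = KinshipCalculator(genealogy)
    out = {}
    for pid in genealogy.ids():
        rels = relatives_of(genealogy, pid, max_degree=3, _kin=kin)
        max_deg = max((p.degree for p in rels), default=0)
        out[pid] = PedigreeMetrics(pid, len(rels), max_deg)
    return out


def relative_pairs_frame(pairs: List[RelativePair]):
    """Relative-pair table as a DataFrame (index_id, relative_id,
    relationship, degree, kinship)."""
    import pandas as pd

    return pd.DataFrame(
        [(p.index_id, p.relative_id, p.relationship,
          p.degree if p.degree is not None else "none", p.kinship) for p in pairs],
        columns=["index_id", "relative_id", "relationship", "degree", "kinship"],
    )
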