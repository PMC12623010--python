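"""Independent oracles used by the test suite.

These deliberately do NOT share algorithms with the package: relationship
classification works from ancestor-depth maps (the package pattern-matches
on parent/child/sibling structure), and kinship is estimated by gene
dropping (the package uses the analytic recursion).
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from famrisk.genealogy import Genealogy


def ancestor_depths(g: Genealogy, pid: str) -> Dict[str, int]:
    """Minimum meiosis count to every ancestor (self at depth 0)."""
    depths = {pid: 0}
    frontier = [pid]
    while frontier:
        nxt = []
        for cur in frontier:
            p = g.people[cur]
            for par in (p.father_id, p.mother_id):
                if par is None:
                    continue
                d = depths[cur] + 1
                if par not in depths or d < depths[par]:
                    depths[par] = d
                    nxt.append(par)
        frontier = nxt
    return depths


_LINEAL_UP = {1: "parent", 2: "grandparent", 3: "great_grandparent"}
_LINEAL_DOWN = {1: "child", 2: "grandchild", 3: "great_grandchild"}


def brute_force_classify(g: Genealogy, index_id: str, relative_id: str) -> str:
    """Closest relationship of `relative_id` to `index_id`, derived purely
    from common-ancestor depth pairs."""
    di = ancestor_depths(g, index_id)
    dj = ancestor_depths(g, relative_id)
    if relative_id in di:
        return _LINEAL_UP.get(di[relative_id], "other")
    if index_id in dj:
        return _LINEAL_DOWN.get(dj[index_id], "other")
    common = set(di) & set(dj)
    if not common:
        if relative_id in g.partners_of(index_id):
            return "spouse"
        return "unrelated"
    # count common ancestors at each (depth_i, depth_j) pair
    counts: Dict[Tuple[int, int], int] = {}
    for a in common:
        key = (di[a], dj[a])
        counts[key] = counts.get(key, 0) + 1
    checks = [
        ("sibling", (1, 1), 2),
        ("half_sibling", (1, 1), 1),
        ("aunt_uncle", (2, 1), 2),
        ("niece_nephew", (1, 2), 2),
        ("first_cousin", (2, 2), 2),
        ("great_aunt_uncle", (3, 1), 2),
        ("grand_niece_nephew", (1, 3), 2),
    ]
    for name, key, min_count in checks:
        if counts.get(key, 0) >= min_count:
            return name
    return "other"


def gene_drop_kinship(g: Genealogy, i: str, j: str, n_rep: int = 100_000,
                      seed: int = 0) -> float:
    """Monte-Carlo kinship: forward-drop founder alleles through the
    pedigree ``n_rep`` times and average the probability that one random
    allele from each of i and j is identical by descent."""
    rng = np.random.default_rng(seed)
    order = sorted(g.people.values(), key=lambda p: (p.birth_year, p.person_id))
    alleles: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    next_allele = 0
    for p in order:
        if p.father_id is None or p.mother_id is None:
            a = np.full(n_rep, next_allele)
            b = np.full(n_rep, next_allele + 1)
            next_allele += 2
        else:
            fa, fb = alleles[p.father_id]
            ma, mb = alleles[p.mother_id]
            pick_f = rng.integers(0, 2, n_rep)
            pick_m = rng.integers(0, 2, n_rep)
            a = np.where(pick_f == 0, fa, fb)
            b = np.where(pick_m == 0, ma, mb)
        alleles[p.person_id] = (a, b)
    ia, ib = alleles[i]
    ja, jb = alleles[j]
    ibd = ((ia == ja).astype(float) + (ia == jb) + (ib == ja) + (ib == jb)) / 4.0
    return float(ibd.mean())


def concordance(pairs, affected: Dict[str, bool]) -> float:
    """Fraction of pairs where both members are affected."""
    both = sum(1 for a, b in pairs if affected[a] and affected[b])
    return both / len(pairs)
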