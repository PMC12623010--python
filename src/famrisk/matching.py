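"""Matched-control sampling and audit.

Greedy sequential matching in seed-randomized case order: each case draws
``ratio`` controls uniformly without replacement from the eligible pool in
its exact stratum (same sex, pedigree-size bin, maximum relative degree and
birth-place category) within the birth-year window.  A control is used at
most once across the whole run; cases whose pool is exhausted come back
unmatched rather than failing the run.  Case order is derived from the seed
(ids are sorted first, then shuffled), so permuting the input order does
not change the assignment.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np

from .genealogy import Genealogy
from .pedigree import pedigree_metrics_all
from .types import MatchSet, PedigreeMetrics, size_stratum

log = logging.getLogger(__name__)


def _stratum_key(genealogy: Genealogy, metrics: Dict[str, PedigreeMetrics],
                 pid: str) -> Tuple[str, str, int, str]:
    p = genealogy.people[pid]
    m = metrics[pid]
    return (p.sex, size_stratum(m.pedigree_size), m.max_degree, p.birth_place)


def match_controls(cases: Iterable[str], eligible: Iterable[str], genealogy: Genealogy,
                   ratio: int = 2, birth_year_window: float = 2.5, seed: int = 0,
                   metrics: Optional[Dict[str, PedigreeMetrics]] = None,
                   ) -> Tuple[List[MatchSet], List[str]]:
    """Sample ``ratio`` unique controls per case; returns (matchsets,
    unmatched case ids).  ``birth_year_window`` of 2.5 years with integer
    birth years means |delta| <= 2."""
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    cases = sorted(set(cases))
    eligible = sorted(set(eligible) - set(cases))
    if metrics is None:
        metrics = pedigree_metrics_all(genealogy)
    window = int(math.floor(birth_year_window))
    rng = np.random.default_rng(seed % 2**31)

    pools: Dict[tuple, List[str]] = {}
    for pid in eligible:
        key = _stratum_key(genealogy, metrics, pid)
        pools.setdefault(key + (genealogy.people[pid].birth_year,), []).append(pid)

    used: Set[str] = set()
    order = list(rng.permutation(len(cases)))
    matchsets: List[MatchSet] = []
    unmatched: List[str] = []
    for idx in order:
        cid = cases[idx]
        key = _stratum_key(genealogy, metrics, cid)
        by = genealogy.people[cid].birth_year
        pool = [pid
                for year in range(by - window, by + window + 1)
                for pid in pools.get(key + (year,), ())
                if pid not in used]
        if len(pool) < ratio:
            unmatched.append(cid)
            continue
        picks = rng.choice(len(pool), size=ratio, replace=False)
        chosen = tuple(pool[int(k)] for k in sorted(picks))
        used.update(chosen)
        matchsets.append(MatchSet(
            case_id=cid,
            control_ids=chosen,
            stratum={
                "sex": key[0],
                "pedigree_size_stratum": key[1],
                "max_degree": key[2],
                "birth_place": key[3],
                "birth_year": by,
                "birth_year_window": window,
            },
        ))
    if unmatched:
        log.info("matching: %d of %d cases had an insufficient control pool",
                 len(unmatched), len(cases))
    matchsets.sort(key=lambda m: m.case_id)
    return matchsets, sorted(unmatched)


def audit_match(matchsets: List[MatchSet], genealogy: Genealogy,
                metrics: Optional[Dict[str, PedigreeMetrics]] = None) -> List[Tuple[str, str]]:
    """Check every matched-set invariant; returns a list of
    (case_id, predicate) violations — empty iff the output is valid."""
    if metrics is None:
        metrics = pedigree_metrics_all(genealogy)
    violations: List[Tuple[str, str]] = []
    seen: Set[str] = set()
    for ms in matchsets:
        ckey = _stratum_key(genealogy, metrics, ms.case_id)
        cby = genealogy.people[ms.case_id].birth_year
        window = int(ms.stratum.get("birth_year_window", 2))
        if len(set(ms.control_ids)) != len(ms.control_ids):
            violations.append((ms.case_id, "uniqueness"))
        for pid in ms.control_ids:
            if pid in seen:
                violations.append((ms.case_id, "uniqueness"))
            seen.add(pid)
            okey = _stratum_key(genealogy, metrics, pid)
            for name, a, b in (
                ("sex", ckey[0], okey[0]),
                ("pedigree_size_stratum", ckey[1], okey[1]),
                ("max_degree", ckey[2], okey[2]),
                ("birth_place", ckey[3], okey[3]),
            ):
                if a != b:
                    violations.append((ms.case_id, name))
            if abs(genealogy.people[pid].birth_year - cby) > window:
                violations.append((ms.case_id, "birth_year"))
    return violations


def matches_frame(matchsets: List[MatchSet]):
    """Match table as a DataFrame: case_id, control_id, rank."""
    import pandas as pd

    rows = [(ms.case_id, pid, rank + 1)
            for ms in matchsets for rank, pid in enumerate(ms.control_ids)]
    return pd.DataFrame(rows, columns=["case_id", "control_id", "rank"])
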