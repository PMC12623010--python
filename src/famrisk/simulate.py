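"""Synthetic genealogies, liability-threshold disease and noisy code streams.

The generator emulates a statewide genealogical database linked to coded
diagnosis records: several founder couples, discrete non-overlapping
generations spaced 25 years apart with +/-5 years of uniform birth-year
jitter, random within-generation mating restricted to non-relatives
(kinship 0), and a truncated-Poisson offspring distribution.

Disease follows a liability-threshold model.  Each person's liability is

    L = A + C_couple + C_sib + E,   Var(L) = 1

with an additive genetic component A transmitted by the midparent rule
(child A = (A_f + A_m)/2 + N(0, h2/2)), a shared-couple environmental
deviate common to both partners, a shared-sibship deviate common to full
siblings, and an independent residual.  A person is affected when L exceeds
the sex-specific threshold Phi^{-1}(1 - prevalence_sex); the female excess
enters only through the thresholds, with sex assigned 50/50 independently
of liability.

Diagnosis records mimic longitudinal EHR extraction: affected people
receive qualifying codes in two or more distinct years with probability
``p_record_given_affected`` (otherwise in exactly one year, emulating the
tested-but-never-confirmed group); unaffected people pick up a single-year
qualifying code at a small noise rate; anyone can carry an exclusionary
(Graves'-type) code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError
from .genealogy import Genealogy
from .types import FEMALE, MALE, Person

GENERATION_SPACING = 25  # years between generation birth cohorts
BIRTH_JITTER = 5         # +/- years of uniform within-generation jitter

#: default ICD-style code sets (autoimmune thyroiditis + unspecified
#: hypothyroidism qualify; Graves'-type hyperthyroidism excludes)
DEFAULT_QUALIFYING_CODES = ("245.2", "E06.3", "244.9", "E03.9")
DEFAULT_EXCLUSIONARY_CODES = ("242.0", "242.9", "E05.0", "E05.9")
RECORD_SOURCES = ("uuh_ehr", "ih_ehr", "claims")


@dataclass
class SimulationParams:
    """Generative knobs for one synthetic study population.

    Defaults are the study conditions emulated throughout: heritability 0.65
    (twin-study estimates for autoimmune hypothyroidism run 65-75%), a
    shared-couple environment of 0.10, lifetime prevalence 6.6% in females
    and 2.4% in males (a ~2.75:1 female excess around an overall ~4.5%), and
    an EHR observation window of 1996-2021.
    """

    n_founder_couples: int = 500
    n_generations: int = 4
    mean_offspring: float = 2.5
    max_offspring: int = 8
    h2: float = 0.65
    c2_couple: float = 0.10
    c2_sibling: float = 0.0
    prevalence_female: float = 0.066
    prevalence_male: float = 0.024
    p_record_given_affected: float = 0.9
    p_single_year_noise: float = 0.02
    p_exclusion_code: float = 0.01
    p_birth_in_state: float = 0.54
    birth_year_range: Tuple[int, int] = (1920, 2005)
    ehr_years: Tuple[int, int] = (1996, 2021)
    seed: int = 0

    def validate(self) -> None:
        def bad(name, msg):
            raise ConfigurationError(f"{name}: {msg}")

        if self.n_founder_couples < 1:
            bad("n_founder_couples", "must be >= 1")
        if self.n_generations < 2:
            bad("n_generations", "must be >= 2")
        if self.mean_offspring < 0:
            bad("mean_offspring", "must be >= 0")
        if self.max_offspring < 1:
            bad("max_offspring", "must be >= 1")
        for name in ("h2", "c2_couple", "c2_sibling", "prevalence_female",
                     "prevalence_male", "p_record_given_affected",
                     "p_single_year_noise", "p_exclusion_code", "p_birth_in_state"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad(name, f"must be in [0, 1], got {v}")
        for name in ("prevalence_female", "prevalence_male"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                bad(name, f"must be in (0, 1), got {v}")
        if self.h2 + self.c2_couple + self.c2_sibling > 1.0 + 1e-12:
            bad("h2", "h2 + c2_couple + c2_sibling must be <= 1")
        lo, hi = self.birth_year_range
        if lo > hi:
            bad("birth_year_range", "start after end")
        span_needed = (self.n_generations - 1) * GENERATION_SPACING + BIRTH_JITTER
        if hi - lo < span_needed:
            bad("birth_year_range",
                f"needs at least {span_needed} years for {self.n_generations} generations")
        if self.ehr_years[0] > self.ehr_years[1]:
            bad("ehr_years", "start after end")


def _truncated_poisson(rng: np.random.Generator, mean: float, maximum: int, size: int) -> np.ndarray:
    """Poisson(mean) conditioned on <= maximum, by rejection."""
    out = rng.poisson(mean, size)
    bad = out > maximum
    while bad.any():
        out[bad] = rng.poisson(mean, int(bad.sum()))
        bad = out > maximum
    return out


def simulate_pedigree(params: SimulationParams) -> Genealogy:
    """Generate an acyclic multi-generation genealogy; deterministic in
    ``params.seed``.  Couples are monogamous and non-consanguineous (mates
    must share no ancestor)."""
    params.validate()
    rng = np.random.default_rng(params.seed % 2**31)
    start_year = params.birth_year_range[0]
    people: List[Person] = []
    couples: List[Tuple[str, str]] = []
    counter = 0

    def new_person(sex, birth_year, father=None, mother=None) -> Person:
        nonlocal counter
        counter += 1
        place = "in_state" if rng.random() < params.p_birth_in_state else "out_of_state"
        return Person(f"I{counter:06d}", father, mother, sex, int(birth_year), place)

    # ancestors-of map (including self) used for the kinship-0 mating rule
    anc: Dict[str, frozenset] = {}

    # founders: paired couples by construction
    gen_members: List[Person] = []
    base = start_year
    for _ in range(params.n_founder_couples):
        jm = int(rng.integers(-BIRTH_JITTER, BIRTH_JITTER + 1))
        jf = int(rng.integers(-BIRTH_JITTER, BIRTH_JITTER + 1))
        m = new_person(MALE, base + jm)
        f = new_person(FEMALE, base + jf)
        anc[m.person_id] = frozenset((m.person_id,))
        anc[f.person_id] = frozenset((f.person_id,))
        people.extend((m, f))
        gen_members.extend((m, f))
        couples.append((m.person_id, f.person_id))
    current_couples = list(couples)

    for gen in range(1, params.n_generations):
        base = start_year + gen * GENERATION_SPACING
        children: List[Person] = []
        n_off = _truncated_poisson(rng, params.mean_offspring, params.max_offspring,
                                   len(current_couples))
        for (fid, mid), k in zip(current_couples, n_off):
            for _ in range(int(k)):
                sex = FEMALE if rng.random() < 0.5 else MALE
                by = base + int(rng.integers(-BIRTH_JITTER, BIRTH_JITTER + 1))
                c = new_person(sex, by, father=fid, mother=mid)
                anc[c.person_id] = anc[fid] | anc[mid] | {c.person_id}
                children.append(c)
        people.extend(children)
        gen_members = children
        # Random within-generation mating among non-relatives.  Two extra
        # constraints keep every named relative pair at its canonical
        # kinship 2^-(degree+1): mates share no ancestor, and the spouses
        # of full siblings are mutually unrelated (two siblings marrying
        # two siblings would otherwise create double first cousins with
        # kinship 1/8 in the next generation).
        males = [p for p in children if p.sex == MALE]
        females = [p for p in children if p.sex == FEMALE]
        rng.shuffle(males)
        rng.shuffle(females)
        sib_spouse_anc: Dict[Tuple[str, str], List[frozenset]] = {}
        current_couples = []
        free_females = list(females)
        for m in males:
            m_id, m_key = m.person_id, (m.father_id, m.mother_id)
            mate_idx = None
            for idx, f in enumerate(free_females):
                f_id, f_key = f.person_id, (f.father_id, f.mother_id)
                if not anc[m_id].isdisjoint(anc[f_id]):
                    continue
                if any(not w.isdisjoint(anc[f_id])
                       for w in sib_spouse_anc.get(m_key, ())):
                    continue
                if any(not v.isdisjoint(anc[m_id])
                       for v in sib_spouse_anc.get(f_key, ())):
                    continue
                mate_idx = idx
                break
            if mate_idx is None:
                continue
            f = free_females.pop(mate_idx)
            sib_spouse_anc.setdefault(m_key, []).append(anc[f.person_id])
            sib_spouse_anc.setdefault((f.father_id, f.mother_id), []).append(anc[m_id])
            current_couples.append((m_id, f.person_id))
            couples.append((m_id, f.person_id))

    return Genealogy(people, couples)


def assign_liability(genealogy: Genealogy, params: SimulationParams,
                     seed: Optional[int] = None) -> Dict[str, bool]:
    """Draw liability components for every person (stored on the Person
    records) and return the affected flags.

    Unpartnered people receive a private couple-environment deviate and
    founders a private sibship deviate, so total liability variance is 1
    for everyone.
    """
    params.validate()
    rng = np.random.default_rng((params.seed + 1 if seed is None else seed) % 2**31)
    h2, c2c, c2s = params.h2, params.c2_couple, params.c2_sibling
    resid_var = 1.0 - h2 - c2c - c2s
    ordered = sorted(genealogy.people.values(), key=lambda p: (p.birth_year, p.person_id))

    additive: Dict[str, float] = {}
    for p in ordered:
        if p.father_id is not None and p.mother_id is not None:
            mid = 0.5 * (additive[p.father_id] + additive[p.mother_id])
            additive[p.person_id] = mid + rng.normal(0.0, np.sqrt(h2 / 2.0)) if h2 > 0 else 0.0
        else:
            additive[p.person_id] = rng.normal(0.0, np.sqrt(h2)) if h2 > 0 else 0.0

    couple_dev: Dict[str, float] = {}
    if c2c > 0:
        sd = np.sqrt(c2c)
        for c in sorted(genealogy.couples, key=sorted):
            d = rng.normal(0.0, sd)
            for pid in c:
                # first couple listed wins if a person were in several
                couple_dev.setdefault(pid, d)
        for p in ordered:
            couple_dev.setdefault(p.person_id, rng.normal(0.0, sd))
    else:
        couple_dev = {p.person_id: 0.0 for p in ordered}

    sib_dev: Dict[str, float] = {}
    if c2s > 0:
        sd = np.sqrt(c2s)
        for key in sorted(genealogy.sibships()):
            d = rng.normal(0.0, sd)
            for pid in genealogy.sibships()[key]:
                sib_dev[pid] = d
        for p in ordered:
            sib_dev.setdefault(p.person_id, rng.normal(0.0, sd))
    else:
        sib_dev = {p.person_id: 0.0 for p in ordered}

    thr = {
        FEMALE: float(norm.isf(params.prevalence_female)),
        MALE: float(norm.isf(params.prevalence_male)),
    }
    affected: Dict[str, bool] = {}
    for p in ordered:
        resid = rng.normal(0.0, np.sqrt(resid_var)) if resid_var > 0 else 0.0
        p.liability_additive = additive[p.person_id]
        p.liability_shared = couple_dev[p.person_id] + sib_dev[p.person_id]
        p.liability_residual = resid
        total = p.liability_additive + p.liability_shared + p.liability_residual
        p.affected = bool(total > thr[p.sex])
        affected[p.person_id] = p.affected
    return affected


def generate_ehr(genealogy: Genealogy, affected: Dict[str, bool],
                 params: SimulationParams, seed: Optional[int] = None) -> pd.DataFrame:
    """Noisy longitudinal diagnosis records as a DataFrame with columns
    person_id, year, code, source; deterministic in the seed."""
    params.validate()
    rng = np.random.default_rng((params.seed + 2 if seed is None else seed) % 2**31)
    start, end = params.ehr_years
    qual = DEFAULT_QUALIFYING_CODES
    excl = DEFAULT_EXCLUSIONARY_CODES
    rows: List[tuple] = []

    def add(pid, years):
        for y in years:
            code = qual[int(rng.integers(0, len(qual)))]
            src = RECORD_SOURCES[int(rng.integers(0, len(RECORD_SOURCES)))]
            rows.append((pid, int(y), code, src))

    for pid in genealogy.ids():
        p = genealogy.people[pid]
        lo = max(start, p.birth_year)
        if lo > end:
            continue  # born after the observation window
        years_avail = np.arange(lo, end + 1)
        if affected.get(pid, False):
            if rng.random() < params.p_record_given_affected and len(years_avail) >= 2:
                k = int(rng.integers(2, min(6, len(years_avail)) + 1))
            else:
                k = 1
            ys = rng.choice(years_avail, size=k, replace=False)
            add(pid, sorted(int(v) for v in ys))
        elif rng.random() < params.p_single_year_noise:
            add(pid, [int(rng.choice(years_avail))])
        if rng.random() < params.p_exclusion_code:
            code = excl[int(rng.integers(0, len(excl)))]
            src = RECORD_SOURCES[int(rng.integers(0, len(RECORD_SOURCES)))]
            rows.append((pid, int(rng.choice(years_avail)), code, src))

    df = pd.DataFrame(rows, columns=["person_id", "year", "code", "source"])
    return df.sort_values(["person_id", "year", "code"], kind="mergesort").reset_index(drop=True)


def simulate_study(params: SimulationParams):
    """Convenience: pedigree + liabilities + records in one call.

    Returns (genealogy, affected flags, records frame)."""
    g = simulate_pedigree(params)
    aff = assign_liability(g, params)
    rec = generate_ehr(g, aff, params)
    return g, aff, rec
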