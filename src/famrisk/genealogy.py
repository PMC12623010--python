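"""Genealogy container and file I/O.

The on-disk format is a tab-separated superset of the PLINK FAM convention:
one header line, then one person per row with columns

    family_id  person_id  father_id  mother_id  sex  birth_year  birth_place

where sex is 1 = male / 2 = female and ``0`` marks a missing parent.
Couple links that cannot be recovered from shared offspring (childless
couples) are stored as ``#couple<TAB>id1<TAB>id2`` comment lines, which
plain FAM readers skip.
"""

from __future__ import annotations

import io
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .errors import ParseError, PedigreeError, PersonLookupError, ReferentialIntegrityError
from .types import FEMALE, MALE, Person

HEADER = ["family_id", "person_id", "father_id", "mother_id", "sex", "birth_year", "birth_place"]

_SEX_TO_CODE = {MALE: "1", FEMALE: "2"}
_CODE_TO_SEX = {"1": MALE, "2": FEMALE}

MIN_PARENT_AGE_GAP = 15  # years; structural invariant, not a biological model


class Genealogy:
    """A set of people with parent links and explicit couple links.

    Parent links live on the :class:`~famrisk.types.Person` records; couple
    links are unordered id pairs.  Child/sibling/couple indexes are built
    lazily and invalidated never (the container is treated as immutable once
    handed to an analysis stage).
    """

    def __init__(self, people: Iterable[Person] = (), couples: Iterable[Tuple[str, str]] = (),
                 family_id: str = "F0"):
        self.family_id = family_id
        self.people: Dict[str, Person] = {}
        for p in people:
            if p.person_id in self.people:
                raise PedigreeError(f"duplicate person id {p.person_id!r}")
            self.people[p.person_id] = p
        self.couples: Set[frozenset] = {frozenset(c) for c in couples}
        self._children: Optional[Dict[str, Tuple[str, ...]]] = None
        self._sibships: Optional[Dict[Tuple[str, str], Tuple[str, ...]]] = None
        self._partners: Optional[Dict[str, Tuple[str, ...]]] = None

    # -- basic access -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.people)

    def __contains__(self, person_id: str) -> bool:
        return person_id in self.people

    def __iter__(self):
        return iter(self.people.values())

    def person(self, person_id: str) -> Person:
        try:
            return self.people[person_id]
        except KeyError:
            raise PersonLookupError(f"unknown person id {person_id!r}") from None

    def ids(self) -> List[str]:
        return sorted(self.people)

    def parents(self, person_id: str) -> Tuple[Optional[str], Optional[str]]:
        p = self.person(person_id)
        return p.father_id, p.mother_id

    # -- lazy indexes ------------------------------------------------------

    def children_of(self, person_id: str) -> Tuple[str, ...]:
        if self._children is None:
            idx: Dict[str, list] = {}
            for p in sorted(self.people.values(), key=lambda q: q.person_id):
                for par in (p.father_id, p.mother_id):
                    if par is not None:
                        idx.setdefault(par, []).append(p.person_id)
            self._children = {k: tuple(v) for k, v in idx.items()}
        self.person(person_id)
        return self._children.get(person_id, ())

    def full_siblings_of(self, person_id: str) -> Tuple[str, ...]:
        """Persons sharing both (non-missing) parents, excluding self."""
        self.sibships()
        p = self.person(person_id)
        if p.father_id is None or p.mother_id is None:
            return ()
        sibs = self._sibships.get((p.father_id, p.mother_id), ())
        return tuple(s for s in sibs if s != person_id)

    def sibships(self) -> Dict[Tuple[str, str], Tuple[str, ...]]:
        """Mapping (father_id, mother_id) -> children ids, for full sibships."""
        if self._sibships is None:
            idx: Dict[Tuple[str, str], list] = {}
            for p in sorted(self.people.values(), key=lambda q: q.person_id):
                if p.father_id is not None and p.mother_id is not None:
                    idx.setdefault((p.father_id, p.mother_id), []).append(p.person_id)
            self._sibships = {k: tuple(v) for k, v in idx.items()}
        return self._sibships

    def partners_of(self, person_id: str) -> Tuple[str, ...]:
        """Partners via explicit couple link or shared offspring (sorted)."""
        if self._partners is None:
            idx: Dict[str, set] = {}
            for c in self.couples:
                a, b = sorted(c)
                idx.setdefault(a, set()).add(b)
                idx.setdefault(b, set()).add(a)
            for p in self.people.values():
                if p.father_id is not None and p.mother_id is not None:
                    idx.setdefault(p.father_id, set()).add(p.mother_id)
                    idx.setdefault(p.mother_id, set()).add(p.father_id)
            self._partners = {k: tuple(sorted(v)) for k, v in idx.items()}
        self.person(person_id)
        return self._partners.get(person_id, ())

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check referential and structural invariants; raise on violation."""
        for p in self.people.values():
            for role, par_id in (("father", p.father_id), ("mother", p.mother_id)):
                if par_id is None:
                    continue
                if par_id not in self.people:
                    raise ReferentialIntegrityError(
                        f"person {p.person_id!r} references missing {role} {par_id!r}"
                    )
                par = self.people[par_id]
                want = MALE if role == "father" else FEMALE
                if par.sex != want:
                    raise PedigreeError(
                        f"{role} {par_id!r} of {p.person_id!r} is not {want}"
                    )
                if p.birth_year - par.birth_year < MIN_PARENT_AGE_GAP:
                    raise PedigreeError(
                        f"parent {par_id!r} born less than {MIN_PARENT_AGE_GAP} years "
                        f"before child {p.person_id!r}"
                    )
        for c in self.couples:
            for pid in c:
                if pid not in self.people:
                    raise ReferentialIntegrityError(
                        f"couple link references missing person {pid!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # parents predate children by >=15y, so cycles are impossible when
        # birth years validate; this guards hand-built data with bad years.
        state: Dict[str, int] = {}

        def visit(pid: str):
            stack = [(pid, iter(self._parent_ids(pid)))]
            state[pid] = 1
            while stack:
                cur, it = stack[-1]
                advanced = False
                for nxt in it:
                    if state.get(nxt, 0) == 1:
                        raise PedigreeError(f"person {nxt!r} is their own ancestor")
                    if state.get(nxt, 0) == 0:
                        state[nxt] = 1
                        stack.append((nxt, iter(self._parent_ids(nxt))))
                        advanced = True
                        break
                if not advanced:
                    state[cur] = 2
                    stack.pop()

        for pid in self.people:
            if state.get(pid, 0) == 0:
                visit(pid)

    def _parent_ids(self, pid: str) -> Tuple[str, ...]:
        p = self.people[pid]
        return tuple(x for x in (p.father_id, p.mother_id) if x is not None)

    # -- equality over persisted content ----------------------------------

    def _effective_couples(self) -> Set[frozenset]:
        """Explicit couple links plus those implied by shared offspring."""
        derived = {
            frozenset((p.father_id, p.mother_id))
            for p in self.people.values()
            if p.father_id is not None and p.mother_id is not None
        }
        return self.couples | derived

    def same_pedigree(self, other: "Genealogy") -> bool:
        """Field-for-field equality of the persisted content (people rows
        and effective couple links); simulation-only liability fields are
        ignored, as is whether a couple with offspring was stored
        explicitly or recovered from the parent columns."""
        if self.family_id != other.family_id or \
                self._effective_couples() != other._effective_couples():
            return False
        if set(self.people) != set(other.people):
            return False
        return all(
            self.people[k].persisted_fields() == other.people[k].persisted_fields()
            for k in self.people
        )


# -- file I/O --------------------------------------------------------------


def write_genealogy(genealogy: Genealogy, path) -> None:
    """Write the extended FAM-style file described in the module docstring."""
    with open(path, "w", newline="") as fh:
        _write_genealogy_stream(genealogy, fh)


def _write_genealogy_stream(genealogy: Genealogy, fh: io.TextIOBase) -> None:
    fh.write("\t".join(HEADER) + "\n")
    derived = {
        frozenset((p.father_id, p.mother_id))
        for p in genealogy.people.values()
        if p.father_id is not None and p.mother_id is not None
    }
    for c in sorted(genealogy.couples - derived, key=sorted):
        a, b = sorted(c)
        fh.write(f"#couple\t{a}\t{b}\n")
    for pid in genealogy.ids():
        p = genealogy.people[pid]
        fh.write(
            "\t".join(
                [
                    genealogy.family_id,
                    p.person_id,
                    p.father_id or "0",
                    p.mother_id or "0",
                    _SEX_TO_CODE[p.sex],
                    str(p.birth_year),
                    p.birth_place,
                ]
            )
            + "\n"
        )


def read_genealogy(path) -> Genealogy:
    """Read a genealogy file; raises :class:`ParseError` with the line number
    on malformed rows and :class:`ReferentialIntegrityError` on dangling
    parent ids."""
    people: List[Person] = []
    couples: List[Tuple[str, str]] = []
    family_id = "F0"
    with open(path) as fh:
        first = fh.readline()
        if first and first.rstrip("\n").split("\t") != HEADER:
            raise ParseError(f"{path}: line 1: expected header {'	'.join(HEADER)!r}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#couple\t"):
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(f"{path}: line {lineno}: malformed couple line")
                couples.append((parts[1], parts[2]))
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(HEADER):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(HEADER)} fields, got {len(parts)}"
                )
            fam, pid, fid, mid, sex_code, by, place = parts
            if sex_code not in _CODE_TO_SEX:
                raise ParseError(f"{path}: line {lineno}: invalid sex code {sex_code!r}")
            try:
                birth_year = int(by)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: invalid birth_year {by!r}"
                ) from None
            family_id = fam
            people.append(
                Person(
                    person_id=pid,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=_CODE_TO_SEX[sex_code],
                    birth_year=birth_year,
                    birth_place=place,
                )
            )
    g = Genealogy(people, couples, family_id=family_id)
    known = set(g.people)
    for p in g.people.values():
        for par in (p.father_id, p.mother_id):
            if par is not None and par not in known:
                raise ReferentialIntegrityError(
                    f"{path}: person {p.person_id!r} references missing parent {par!r}"
                )
    for c in g.couples:
        for pid in c:
            if pid not in known:
                raise ReferentialIntegrityError(
                    f"{path}: couple link references missing person {pid!r}"
                )
    return g


RECORD_COLUMNS = ["person_id", "year", "code", "source"]


def write_records(records, path) -> None:
    """Write a diagnosis-record table (CSV with header
    person_id,year,code,source)."""
    records.to_csv(path, index=False, columns=RECORD_COLUMNS)


def read_records(path, genealogy: Optional[Genealogy] = None):
    """Read a diagnosis-record CSV; with a genealogy supplied, rows naming
    unknown persons raise :class:`ReferentialIntegrityError`."""
    import pandas as pd

    try:
        df = pd.read_csv(path, dtype={"person_id": str, "code": str, "source": str})
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: line 1: missing columns {missing}")
    if not df.empty:
        try:
            df["year"] = df["year"].astype(int)
        except (TypeError, ValueError):
            bad = df.index[pd.to_numeric(df["year"], errors="coerce").isna()]
            lineno = int(bad[0]) + 2 if len(bad) else "?"
            raise ParseError(f"{path}: line {lineno}: invalid year") from None
    if genealogy is not None and not df.empty:
        unknown = sorted(set(df["person_id"]) - set(genealogy.people))
        if unknown:
            raise ReferentialIntegrityError(
                f"{path}: records reference unknown person id {unknown[0]!r}"
                + (f" (and {len(unknown) - 1} more)" if len(unknown) > 1 else "")
            )
    return df[RECORD_COLUMNS]
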