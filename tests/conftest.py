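import pytest

from famrisk.genealogy import Genealogy
from famrisk.types import FEMALE, MALE, Person


def _p(pid, sex, by, father=None, mother=None, place="in_state"):
    return Person(person_id=pid, father_id=father, mother_id=mother,
                  sex=sex, birth_year=by, birth_place=place)


@pytest.fixture
def trio():
    """Father + mother + one child."""
    return Genealogy([
        _p("dad", MALE, 1950),
        _p("mom", FEMALE, 1952),
        _p("kid", FEMALE, 1980, father="dad", mother="mom"),
    ])


@pytest.fixture
def toy20():
    """Hand-built 20-person, 4-generation pedigree.

    Generation 0 (1900): founder couples (A1,A2) and (B1,B2).
    Generation 1 (1930): A-children C1,C2,C3; B-children D1,D2; married-in
      founders E1f, E2m, M1.  Couples: (C1,D1), (C3,E1f), (E2m,C2);
      C1 also has a child with M1; (D2,M1) is a childless couple link.
    Generation 2 (1960): F1,F2 of (C1,D1); G1 of (C3,E1f); H1,H2 of
      (E2m,C2); N1 of (C1,M1) — half-sibling of F1/F2; married-in founder
      I1f.  Couple: (H1,I1f).
    Generation 3 (1990): J1 of (H1,I1f).
    """
    people = [
        _p("A1", MALE, 1900), _p("A2", FEMALE, 1900),
        _p("B1", MALE, 1900), _p("B2", FEMALE, 1900),
        _p("C1", MALE, 1930, "A1", "A2"),
        _p("C2", FEMALE, 1930, "A1", "A2"),
        _p("C3", MALE, 1930, "A1", "A2"),
        _p("D1", FEMALE, 1930, "B1", "B2"),
        _p("D2", MALE, 1930, "B1", "B2"),
        _p("E1f", FEMALE, 1930), _p("E2m", MALE, 1930), _p("M1", FEMALE, 1930),
        _p("F1", MALE, 1960, "C1", "D1"),
        _p("F2", FEMALE, 1960, "C1", "D1"),
        _p("G1", FEMALE, 1960, "C3", "E1f"),
        _p("H1", MALE, 1960, "E2m", "C2"),
        _p("H2", FEMALE, 1960, "E2m", "C2"),
        _p("N1", MALE, 1960, "C1", "M1"),
        _p("I1f", FEMALE, 1960),
        _p("J1", MALE, 1990, "H1", "I1f"),
    ]
    g = Genealogy(people, couples=[("D2", "M1")])
    g.validate()
    return g


@pytest.fixture(scope="session")
def default_study():
    """One full default-condition study run, shared read-only by tests."""
    from famrisk.config import RunConfig
    from famrisk.pipeline import run_study

    return run_study(RunConfig())
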