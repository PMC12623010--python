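"""Domain types shared across the pipeline.

Sex is encoded as the strings ``"male"`` / ``"female"`` in memory and as the
PLINK-FAM convention 1 / 2 on disk.  Relationship labels follow the standard
first/second/third-degree taxonomy used in genealogical relative-risk studies;
``degree`` is assigned from the named relationship, never from raw path
length, so spouses stay outside the degree system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

#: relationship label -> degree of relatedness (spouse and unrelated excluded)
RELATIONSHIP_DEGREE = {
    "parent": 1,
    "child": 1,
    "sibling": 1,
    "grandparent": 2,
    "grandchild": 2,
    "aunt_uncle": 2,
    "niece_nephew": 2,
    "half_sibling": 2,
    "first_cousin": 3,
    "great_aunt_uncle": 3,
    "grand_niece_nephew": 3,
    "great_grandparent": 3,
    "great_grandchild": 3,
}

#: tie-break priority when a pair is related in more than one way: smallest
#: degree first, then this listing order.
RELATIONSHIP_ORDER = (
    "parent",
    "child",
    "sibling",
    "half_sibling",
    "grandparent",
    "grandchild",
    "aunt_uncle",
    "niece_nephew",
    "first_cousin",
    "great_aunt_uncle",
    "grand_niece_nephew",
    "great_grandparent",
    "great_grandchild",
    "spouse",
    "other",
    "unrelated",
)

#: converse relationship under role reversal (index <-> relative)
CONVERSE = {
    "parent": "child",
    "child": "parent",
    "sibling": "sibling",
    "half_sibling": "half_sibling",
    "grandparent": "grandchild",
    "grandchild": "grandparent",
    "aunt_uncle": "niece_nephew",
    "niece_nephew": "aunt_uncle",
    "first_cousin": "first_cousin",
    "great_aunt_uncle": "grand_niece_nephew",
    "grand_niece_nephew": "great_aunt_uncle",
    "great_grandparent": "great_grandchild",
    "great_grandchild": "great_grandparent",
    "spouse": "spouse",
    "other": "other",
    "unrelated": "unrelated",
}


@dataclass
class Person:
    """One genealogy member.

    ``father_id`` / ``mother_id`` are ``None`` for founders.  The liability
    components and ``affected`` flag exist only for simulated people and are
    never read by any analysis stage; real data carries ``None`` there.
    """

    person_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = FEMALE
    birth_year: int = 0
    birth_place: str = "in_state"
    liability_additive: Optional[float] = None
    liability_shared: Optional[float] = None
    liability_residual: Optional[float] = None
    affected: Optional[bool] = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def liability_total(self) -> Optional[float]:
        if self.liability_additive is None:
            return None
        return (
            self.liability_additive
            + (self.liability_shared or 0.0)
            + (self.liability_residual or 0.0)
        )

    def persisted_fields(self) -> tuple:
        """The fields written to / read from the genealogy file."""
        return (
            self.person_id,
            self.father_id,
            self.mother_id,
            self.sex,
            self.birth_year,
            self.birth_place,
        )


@dataclass(frozen=True)
class DiagnosisRecord:
    """One coded diagnosis event (year resolution)."""

    person_id: str
    year: int
    code: str
    source: str = "ehr"


@dataclass(frozen=True)
class RelativePair:
    """An (index, relative) pair with its closest relationship."""

    index_id: str
    relative_id: str
    relationship: str
    degree: Optional[int]  # 1, 2, 3 or None (spouse / other / unrelated)
    kinship: float


@dataclass(frozen=True)
class PedigreeMetrics:
    """Pedigree size and quality metrics used for matching strata."""

    person_id: str
    pedigree_size: int  # relatives of degree <= 3
    max_degree: int  # most distant degree with >= 1 relative; 0 = none

    @property
    def size_stratum(self) -> str:
        return size_stratum(self.pedigree_size)


def size_stratum(n: int) -> str:
    """Pedigree-size bin used for matching: 0-4 / 5-9 / 10+."""
    if n < 5:
        return "0-4"
    if n < 10:
        return "5-9"
    return "10+"


@dataclass
class MatchSet:
    """A case index with its matched control indexes and the stratum used."""

    case_id: str
    control_ids: tuple
    stratum: dict = field(default_factory=dict)


@dataclass
class RiskEstimate:
    """One fitted contrast: odds ratio, Wald CI, p-value and row counts."""

    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_case_relatives: int = 0
    n_control_relatives: int = 0

    def __post_init__(self):
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError(
                f"inconsistent estimate for {self.term!r}: "
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket {self.odds_ratio}"
            )
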