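"""Family-history enrichment scoring for case selection.

Discovery-stage cases in enriched-sampling designs are chosen for early
onset, familial aggregation, or bilateral disease.  The scoring system here
quantifies that enrichment per family:

* every breast-cancer diagnosis in the family contributes an age score —
  1 at age 50 or older, 1.5 at 40–49, 2 below 40;
* each affected person's diagnoses are weighted by their relationship to the
  index case — weight 1 for the index, 0.5 for first-degree relatives, 0.25
  for second-degree relatives;
* bilateral cases contribute both diagnoses (a bilateral index with both
  cancers at ≥50 therefore scores 2);
* the family total is the sum over all contributions.

An eligibility rule gates entry to the discovery set: the index must be
diagnosed before 50 and have either one first-degree relative diagnosed
before 50, or two affected relatives diagnosed before 60.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "FamilyMember",
    "Pedigree",
    "ScoreRules",
    "FamilyScore",
    "SCORE_BINS",
    "age_score",
    "member_contribution",
    "family_score",
    "eligibility",
    "bin_label",
    "bin_scores",
]

#: Score bins reported for the discovery-set distribution, left-closed.
SCORE_BINS = ("<2", "[2,2.5)", "[2.5,3)", "[3,3.5)", "[3.5,4)", ">=4")

_RELATIONS = ("index", "first_degree", "second_degree")


@dataclass
class FamilyMember:
    """One pedigree member; ``ages_at_dx`` holds one diagnosis age per
    cancer (two entries for bilateral cases), empty when unaffected."""

    member_id: str
    relation: str
    ages_at_dx: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.relation not in _RELATIONS:
            raise ValueError(f"relation must be one of {_RELATIONS}")
        self.ages_at_dx = tuple(self.ages_at_dx)
        if any(a <= 0 for a in self.ages_at_dx):
            raise ValueError("diagnosis ages must be positive")

    @property
    def affected(self) -> bool:
        return len(self.ages_at_dx) > 0

    @property
    def bilateral(self) -> bool:
        return len(self.ages_at_dx) >= 2


@dataclass
class Pedigree:
    family_id: str
    members: tuple[FamilyMember, ...]

    def __post_init__(self) -> None:
        self.members = tuple(self.members)

    @property
    def index(self) -> FamilyMember:
        for m in self.members:
            if m.relation == "index":
                return m
        raise ValueError(f"pedigree {self.family_id} has no index case")

    @property
    def relatives(self) -> tuple[FamilyMember, ...]:
        return tuple(m for m in self.members if m.relation != "index")


@dataclass(frozen=True)
class ScoreRules:
    """Age-score cutpoints and degree weights.

    Defaults implement the standard rule set; override only deliberately.
    Age bands are left-closed: [50, ∞) → 1, [40, 50) → 1.5, (0, 40) → 2.
    """

    age_cutoffs: tuple[float, float] = (40.0, 50.0)
    age_values: tuple[float, float, float] = (2.0, 1.5, 1.0)  # <40, 40-49, >=50
    degree_weights: dict = field(
        default_factory=lambda: {"index": 1.0, "first_degree": 0.5, "second_degree": 0.25}
    )


DEFAULT_RULES = ScoreRules()


def age_score(age: float, rules: ScoreRules = DEFAULT_RULES) -> float:
    """Per-diagnosis age score: 2 below 40, 1.5 at 40–49, 1 at 50+."""
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    young, old = rules.age_cutoffs
    if age < young:
        return rules.age_values[0]
    if age < old:
        return rules.age_values[1]
    return rules.age_values[2]


def member_contribution(member: FamilyMember, rules: ScoreRules = DEFAULT_RULES) -> float:
    """Degree weight times the sum of age scores over the member's
    diagnoses; bilateral cases contribute both.  Unaffected members
    contribute 0."""
    if not member.affected:
        return 0.0
    weight = rules.degree_weights[member.relation]
    return weight * sum(age_score(a, rules) for a in member.ages_at_dx)


@dataclass
class FamilyScore:
    family_id: str
    total: float
    contributions: dict
    bin: str
    eligible: bool


def family_score(pedigree: Pedigree, rules: ScoreRules = DEFAULT_RULES) -> FamilyScore:
    """Total enrichment score of a family: the sum of weighted per-diagnosis
    age scores over all affected members.  Requires an affected index."""
    index = pedigree.index  # raises if absent
    if not index.affected:
        raise ValueError(f"index case of {pedigree.family_id} must be affected")
    contributions = {
        m.member_id: member_contribution(m, rules)
        for m in pedigree.members
        if m.affected
    }
    total = sum(contributions.values())
    return FamilyScore(
        family_id=pedigree.family_id,
        total=total,
        contributions=contributions,
        bin=bin_label(total),
        eligible=eligibility(pedigree),
    )


def eligibility(pedigree: Pedigree) -> bool:
    """Discovery-set eligibility: index diagnosed before 50 and either one
    affected first-degree relative diagnosed before 50, or two affected
    relatives (any degree) diagnosed before 60."""
    index = pedigree.index
    if not index.affected or min(index.ages_at_dx) >= 50:
        return False
    first_lt50 = sum(
        1
        for m in pedigree.relatives
        if m.relation == "first_degree" and m.affected and min(m.ages_at_dx) < 50
    )
    any_lt60 = sum(
        1 for m in pedigree.relatives if m.affected and min(m.ages_at_dx) < 60
    )
    return first_lt50 >= 1 or any_lt60 >= 2


def bin_label(total: float) -> str:
    """Left-closed score bin containing ``total``."""
    if total < 2.0:
        return SCORE_BINS[0]
    if total < 2.5:
        return SCORE_BINS[1]
    if total < 3.0:
        return SCORE_BINS[2]
    if total < 3.5:
        return SCORE_BINS[3]
    if total < 4.0:
        return SCORE_BINS[4]
    return SCORE_BINS[5]


def bin_scores(scores: Iterable[float]):
    """Fractional score distribution over the six reporting bins.

    Returns ``dict bin -> fraction`` summing to 1, or ``None`` on empty
    input.
    """
    scores = list(scores)
    if not scores:
        return None
    counts = {b: 0 for b in SCORE_BINS}
    for s in scores:
        counts[bin_label(s)] += 1
    n = len(scores)
    return {b: c / n for b, c in counts.items()}
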