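"""Core domain records for a kin-cohort family registry.

A kin-cohort study ascertains families through a genotyped proband and
treats her female first-degree relatives (mother, sisters, daughters) as a
retrospective cohort.  Each woman contributes an age at breast and/or
ovarian cancer diagnosis where one occurred, ages of risk-reducing surgery
(bilateral salpingo-oophorectomy, RRSO; bilateral mastectomy, RRM), and an
age at last follow-up or death.  Follow-up for a given outcome starts at
birth and ends at the event or at the earliest applicable censoring cause.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "ROLES",
    "RELATIVE_ROLES",
    "GENOTYPES",
    "OUTCOMES",
    "IndividualRecord",
    "Family",
    "FollowUpRecord",
    "ValidationError",
    "derive_followup",
]

ROLES = frozenset({"proband", "mother", "sister", "daughter"})
RELATIVE_ROLES = frozenset({"mother", "sister", "daughter"})
GENOTYPES = frozenset({"carrier", "noncarrier", "untested"})
OUTCOMES = ("breast", "ovarian")

#: roles recognised as more distant kin; dropped (with a warning) rather than
#: rejected, since questionnaires often list them.
EXTENDED_ROLES = frozenset(
    {"grandmother", "granddaughter", "aunt", "niece", "cousin", "other"}
)

MAX_AGE = 120.0


class ValidationError(ValueError):
    """A record or family violates a structural invariant."""


def _check_age(name: str, value: Optional[float]) -> Optional[float]:
    if value is None:
        return None
    value = float(value)
    if not (0.0 <= value <= MAX_AGE):
        raise ValidationError(f"{name}={value} outside [0, {MAX_AGE}]")
    return value


@dataclass
class IndividualRecord:
    """One woman in the registry.

    All ages are in years; event/surgery ages are ``None`` when the event
    did not occur during follow-up.  Male relatives are out of scope: every
    record is female, so breast and ovarian outcomes apply to all.
    """

    family_id: str
    person_id: str
    role: str
    genotype: str = "untested"
    age_breast_dx: Optional[float] = None
    age_ovarian_dx: Optional[float] = None
    age_rrso: Optional[float] = None
    age_rrm: Optional[float] = None
    age_last: Optional[float] = None
    vital: str = "alive"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"person {self.person_id!r}: unknown role {self.role!r}"
            )
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"person {self.person_id!r}: unknown genotype {self.genotype!r}"
            )
        if self.vital not in ("alive", "dead"):
            raise ValidationError(
                f"person {self.person_id!r}: unknown vital status {self.vital!r}"
            )
        for name in ("age_breast_dx", "age_ovarian_dx", "age_rrso",
                     "age_rrm", "age_last"):
            object.__setattr__(self, name, _check_age(name, getattr(self, name)))
        if self.age_last is not None:
            for name in ("age_breast_dx", "age_ovarian_dx", "age_rrso", "age_rrm"):
                age = getattr(self, name)
                if age is not None and age > self.age_last:
                    raise ValidationError(
                        f"person {self.person_id!r}: {name}={age} exceeds "
                        f"age_last={self.age_last}"
                    )

    def with_genotype(self, genotype: str) -> "IndividualRecord":
        return replace(self, genotype=genotype)


@dataclass
class Family:
    """A proband plus her female first-degree relatives.

    ``proband_gene_status`` records which gene (if any) the proband tested
    positive for; mutation-negative probands carry the status ``negative``.
    """

    family_id: str
    proband: IndividualRecord
    relatives: list[IndividualRecord] = field(default_factory=list)
    proband_gene_status: str = "negative"

    def __post_init__(self) -> None:
        if self.proband.role != "proband":
            raise ValidationError(
                f"family {self.family_id!r}: proband record has role "
                f"{self.proband.role!r}"
            )
        if self.proband.genotype == "untested":
            raise ValidationError(
                f"family {self.family_id!r}: proband genotype may not be untested"
            )
        for rel in self.relatives:
            if rel.role not in RELATIVE_ROLES:
                raise ValidationError(
                    f"family {self.family_id!r}: relative {rel.person_id!r} "
                    f"has non-first-degree role {rel.role!r}"
                )

    @property
    def members(self) -> list[IndividualRecord]:
        return [self.proband, *self.relatives]


@dataclass(frozen=True)
class FollowUpRecord:
    """Derived (time, event) pair for one woman and one outcome.

    ``event`` is the indicator delta (1 = the outcome occurred at ``time``);
    for censored records ``censor_reason`` names the earliest censoring
    cause.
    """

    family_id: str
    person_id: str
    outcome: str
    time: float
    event: int
    censor_reason: str = "none"

    def __post_init__(self) -> None:
        if self.event == 1 and self.censor_reason != "none":
            raise ValidationError("event records carry censor_reason='none'")


# censoring causes considered per outcome, in tie-break priority order
_BREAST_CENSORS = (
    ("age_ovarian_dx", "competing_cancer"),
    ("age_rrso", "rrso"),
    ("age_rrm", "rrm"),
    ("age_last", "last_followup"),
)
_OVARIAN_CENSORS = (
    ("age_rrso", "rrso"),
    ("age_last", "last_followup"),
)


def derive_followup(individual: IndividualRecord, outcome: str) -> FollowUpRecord:
    """Apply the outcome-specific censoring rules to one woman.

    Breast follow-up runs from birth to breast cancer, censored at the
    earliest of ovarian cancer, RRSO, RRM, or last follow-up / death.
    Ovarian follow-up runs from birth to ovarian cancer, censored at the
    earliest of RRSO or last follow-up / death.  A within-year tie between
    the event and a censoring cause is resolved in favour of the event, so
    a breast diagnosis at the age of RRM still counts as a case.

    Raises
    ------
    ValidationError
        if no candidate age is available (``age_last`` absent and no other
        usable age).
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    event_age = (individual.age_breast_dx if outcome == "breast"
                 else individual.age_ovarian_dx)
    censors = _BREAST_CENSORS if outcome == "breast" else _OVARIAN_CENSORS

    best_age: Optional[float] = None
    best_reason = "none"
    for attr, reason in censors:
        age = getattr(individual, attr)
        if age is None:
            continue
        if best_age is None or age < best_age:
            best_age = age
            if reason == "last_followup" and individual.vital == "dead":
                reason = "death"
            best_reason = reason

    if event_age is not None and (best_age is None or event_age <= best_age):
        return FollowUpRecord(individual.family_id, individual.person_id,
                              outcome, event_age, 1)
    if best_age is None:
        raise ValidationError(
            f"person {individual.person_id!r}: no usable follow-up age for "
            f"outcome {outcome!r}"
        )
    return FollowUpRecord(individual.family_id, individual.person_id,
                          outcome, best_age, 0, best_reason)
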