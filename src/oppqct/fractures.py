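"""Semiquantitative vertebral fracture grading and incident-fracture rules.

Vertebral deformities are graded 0-3 from the fractional height reduction of
the most collapsed of the anterior, middle, and posterior heights relative to
a reference (expected) height: grade 1 at 20-25% reduction, grade 2 at
25-40%, grade 3 at >= 40%.  The thresholds live in an editable table.

An incident fracture between baseline and follow-up is a new deformity in a
previously normal vertebra, or a grade increase in a vertebra whose baseline
fracture was consolidated (no bone-marrow edema on recent MRI).  Vertebrae
with active fracture signs at baseline (edema on MRI or callus on CT) are
excluded from incident ascertainment entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InputError

__all__ = [
    "GENANT_THRESHOLDS",
    "VertebralHeights",
    "GenantAssessment",
    "VertebraFollowUp",
    "genant_grade",
    "incident_fracture",
    "patient_incident_status",
]

#: Height-reduction lower bounds for grades 1, 2, 3 (fractions of reference).
GENANT_THRESHOLDS: tuple[float, float, float] = (0.20, 0.25, 0.40)


@dataclass(frozen=True)
class VertebralHeights:
    """Anterior/middle/posterior heights of one vertebra, mm, plus reference."""

    level: str
    anterior: float
    middle: float
    posterior: float
    reference_height: float

    def __post_init__(self) -> None:
        for name in ("anterior", "middle", "posterior", "reference_height"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


@dataclass(frozen=True)
class GenantAssessment:
    level: str
    height_reduction: float
    grade: int


@dataclass(frozen=True)
class VertebraFollowUp:
    """Grades of one vertebra at baseline and follow-up plus healing flags."""

    level: str
    baseline_grade: int
    followup_grade: int
    consolidated_at_baseline: bool = True
    active_signs: bool = False

    def __post_init__(self) -> None:
        for g in (self.baseline_grade, self.followup_grade):
            if g not in (0, 1, 2, 3):
                raise InputError("grades must be integers 0..3")


def genant_grade(
    h: VertebralHeights,
    thresholds: Sequence[float] = GENANT_THRESHOLDS,
) -> GenantAssessment:
    """Grade a vertebra from its worst height ratio.

    ``height_reduction = 1 - min(anterior, middle, posterior) / reference``;
    the grade is the number of thresholds at or below the reduction
    (left-closed intervals).
    """
    t1, t2, t3 = thresholds
    if not 0 < t1 < t2 < t3:
        raise InputError("thresholds must be increasing and positive")
    reduction = 1.0 - min(h.anterior, h.middle, h.posterior) / h.reference_height
    # tiny tolerance so height ratios landing exactly on a threshold are not
    # pushed below it by floating-point division
    grade = sum(reduction >= t - 1e-12 for t in (t1, t2, t3))
    return GenantAssessment(level=h.level, height_reduction=reduction, grade=grade)


def incident_fracture(v: VertebraFollowUp) -> bool:
    """Whether one vertebra sustained an incident fracture.

    True iff the vertebra was normal at baseline and deformed at follow-up, or
    carried a consolidated baseline fracture that increased by at least one
    grade.  A vertebra with active fracture signs at baseline never counts.
    """
    if v.active_signs:
        return False
    if v.baseline_grade == 0:
        return v.followup_grade >= 1
    return v.consolidated_at_baseline and v.followup_grade >= v.baseline_grade + 1


def patient_incident_status(
    vertebrae: Iterable[VertebraFollowUp],
) -> tuple[bool, list[str]]:
    """Patient-level incident status plus the contributing vertebral levels."""
    vertebrae = list(vertebrae)
    if not vertebrae:
        raise InputError("no vertebrae supplied")
    levels = [v.level for v in vertebrae if incident_fracture(v)]
    return bool(levels), levels
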