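"""Sentinel-diagnosis assignment, subgroups, complexity flags, exclusions.

A patient's diagnosis concepts are pooled across *all* of their records
(later procedures often carry fuller diagnostic coding), and matched against
the dictionary's diagnosis markers.  When markers for several sentinel CHDs
are present, the highest-precedence (most clinically complex) diagnosis
wins: HLHS > FUH > TGA > PA > AVSD > TOF > AS > COARCT > VSD.  Assignment is
a pure function of the pooled concept set, so it is invariant to record
order and duplication.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .dictionary import ConceptDictionary
from .records import (
    DIAGNOSIS_PRECEDENCE,
    Diagnosis,
    PatientHistory,
    Residency,
)


@dataclass(frozen=True)
class SentinelDiagnosis:
    diagnosis: Diagnosis
    subgroup: Optional[str]
    #: ordered record of rules fired, for audit export
    trace: tuple[str, ...] = ()


class ExclusionReason(str, Enum):
    OUTSIDE_ENGLAND_WALES = "outside_england_wales"
    NON_NHS = "non_nhs"
    BORN_OUTSIDE_WINDOW = "born_outside_window"
    NO_CARDIAC_CODES = "no_cardiac_codes"
    MAJOR_DATA_ERROR = "major_data_error"
    NOT_SENTINEL = "not_sentinel"


@dataclass(frozen=True)
class ExclusionOutcome:
    excluded: bool
    reason: Optional[ExclusionReason] = None

    def __post_init__(self) -> None:
        assert self.excluded == (self.reason is not None)


def assign_sentinel_diagnosis(
    history: PatientHistory,
    dictionary: ConceptDictionary,
    precedence: Sequence[Diagnosis] = DIAGNOSIS_PRECEDENCE,
) -> SentinelDiagnosis:
    """Assign the sentinel diagnosis (or NONE) from pooled diagnosis concepts."""
    pool = history.pooled_diagnosis_concepts()
    trace: list[str] = []
    if not pool:
        trace.append("empty diagnosis concept pool")
        return SentinelDiagnosis(Diagnosis.NONE, None, tuple(trace))

    candidates = {
        dictionary.diagnosis_markers[c] for c in pool if c in dictionary.diagnosis_markers
    }
    for dx in sorted(candidates, key=lambda d: list(precedence).index(d)):
        trace.append(f"candidate:{dx.value}")
    if not candidates:
        trace.append("no sentinel markers present")
        return SentinelDiagnosis(Diagnosis.NONE, None, tuple(trace))

    winner = next(dx for dx in precedence if dx in candidates)
    trace.append(f"winner:{winner.value} (precedence)")
    subgroup = assign_subgroup(winner, pool, dictionary, trace)
    return SentinelDiagnosis(winner, subgroup, tuple(trace))


def assign_subgroup(
    diagnosis: Diagnosis,
    concepts: frozenset[str],
    dictionary: ConceptDictionary,
    trace: Optional[list[str]] = None,
) -> str:
    """Per-diagnosis subgroup from modifier concepts; residual default otherwise."""
    if diagnosis is Diagnosis.NONE:
        raise ValueError("cannot assign a subgroup without a sentinel diagnosis")
    rules, default = dictionary.subgroup_rules[diagnosis]
    for rule in rules:
        if rule.when_all <= concepts:
            if trace is not None:
                trace.append(
                    f"subgroup:{rule.subgroup} (markers {sorted(rule.when_all)})"
                )
            return rule.subgroup
    if trace is not None:
        trace.append(f"subgroup:{default} (residual)")
    return default


def derive_complexity_flags(
    history: PatientHistory, dictionary: ConceptDictionary
) -> tuple[bool, bool]:
    """(prematurity, congenital comorbidity): true iff any record carries a marker."""
    pool = history.pooled_diagnosis_concepts() | history.pooled_procedure_concepts()
    prematurity = bool(pool & dictionary.prematurity_concepts)
    comorbidity = bool(pool & dictionary.comorbidity_concepts)
    return prematurity, comorbidity


def _has_major_data_error(history: PatientHistory) -> bool:
    if not history.patient_id:
        return True
    prev = None
    for rec in history.records:
        if prev is not None and rec.age_days < prev:
            return True  # age regression: sorting contract violated upstream
        prev = rec.age_days
        if rec.discharge_age_days is not None and rec.discharge_age_days < rec.age_days:
            return True
    return False


def apply_exclusions(
    history: PatientHistory,
    diagnosis: Optional[Diagnosis] = None,
) -> ExclusionOutcome:
    """Cohort inclusion rules, first matching reason in fixed order.

    Order: born outside the study window, then residency outside England and
    Wales, then non-NHS status, then absence of any cardiac procedure codes,
    then major data errors, then (when ``diagnosis`` is given) non-sentinel
    diagnosis.  Pass ``diagnosis=None`` before phenotyping to evaluate only
    the structural rules.
    """
    if any(not r.born_in_window for r in history.records):
        return ExclusionOutcome(True, ExclusionReason.BORN_OUTSIDE_WINDOW)
    residencies = {r.residency for r in history.records}
    if Residency.OTHER in residencies:
        return ExclusionOutcome(True, ExclusionReason.OUTSIDE_ENGLAND_WALES)
    if Residency.NON_NHS in residencies:
        return ExclusionOutcome(True, ExclusionReason.NON_NHS)
    if not any(r.procedure_concepts for r in history.records):
        return ExclusionOutcome(True, ExclusionReason.NO_CARDIAC_CODES)
    if _has_major_data_error(history):
        return ExclusionOutcome(True, ExclusionReason.MAJOR_DATA_ERROR)
    if diagnosis is not None and diagnosis is Diagnosis.NONE:
        return ExclusionOutcome(True, ExclusionReason.NOT_SENTINEL)
    return ExclusionOutcome(False, None)
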