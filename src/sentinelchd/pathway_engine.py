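"""Pathway-role labelling, the one-occurrence rule, and reintervention adjudication.

Each sentinel diagnosis has an expected interventional treatment pathway:
an optional short-lived *prepathway* procedure (e.g. balloon atrial
septostomy in TGA), the staged palliative course (stage 1, stage 2 Glenn,
stage 3 Fontan) for functionally single-ventricle circulations, and/or a
*reparative* procedure for biventricular ones.  Scanning a patient's records
in age order, the first record bearing each role fills that pathway slot;
every later occurrence of a pathway procedure, and every other therapeutic
intervention, is a reintervention.  Transplants are competing events, never
reinterventions; purely diagnostic records are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .dictionary import ConceptDictionary
from .records import (
    SLOT_ROLES,
    SURGICAL_MODALITIES,
    Diagnosis,
    Modality,
    PatientHistory,
    ProcedureRecord,
    Role,
)

#: reintervention category per modality
SURGICAL_CATEGORY = "surgical"
CATHETER_CATEGORY = "catheter"


def reintervention_category(modality: Modality) -> str:
    return SURGICAL_CATEGORY if modality in SURGICAL_MODALITIES else CATHETER_CATEGORY


@dataclass(frozen=True)
class Reintervention:
    record_index: int
    age_days: int
    modality: Modality
    category: str


PATHWAY_SINGLE_VENTRICLE = "single_ventricle"
PATHWAY_BIVENTRICULAR = "biventricular"
PATHWAY_INDETERMINATE = "indeterminate"


@dataclass
class PathwayAssignment:
    """Per-patient pathway slots, reintervention list and pathway type."""

    slots: dict[Role, Optional[int]]  # slot role -> record index in history
    reinterventions: list[Reintervention]
    pathway_type: str
    transplant_age_days: Optional[int] = None
    #: per-record rationale lines for audit export
    trace: tuple[str, ...] = ()

    def slot_age(self, history: PatientHistory, role: Role) -> Optional[int]:
        idx = self.slots.get(role)
        return None if idx is None else history.records[idx].age_days

    def filled(self, role: Role) -> bool:
        return self.slots.get(role) is not None


def classify_procedure_role(
    record: ProcedureRecord,
    diagnosis: Diagnosis,
    dictionary: ConceptDictionary,
) -> Role:
    """Pathway role of one record for the patient's diagnosis."""
    if diagnosis is Diagnosis.NONE:
        raise ValueError("procedure roles are defined per sentinel diagnosis")
    return dictionary.role_of(diagnosis, record.procedure_concepts)


def assign_pathway(
    history: PatientHistory,
    diagnosis: Diagnosis,
    dictionary: ConceptDictionary,
) -> PathwayAssignment:
    """Fill pathway slots and adjudicate reinterventions for one patient.

    Records must be sorted by age (the linkage step guarantees this); ties
    keep file order, so when a slot procedure and its same-day repeat share
    an age the earlier row fills the slot, deterministically.
    """
    slots: dict[Role, Optional[int]] = {role: None for role in SLOT_ROLES}
    reints: list[Reintervention] = []
    transplant_age: Optional[int] = None
    trace: list[str] = []

    for idx, rec in enumerate(history.records):
        role = classify_procedure_role(rec, diagnosis, dictionary)
        if role is Role.TRANSPLANT:
            if transplant_age is None:
                transplant_age = rec.age_days
            trace.append(f"{idx}:transplant@{rec.age_days}")
            continue
        if role is Role.PREPATHWAY:
            if slots[Role.PREPATHWAY] is None:
                slots[Role.PREPATHWAY] = idx
                trace.append(f"{idx}:slot:prepathway@{rec.age_days}")
            else:
                # repeat prepathway procedures are never reinterventions
                trace.append(f"{idx}:prepathway-repeat@{rec.age_days}:ignored")
            continue
        if role is Role.OTHER:
            if dictionary.is_diagnostic_only(rec.procedure_concepts):
                trace.append(f"{idx}:diagnostic@{rec.age_days}:ignored")
                continue
            reints.append(
                Reintervention(
                    idx, rec.age_days, rec.modality, reintervention_category(rec.modality)
                )
            )
            trace.append(f"{idx}:reintervention(other)@{rec.age_days}")
            continue
        # stage 1/2/3 or repair: one occurrence fills the slot, repeats are
        # reinterventions (reoperations)
        if slots[role] is None:
            slots[role] = idx
            trace.append(f"{idx}:slot:{role.value}@{rec.age_days}")
        else:
            reints.append(
                Reintervention(
                    idx, rec.age_days, rec.modality, reintervention_category(rec.modality)
                )
            )
            trace.append(f"{idx}:reintervention(repeat-{role.value})@{rec.age_days}")

    assignment = PathwayAssignment(
        slots=slots,
        reinterventions=reints,
        pathway_type=PATHWAY_INDETERMINATE,
        transplant_age_days=transplant_age,
        trace=tuple(trace),
    )
    assignment.pathway_type = determine_pathway_type(assignment)
    return assignment


def determine_pathway_type(assignment: PathwayAssignment) -> str:
    """Single-ventricle, biventricular or indeterminate pathway.

    Single ventricle: stage 2 or 3 reached, no repair.  Biventricular:
    repaired without staged palliation beyond stage 1.  Both or neither is
    indeterminate and a target for data-quality review.
    """
    staged = assignment.filled(Role.STAGE2) or assignment.filled(Role.STAGE3)
    repaired = assignment.filled(Role.REPAIR)
    if staged and not repaired:
        return PATHWAY_SINGLE_VENTRICLE
    if repaired and not staged:
        return PATHWAY_BIVENTRICULAR
    return PATHWAY_INDETERMINATE


def pathway_completion_summary(
    assignments_by_group: Mapping[str, Iterable[PathwayAssignment]],
) -> pd.DataFrame:
    """Per-group slot completion counts and percentages (1 decimal).

    ``assignments_by_group`` maps a group label (diagnosis or subgroup) to
    that group's pathway assignments; callers apply any quality-flag
    exclusion policy beforehand.  Percentages are absent for empty groups.
    """
    rows = []
    for group, assignments in assignments_by_group.items():
        assignments = list(assignments)
        n = len(assignments)
        for role in SLOT_ROLES:
            n_filled = sum(1 for a in assignments if a.filled(role))
            pct = round(100.0 * n_filled / n, 1) if n else None
            rows.append(
                {
                    "group": group,
                    "slot": role.value,
                    "n_patients": n,
                    "n_filled": n_filled,
                    "pct_filled": pct,
                }
            )
    return pd.DataFrame(rows, columns=["group", "slot", "n_patients", "n_filled", "pct_filled"])
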