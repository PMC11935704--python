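"""Core domain types for procedure-level congenital cardiac registry data.

The registry is procedure based: one row per cardiac procedure, carrying the
diagnostic and procedural concept codes recorded at that admission. Linking
rows on the pseudonymous patient identifier turns it into a patient-based
data set, with life status (death age and/or alive-confirmation age) joined
from a separate table.

All ages are integer days since birth; the report ages of 1, 5 and 10 years
are ``365.25 * k`` days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

DAYS_PER_YEAR = 365.25
#: default ages (years) at which survival and reintervention are reported
REPORT_AGES_YEARS = (1.0, 5.0, 10.0)


def years_to_days(years: float) -> float:
    return years * DAYS_PER_YEAR


class Modality(str, Enum):
    """Broad procedure modality as recorded by the audit."""

    BYPASS_SURGERY = "bypass_surgery"
    NONBYPASS_SURGERY = "nonbypass_surgery"
    HYBRID = "hybrid"
    CATHETER = "catheter"
    ELECTROPHYSIOLOGY = "electrophysiology"


#: modalities counted as surgical reinterventions
SURGICAL_MODALITIES = frozenset(
    {Modality.BYPASS_SURGERY, Modality.NONBYPASS_SURGERY, Modality.HYBRID}
)
#: modalities counted as interventional-cardiology reinterventions
CATHETER_MODALITIES = frozenset({Modality.CATHETER, Modality.ELECTROPHYSIOLOGY})


class Residency(str, Enum):
    ENGLAND_WALES = "england_wales"
    OTHER = "other"
    NON_NHS = "non_nhs"


class Diagnosis(str, Enum):
    """The nine sentinel CHD diagnoses, plus ``NONE`` for non-sentinel."""

    HLHS = "HLHS"
    FUH = "FUH"
    TGA = "TGA"
    PA = "PA"
    AVSD = "AVSD"
    TOF = "TOF"
    AS = "AS"
    COARCT = "COARCT"
    VSD = "VSD"
    NONE = "none"


#: default precedence: decreasing clinical complexity.  When markers for
#: several sentinel diagnoses are present the most complex wins.
DIAGNOSIS_PRECEDENCE: tuple[Diagnosis, ...] = (
    Diagnosis.HLHS,
    Diagnosis.FUH,
    Diagnosis.TGA,
    Diagnosis.PA,
    Diagnosis.AVSD,
    Diagnosis.TOF,
    Diagnosis.AS,
    Diagnosis.COARCT,
    Diagnosis.VSD,
)

#: valid subgroups per diagnosis; the last entry is the residual subgroup
#: used when no modifier marker is present.
SUBGROUPS: dict[Diagnosis, tuple[str, ...]] = {
    Diagnosis.HLHS: ("hlhs",),
    Diagnosis.FUH: ("double_inlet_ventricle", "tricuspid_atresia"),
    Diagnosis.TGA: ("complex_with_PS", "complex_without_PS", "intact_septum"),
    Diagnosis.PA: ("with_VSD", "intact_septum"),
    Diagnosis.AVSD: ("tetralogy_AVSD", "unbalanced", "partial", "complete"),
    Diagnosis.TOF: ("absent_pulm_valve", "DORV", "standard"),
    Diagnosis.AS: ("multilevel_LHO", "isolated"),
    Diagnosis.COARCT: ("with_VSD", "isolated"),
    Diagnosis.VSD: ("multiple", "isolated"),
}


class Role(str, Enum):
    """Pathway role of a procedure for a given sentinel diagnosis."""

    PREPATHWAY = "prepathway"
    STAGE1 = "stage1"
    STAGE2 = "stage2"
    STAGE3 = "stage3"
    REPAIR = "repair"
    TRANSPLANT = "transplant"
    OTHER = "other"


#: pathway slots, in scan order; each fillable at most once per patient
SLOT_ROLES: tuple[Role, ...] = (
    Role.PREPATHWAY,
    Role.STAGE1,
    Role.STAGE2,
    Role.STAGE3,
    Role.REPAIR,
)

#: if a record carries several role-bearing concepts the most specific
#: (latest-stage) role wins
ROLE_PRIORITY: tuple[Role, ...] = (
    Role.TRANSPLANT,
    Role.STAGE3,
    Role.STAGE2,
    Role.STAGE1,
    Role.REPAIR,
    Role.PREPATHWAY,
)


class RecordError(ValueError):
    """A procedure or life-status record violates a structural invariant."""


@dataclass(frozen=True)
class ProcedureRecord:
    """One registry row: a single cardiac procedure for one patient."""

    patient_id: str
    age_days: int
    procedure_concepts: frozenset[str]
    diagnosis_concepts: frozenset[str]
    modality: Modality
    discharge_age_days: Optional[int] = None
    center_id: str = ""
    residency: Residency = Residency.ENGLAND_WALES
    born_in_window: bool = True

    def __post_init__(self) -> None:
        if self.age_days < 0:
            raise RecordError(
                f"negative age_days ({self.age_days}) for patient {self.patient_id!r}"
            )
        if self.discharge_age_days is not None and self.discharge_age_days < self.age_days:
            raise RecordError(
                f"discharge before procedure for patient {self.patient_id!r}: "
                f"{self.discharge_age_days} < {self.age_days}"
            )


@dataclass
class LifeStatus:
    """Life-status row: audit-recorded and national-register death/alive ages."""

    patient_id: str
    nchda_death_age_days: Optional[int] = None
    ons_death_age_days: Optional[int] = None
    ons_alive_confirm_age_days: Optional[int] = None

    def is_empty(self) -> bool:
        return (
            self.nchda_death_age_days is None
            and self.ons_death_age_days is None
            and self.ons_alive_confirm_age_days is None
        )

    @classmethod
    def empty(cls, patient_id: str) -> "LifeStatus":
        return cls(patient_id=patient_id)


@dataclass
class PatientHistory:
    """All procedure records of one patient, sorted by age, plus life status."""

    patient_id: str
    records: list[ProcedureRecord]
    life_status: LifeStatus
    prematurity: bool = False
    comorbidity: bool = False

    def pooled_diagnosis_concepts(self) -> frozenset[str]:
        out: set[str] = set()
        for rec in self.records:
            out |= rec.diagnosis_concepts
        return frozenset(out)

    def pooled_procedure_concepts(self) -> frozenset[str]:
        out: set[str] = set()
        for rec in self.records:
            out |= rec.procedure_concepts
        return frozenset(out)

    def first_procedure_age(self) -> Optional[int]:
        return self.records[0].age_days if self.records else None

    def last_discharge_age(self) -> Optional[int]:
        ages = [
            r.discharge_age_days if r.discharge_age_days is not None else r.age_days
            for r in self.records
        ]
        return max(ages) if ages else None
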