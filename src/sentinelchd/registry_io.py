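"""Readers, writers and patient linkage for the registry CSV dialect.

Input dialect: comma-separated UTF-8, one procedure per row; multi-valued
code fields are semicolon-joined within a cell.  Loaders are forgiving at
row level (a malformed row is dropped and logged) but strict at schema
level (a missing mandatory column aborts the load).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .dictionary import ConceptDictionary
from .records import (
    LifeStatus,
    Modality,
    PatientHistory,
    ProcedureRecord,
    RecordError,
    Residency,
)

logger = logging.getLogger(__name__)

PROCEDURE_COLUMNS = (
    "patient_id",
    "age_days",
    "procedure_codes",
    "diagnosis_codes",
    "modality",
    "discharge_age_days",
    "center_id",
    "residency",
    "born_in_window",
)

LIFE_COLUMNS = (
    "patient_id",
    "nchda_death_age_days",
    "ons_death_age_days",
    "ons_alive_confirm_age_days",
)


class SchemaError(ValueError):
    """The file header does not match the configured schema."""


class LinkageError(ValueError):
    """Conflicting life-status rows for one patient."""


@dataclass
class LoadReport:
    """Row counts, drop reasons and untranslated-code tallies for one load."""

    n_rows: int = 0
    n_dropped: int = 0
    row_errors: list[tuple[int, str]] = field(default_factory=list)
    untranslated: Counter = field(default_factory=Counter)


@dataclass
class LoadResult:
    records: list[ProcedureRecord]
    report: LoadReport

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")


def _split_codes(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [c.strip() for c in str(cell).split(";") if c.strip()]


def _opt_int(cell) -> Optional[int]:
    if cell is None or cell == "" or (isinstance(cell, float) and pd.isna(cell)):
        return None
    return int(float(cell))


def _parse_bool(cell) -> bool:
    return str(cell).strip().lower() in {"true", "1", "yes"}


def read_procedure_table(
    path: Union[str, Path], dictionary: ConceptDictionary
) -> LoadResult:
    """Read a procedure CSV, translating raw codes to concepts.

    Untranslatable codes are tallied in the report (the record is kept);
    rows with unparseable or negative ages are dropped and logged.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, PROCEDURE_COLUMNS, path)
    report = LoadReport(n_rows=len(df))
    records: list[ProcedureRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            age = int(str(row.age_days))
            proc_concepts, unknown_p = dictionary.translate(
                _split_codes(row.procedure_codes)
            )
            diag_concepts, unknown_d = dictionary.translate(
                _split_codes(row.diagnosis_codes)
            )
            rec = ProcedureRecord(
                patient_id=str(row.patient_id),
                age_days=age,
                procedure_concepts=proc_concepts,
                diagnosis_concepts=diag_concepts,
                modality=Modality(str(row.modality)),
                discharge_age_days=_opt_int(row.discharge_age_days),
                center_id=str(row.center_id),
                residency=Residency(str(row.residency)),
                born_in_window=_parse_bool(row.born_in_window),
            )
        except (ValueError, RecordError) as exc:
            report.n_dropped += 1
            report.row_errors.append((idx, str(exc)))
            logger.warning("dropped row %d of %s: %s", idx, path, exc)
            continue
        report.untranslated.update(unknown_p)
        report.untranslated.update(unknown_d)
        records.append(rec)
    logger.info(
        "%s: %d rows read, %d dropped, %d untranslated codes",
        path,
        report.n_rows,
        report.n_dropped,
        sum(report.untranslated.values()),
    )
    return LoadResult(records=records, report=report)


def write_procedure_table(
    records: Iterable[ProcedureRecord],
    path: Union[str, Path],
    dictionary: ConceptDictionary,
) -> None:
    """Write records in the input dialect (concepts back to canonical codes)."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "age_days": r.age_days,
                "procedure_codes": ";".join(
                    sorted(dictionary.primary_code(c) for c in r.procedure_concepts)
                ),
                "diagnosis_codes": ";".join(
                    sorted(dictionary.primary_code(c) for c in r.diagnosis_concepts)
                ),
                "modality": r.modality.value,
                "discharge_age_days": (
                    "" if r.discharge_age_days is None else r.discharge_age_days
                ),
                "center_id": r.center_id,
                "residency": r.residency.value,
                "born_in_window": str(r.born_in_window).lower(),
            }
        )
    pd.DataFrame(rows, columns=list(PROCEDURE_COLUMNS)).to_csv(path, index=False)


def read_life_status_table(path: Union[str, Path]) -> list[LifeStatus]:
    """Read the life-status CSV; conflicting duplicate rows are an error."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, LIFE_COLUMNS, path)
    seen: dict[str, LifeStatus] = {}
    out: list[LifeStatus] = []
    for row in df.itertuples(index=False):
        ls = LifeStatus(
            patient_id=str(row.patient_id),
            nchda_death_age_days=_opt_int(row.nchda_death_age_days),
            ons_death_age_days=_opt_int(row.ons_death_age_days),
            ons_alive_confirm_age_days=_opt_int(row.ons_alive_confirm_age_days),
        )
        prev = seen.get(ls.patient_id)
        if prev is not None:
            if prev != ls:
                raise LinkageError(
                    f"conflicting life-status rows for patient {ls.patient_id!r}"
                )
            continue
        seen[ls.patient_id] = ls
        out.append(ls)
    return out


def write_life_status_table(
    life: Iterable[LifeStatus], path: Union[str, Path]
) -> None:
    rows = []
    for ls in life:
        rows.append(
            {
                "patient_id": ls.patient_id,
                "nchda_death_age_days": (
                    "" if ls.nchda_death_age_days is None else ls.nchda_death_age_days
                ),
                "ons_death_age_days": (
                    "" if ls.ons_death_age_days is None else ls.ons_death_age_days
                ),
                "ons_alive_confirm_age_days": (
                    ""
                    if ls.ons_alive_confirm_age_days is None
                    else ls.ons_alive_confirm_age_days
                ),
            }
        )
    pd.DataFrame(rows, columns=list(LIFE_COLUMNS)).to_csv(path, index=False)


def link_patients(
    records: Iterable[ProcedureRecord],
    life: Iterable[LifeStatus],
) -> list[PatientHistory]:
    """Group procedure rows into per-patient histories and join life status.

    Records are sorted by age within patient (stable, so same-day procedures
    keep input file order).  Patients absent from the life table get an empty
    life status.  Histories are returned in order of first appearance, so the
    output is a pure function of the input row order.
    """
    by_patient: dict[str, list[ProcedureRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)

    life_by_id: dict[str, LifeStatus] = {}
    for ls in life:
        prev = life_by_id.get(ls.patient_id)
        if prev is not None and prev != ls:
            raise LinkageError(
                f"conflicting life-status rows for patient {ls.patient_id!r}"
            )
        life_by_id[ls.patient_id] = ls

    histories: list[PatientHistory] = []
    for pid, recs in by_patient.items():
        recs_sorted = sorted(recs, key=lambda r: r.age_days)  # stable
        histories.append(
            PatientHistory(
                patient_id=pid,
                records=recs_sorted,
                life_status=life_by_id.get(pid, LifeStatus.empty(pid)),
            )
        )
    return histories
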