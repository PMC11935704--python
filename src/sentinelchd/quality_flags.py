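"""Declarative data-quality rules for implausible procedure sequences.

The production audit flags patients whose coded sequences are clinically
implausible for their diagnosis (suspected missing or miscoded records) so
they can be queried with the treating centre and excluded from
reintervention metrics.  The concrete production rule list is curated by
clinicians; the default ruleset here is a documented, versioned
reconstruction and is fully replaceable through the same YAML format.

Default rules
-------------
q1  stage 2 filled but stage 1 empty or coded after stage 2
q2  stage 3 filled but stage 2 empty or coded after stage 3
q3  exclusively-biventricular diagnosis with stage 2 or stage 3 filled
q4  indeterminate pathway: repair and stage 2/3 both filled
q5  first procedure age above a per-diagnosis plausibility bound
q6  a reintervention duplicates a filled pathway slot on the same day
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

from .pathway_engine import PathwayAssignment
from .records import Diagnosis, PatientHistory, Role


class RulesetError(ValueError):
    """Unknown rule id or malformed ruleset document."""


@dataclass(frozen=True)
class QualityFlag:
    patient_id: str
    rules_fired: tuple[str, ...]

    @property
    def flagged(self) -> bool:
        return bool(self.rules_fired)


@dataclass
class QualityRuleset:
    version: str
    rule_ids: tuple[str, ...]
    #: q3: diagnoses whose pathway is exclusively biventricular
    biventricular_only: frozenset[Diagnosis] = frozenset()
    #: q5: per-diagnosis maximum plausible first-procedure age (days)
    max_first_age_days: dict[Diagnosis, int] = field(default_factory=dict)


KNOWN_RULES = ("q1", "q2", "q3", "q4", "q5", "q6")


def default_ruleset_path() -> Path:
    return Path(resources.files("sentinelchd").joinpath("data/default_ruleset.yaml"))


def load_ruleset(path: Union[str, Path, None] = None) -> QualityRuleset:
    p = Path(path) if path is not None else default_ruleset_path()
    with open(p, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    rule_ids = []
    bivent: frozenset[Diagnosis] = frozenset()
    max_first: dict[Diagnosis, int] = {}
    for entry in doc.get("rules", []):
        rid = str(entry["id"])
        if rid not in KNOWN_RULES:
            raise RulesetError(f"unknown rule id {rid!r}")
        rule_ids.append(rid)
        params = entry.get("params") or {}
        if rid == "q3":
            bivent = frozenset(Diagnosis(d) for d in params.get("biventricular_only", []))
        if rid == "q5":
            max_first = {
                Diagnosis(d): int(v)
                for d, v in params.get("max_first_procedure_age_days", {}).items()
            }
    return QualityRuleset(
        version=str(doc.get("version", "unversioned")),
        rule_ids=tuple(rule_ids),
        biventricular_only=bivent,
        max_first_age_days=max_first,
    )


def flag_patient(
    history: PatientHistory,
    diagnosis: Diagnosis,
    assignment: PathwayAssignment,
    ruleset: QualityRuleset,
) -> QualityFlag:
    """Evaluate the ruleset for one patient; deterministic."""
    fired: list[str] = []
    for rid in ruleset.rule_ids:
        if _rule_fires(rid, history, diagnosis, assignment, ruleset):
            fired.append(rid)
    return QualityFlag(patient_id=history.patient_id, rules_fired=tuple(fired))


def _rule_fires(
    rid: str,
    history: PatientHistory,
    diagnosis: Diagnosis,
    a: PathwayAssignment,
    ruleset: QualityRuleset,
) -> bool:
    if rid == "q1":
        if not a.filled(Role.STAGE2):
            return False
        s1 = a.slot_age(history, Role.STAGE1)
        # missing stage 1, or stage 1 coded after stage 2 (out of order)
        return s1 is None or s1 > a.slot_age(history, Role.STAGE2)
    if rid == "q2":
        if not a.filled(Role.STAGE3):
            return False
        s2 = a.slot_age(history, Role.STAGE2)
        return s2 is None or s2 > a.slot_age(history, Role.STAGE3)
    if rid == "q3":
        return diagnosis in ruleset.biventricular_only and (
            a.filled(Role.STAGE2) or a.filled(Role.STAGE3)
        )
    if rid == "q4":
        return a.filled(Role.REPAIR) and (
            a.filled(Role.STAGE2) or a.filled(Role.STAGE3)
        )
    if rid == "q5":
        bound = ruleset.max_first_age_days.get(diagnosis)
        first = history.first_procedure_age()
        return bound is not None and first is not None and first > bound
    if rid == "q6":
        slot_keys = set()
        for role, idx in a.slots.items():
            if idx is not None and role is not Role.PREPATHWAY:
                rec = history.records[idx]
                slot_keys.add((rec.age_days, rec.procedure_concepts))
        for reint in a.reinterventions:
            rec = history.records[reint.record_index]
            if (rec.age_days, rec.procedure_concepts) in slot_keys:
                return True
        return False
    raise RulesetError(f"unknown rule id {rid!r}")


def flag_prevalence(flags: Iterable[QualityFlag]) -> tuple[int, int, Optional[float]]:
    """(n patients, n flagged, flagged %, 1 decimal); pct absent if empty."""
    flags = list(flags)
    n = len(flags)
    n_flagged = sum(1 for f in flags if f.flagged)
    pct = round(100.0 * n_flagged / n, 1) if n else None
    return n, n_flagged, pct
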