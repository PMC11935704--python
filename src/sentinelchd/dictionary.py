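"""Concept dictionary: raw clinical codes -> named concepts -> pathway roles.

Real registries code diagnoses and procedures with thousands of hierarchical
clinical codes (the IPCCC schema).  This package abstracts that layer to a
configurable dictionary: raw codes translate to named concepts; concepts mark
sentinel diagnoses, split subgroups, and carry a pathway role per diagnosis.
A licensed production code list plugs in through the same YAML format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

from .records import (
    DIAGNOSIS_PRECEDENCE,
    ROLE_PRIORITY,
    SUBGROUPS,
    Diagnosis,
    Role,
)


class DictionaryError(ValueError):
    """The dictionary document is malformed or incomplete."""


#: roles each sentinel diagnosis must have at least one concept for; loading
#: fails otherwise, so an incomplete rule file is caught before any analysis.
REQUIRED_ROLES: dict[Diagnosis, frozenset[Role]] = {
    Diagnosis.HLHS: frozenset({Role.STAGE1, Role.STAGE2, Role.STAGE3}),
    Diagnosis.FUH: frozenset({Role.STAGE1, Role.STAGE2, Role.STAGE3}),
    Diagnosis.TGA: frozenset({Role.STAGE1, Role.STAGE2, Role.STAGE3, Role.REPAIR}),
    Diagnosis.PA: frozenset({Role.STAGE1, Role.STAGE2, Role.STAGE3, Role.REPAIR}),
    Diagnosis.AVSD: frozenset({Role.STAGE1, Role.STAGE2, Role.STAGE3, Role.REPAIR}),
    Diagnosis.TOF: frozenset({Role.STAGE1, Role.REPAIR}),
    Diagnosis.AS: frozenset({Role.REPAIR}),
    Diagnosis.COARCT: frozenset({Role.REPAIR}),
    Diagnosis.VSD: frozenset({Role.REPAIR}),
}


@dataclass(frozen=True)
class SubgroupRule:
    """Assign ``subgroup`` when every concept in ``when_all`` is present."""

    when_all: frozenset[str]
    subgroup: str


@dataclass
class ConceptDictionary:
    version: str
    code_to_concept: dict[str, str]
    diagnosis_markers: dict[str, Diagnosis]  # concept -> sentinel diagnosis
    subgroup_rules: dict[Diagnosis, tuple[tuple[SubgroupRule, ...], str]]
    roles: dict[Diagnosis, dict[str, Role]]  # diagnosis -> concept -> role
    prematurity_concepts: frozenset[str]
    comorbidity_concepts: frozenset[str]
    diagnostic_concepts: frozenset[str]
    _concept_to_code: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._concept_to_code:
            # first code listed for a concept is its canonical code on write
            for code, concept in self.code_to_concept.items():
                self._concept_to_code.setdefault(concept, code)

    # -- translation ---------------------------------------------------

    def translate(self, codes: Iterable[str]) -> tuple[frozenset[str], list[str]]:
        """Translate raw codes; returns (concepts, untranslatable codes)."""
        concepts: set[str] = set()
        unknown: list[str] = []
        for code in codes:
            concept = self.code_to_concept.get(code)
            if concept is None:
                unknown.append(code)
            else:
                concepts.add(concept)
        return frozenset(concepts), unknown

    def primary_code(self, concept: str) -> str:
        try:
            return self._concept_to_code[concept]
        except KeyError:
            raise DictionaryError(f"concept {concept!r} has no raw code") from None

    def known_concepts(self) -> frozenset[str]:
        return frozenset(self.code_to_concept.values())

    # -- roles ---------------------------------------------------------

    def role_of(self, diagnosis: Diagnosis, concepts: frozenset[str]) -> Role:
        """Pathway role of a record's procedure concepts for ``diagnosis``.

        Concepts without a role for this diagnosis map to ``OTHER``; if
        several role-bearing concepts co-occur the latest-stage role wins.
        """
        table = self.roles.get(diagnosis, {})
        found = {table[c] for c in concepts if c in table}
        if not found:
            return Role.OTHER
        for role in ROLE_PRIORITY:
            if role in found:
                return role
        return Role.OTHER

    def is_diagnostic_only(self, concepts: frozenset[str]) -> bool:
        """True when a record is purely diagnostic (never a reintervention)."""
        return bool(concepts) and concepts <= self.diagnostic_concepts


def _parse_roles(raw: dict) -> dict[Diagnosis, dict[str, Role]]:
    roles: dict[Diagnosis, dict[str, Role]] = {}
    for dx_name, table in raw.items():
        dx = Diagnosis(dx_name)
        roles[dx] = {}
        for concept, role_name in table.items():
            role = Role(role_name)
            if concept in roles[dx]:
                raise DictionaryError(
                    f"concept {concept!r} has two roles for {dx.value}"
                )
            roles[dx][concept] = role
    return roles


def _validate(d: ConceptDictionary) -> None:
    marked = set(d.diagnosis_markers.values())
    missing_marks = [dx.value for dx in DIAGNOSIS_PRECEDENCE if dx not in marked]
    if missing_marks:
        raise DictionaryError(f"no marker concept for diagnoses: {missing_marks}")
    for dx, required in REQUIRED_ROLES.items():
        present = set(d.roles.get(dx, {}).values())
        missing = sorted(r.value for r in required - present)
        if missing:
            raise DictionaryError(f"{dx.value}: missing roles {missing}")
    for dx in DIAGNOSIS_PRECEDENCE:
        if dx not in d.subgroup_rules:
            raise DictionaryError(f"{dx.value}: no subgroup rules")
        rules, default = d.subgroup_rules[dx]
        valid = SUBGROUPS[dx]
        for rule in rules:
            if rule.subgroup not in valid:
                raise DictionaryError(
                    f"{dx.value}: unknown subgroup {rule.subgroup!r}"
                )
        if default not in valid:
            raise DictionaryError(f"{dx.value}: unknown default subgroup {default!r}")


def parse_concept_dictionary(doc: dict) -> ConceptDictionary:
    """Build and validate a :class:`ConceptDictionary` from a parsed document."""
    codes_raw = doc.get("codes", {})
    code_to_concept: dict[str, str] = {}
    conflicts: list[str] = []
    for code, concept in codes_raw.items():
        code = str(code)
        if code in code_to_concept and code_to_concept[code] != concept:
            conflicts.append(code)
        code_to_concept[code] = str(concept)
    if conflicts:
        raise DictionaryError(f"duplicate codes with conflicting concepts: {conflicts}")

    markers = {
        str(c): Diagnosis(dx) for c, dx in doc.get("diagnosis_markers", {}).items()
    }

    subgroup_rules: dict[Diagnosis, tuple[tuple[SubgroupRule, ...], str]] = {}
    for dx_name, block in doc.get("subgroup_rules", {}).items():
        dx = Diagnosis(dx_name)
        rules = tuple(
            SubgroupRule(frozenset(r["when_all"]), str(r["subgroup"]))
            for r in block.get("rules", [])
        )
        subgroup_rules[dx] = (rules, str(block["default"]))

    d = ConceptDictionary(
        version=str(doc.get("version", "unversioned")),
        code_to_concept=code_to_concept,
        diagnosis_markers=markers,
        subgroup_rules=subgroup_rules,
        roles=_parse_roles(doc.get("roles", {})),
        prematurity_concepts=frozenset(doc.get("prematurity_concepts", [])),
        comorbidity_concepts=frozenset(doc.get("comorbidity_concepts", [])),
        diagnostic_concepts=frozenset(doc.get("diagnostic_concepts", [])),
    )
    _validate(d)
    return d


def default_dictionary_path() -> Path:
    return Path(resources.files("sentinelchd").joinpath("data/default_dictionary.yaml"))


def load_concept_dictionary(
    path: Union[str, Path, None] = None,
) -> ConceptDictionary:
    """Load a concept dictionary; the bundled default when ``path`` is None."""
    p = Path(path) if path is not None else default_dictionary_path()
    with open(p, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise DictionaryError(f"{p}: not a mapping document")
    return parse_concept_dictionary(doc)
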