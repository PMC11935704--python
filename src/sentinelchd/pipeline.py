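"""End-to-end orchestration: ingest or simulate, phenotype, classify
pathways, flag quality, estimate outcomes, and emit an auditable bundle.

Stage order is fixed: ingest -> exclusions -> phenotype -> pathway ->
quality flags -> outcomes -> tables.  Every stage logs in/out counts so the
bundle contains a reproducible inclusion flow chart; all randomness flows
from the single run seed and no wall-clock value enters any output, so
regenerating a bundle from its persisted config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .dictionary import ConceptDictionary, load_concept_dictionary
from .outcomes import (
    Ascertainment,
    EventHistory,
    ascertain_life_status,
    build_event_history,
    metrics_table,
    scoping_metrics,
)
from .pathway_engine import PathwayAssignment, assign_pathway, pathway_completion_summary
from .phenotyping import (
    ExclusionOutcome,
    ExclusionReason,
    SentinelDiagnosis,
    apply_exclusions,
    assign_sentinel_diagnosis,
    derive_complexity_flags,
)
from .quality_flags import QualityFlag, QualityRuleset, flag_patient, load_ruleset
from .records import REPORT_AGES_YEARS, Diagnosis, PatientHistory
from .registry_io import link_patients, read_life_status_table, read_procedure_table
from .synthetic_registry import CohortSpec, generate_cohort, load_cohort_spec

logger = logging.getLogger(__name__)

#: flow-chart exclusion order (matches apply_exclusions precedence)
EXCLUSION_ORDER = [
    ExclusionReason.BORN_OUTSIDE_WINDOW.value,
    ExclusionReason.OUTSIDE_ENGLAND_WALES.value,
    ExclusionReason.NON_NHS.value,
    ExclusionReason.NO_CARDIAC_CODES.value,
    ExclusionReason.MAJOR_DATA_ERROR.value,
    ExclusionReason.NOT_SENTINEL.value,
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``procedures_path`` (with ``life_path``) or ``simulate``
    must be active.
    """

    procedures_path: Optional[Path] = None
    life_path: Optional[Path] = None
    simulate: bool = False
    cohort_spec_path: Optional[Path] = None
    cohort_spec: Optional[CohortSpec] = None  # in-memory alternative to the path
    dictionary_path: Optional[Path] = None
    ruleset_path: Optional[Path] = None
    seed: int = 0
    report_ages_years: tuple[float, ...] = REPORT_AGES_YEARS
    exclude_flagged_from_survival: bool = False
    exclude_flagged_from_completion: bool = True

    def validate(self) -> None:
        has_paths = self.procedures_path is not None
        if has_paths == self.simulate:
            raise PipelineError(
                "config: exactly one of input paths or simulation must be set"
            )
        if has_paths and self.life_path is None:
            raise PipelineError("config: life_path required with procedures_path")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        kw = {}
        for key in (
            "procedures_path",
            "life_path",
            "cohort_spec_path",
            "dictionary_path",
            "ruleset_path",
        ):
            if doc.get(key):
                kw[key] = Path(doc[key])
        for key in (
            "simulate",
            "seed",
            "exclude_flagged_from_survival",
            "exclude_flagged_from_completion",
        ):
            if key in doc:
                kw[key] = doc[key]
        if "report_ages_years" in doc:
            kw["report_ages_years"] = tuple(float(x) for x in doc["report_ages_years"])
        return cls(**kw)


@dataclass
class PatientResult:
    history: PatientHistory
    exclusion: ExclusionOutcome
    phenotype: Optional[SentinelDiagnosis] = None
    assignment: Optional[PathwayAssignment] = None
    flag: Optional[QualityFlag] = None
    ascertainment: Optional[Ascertainment] = None
    event_history: Optional[EventHistory] = None


@dataclass
class ReportBundle:
    """All pipeline outputs plus provenance for one run."""

    flowchart: pd.DataFrame
    cohort: pd.DataFrame  # one row per included patient
    metrics: pd.DataFrame
    completion: pd.DataFrame
    scoping: pd.DataFrame
    manifest: dict
    patients: dict[str, PatientResult] = field(default_factory=dict, repr=False)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("ingest")
def _ingest(config: RunConfig, dictionary: ConceptDictionary):
    if config.simulate:
        spec = config.cohort_spec or load_cohort_spec(config.cohort_spec_path)
        records, life, truth = generate_cohort(spec, seed=config.seed, dictionary=dictionary)
        return records, life, truth
    result = read_procedure_table(config.procedures_path, dictionary)
    life = read_life_status_table(config.life_path)
    return result.records, life, None


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis and return the report bundle."""
    config.validate()
    dictionary = load_concept_dictionary(config.dictionary_path)
    ruleset = load_ruleset(config.ruleset_path)

    records, life, truth = _ingest(config, dictionary)
    histories = link_patients(records, life)
    n_initial = len(histories)

    # exclusions + phenotyping -------------------------------------------
    results: dict[str, PatientResult] = {}
    excl_counts: dict[str, int] = {r: 0 for r in EXCLUSION_ORDER}
    included: list[str] = []
    for h in histories:
        outcome = apply_exclusions(h)
        if outcome.excluded:
            results[h.patient_id] = PatientResult(h, outcome)
            excl_counts[outcome.reason.value] += 1
            continue
        phenotype = assign_sentinel_diagnosis(h, dictionary)
        outcome = apply_exclusions(h, phenotype.diagnosis)
        pr = PatientResult(h, outcome, phenotype=phenotype)
        results[h.patient_id] = pr
        if outcome.excluded:
            excl_counts[outcome.reason.value] += 1
            continue
        h.prematurity, h.comorbidity = derive_complexity_flags(h, dictionary)
        included.append(h.patient_id)

    # pathway + quality flags --------------------------------------------
    dropped_no_lifestatus = 0
    cohort_rows = []
    for pid in included:
        pr = results[pid]
        dx = pr.phenotype.diagnosis
        pr.assignment = assign_pathway(pr.history, dx, dictionary)
        pr.flag = flag_patient(pr.history, dx, pr.assignment, ruleset)
        pr.ascertainment = ascertain_life_status(pr.history)
        if pr.ascertainment is None:
            dropped_no_lifestatus += 1
            continue
        pr.event_history = build_event_history(pr.history, pr.assignment, pr.ascertainment)
        cohort_rows.append(
            {
                "patient_id": pid,
                "diagnosis": dx.value,
                "subgroup": pr.phenotype.subgroup,
                "pathway_type": pr.assignment.pathway_type,
                "prematurity": pr.history.prematurity,
                "comorbidity": pr.history.comorbidity,
                "flagged": pr.flag.flagged,
                "rules_fired": ";".join(pr.flag.rules_fired),
                "lost_to_followup": pr.ascertainment.lost_to_followup,
                "terminal_kind": pr.ascertainment.kind,
                "terminal_age_days": pr.ascertainment.age_days,
            }
        )
    cohort = pd.DataFrame(cohort_rows)

    # outcome tables ------------------------------------------------------
    event_histories = {
        pid: results[pid].event_history
        for pid in cohort["patient_id"]
    } if len(cohort) else {}
    if len(cohort):
        metrics = metrics_table(
            cohort,
            event_histories,
            report_ages_years=config.report_ages_years,
            exclude_flagged_from_survival=config.exclude_flagged_from_survival,
        )
        by_dx: dict[str, list[PathwayAssignment]] = {}
        for pid in cohort["patient_id"]:
            pr = results[pid]
            if config.exclude_flagged_from_completion and pr.flag.flagged:
                continue
            by_dx.setdefault(pr.phenotype.diagnosis.value, []).append(pr.assignment)
        completion = pathway_completion_summary(by_dx)
        scoping = scoping_metrics(
            cohort,
            {pid: results[pid].history for pid in cohort["patient_id"]},
            {pid: results[pid].ascertainment for pid in cohort["patient_id"]},
        )
    else:
        metrics = pd.DataFrame()
        completion = pd.DataFrame()
        scoping = pd.DataFrame()

    # flow chart ----------------------------------------------------------
    stage_logs = [("initial", n_initial)]
    running = n_initial
    for reason in EXCLUSION_ORDER:
        running -= excl_counts[reason]
        stage_logs.append((f"excluded:{reason}", excl_counts[reason]))
    stage_logs.append(("excluded:no_resolvable_life_status", dropped_no_lifestatus))
    running -= dropped_no_lifestatus
    stage_logs.append(("final", running))
    flowchart = emit_flowchart_counts(stage_logs, n_initial)
    if len(cohort):
        sentinel_row = pd.DataFrame(
            [{"stage": "sentinel_cohort", "n": len(cohort), "remaining": running}]
        )
        flowchart = pd.concat([flowchart, sentinel_row], ignore_index=True)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "dictionary_version": dictionary.version,
        "ruleset_version": ruleset.version,
        "simulated": config.simulate,
        "report_ages_years": list(config.report_ages_years),
        "n_initial": n_initial,
        "n_final": int(running),
        "exclusions": excl_counts,
    }
    return ReportBundle(
        flowchart=flowchart,
        cohort=cohort,
        metrics=metrics,
        completion=completion,
        scoping=scoping,
        manifest=manifest,
        patients=results,
    )


def emit_flowchart_counts(
    stage_logs: Sequence[tuple[str, int]], n_initial: int
) -> pd.DataFrame:
    """Ordered inclusion flow chart; conserves counts at every stage."""
    rows = []
    remaining = n_initial
    for stage, n in stage_logs:
        if stage.startswith("excluded:"):
            remaining -= n
        rows.append({"stage": stage, "n": n, "remaining": remaining})
    return pd.DataFrame(rows, columns=["stage", "n", "remaining"])


def format_outcome_table(metrics: pd.DataFrame, ages=(1, 5, 10)) -> pd.DataFrame:
    """Human-readable percentage table: '57.6% (54.9%-60.4%)' cells."""

    def cell(row, prefix, age):
        v = row.get(f"{prefix}_{age:g}y")
        lo = row.get(f"{prefix}_{age:g}y_lo")
        hi = row.get(f"{prefix}_{age:g}y_hi")
        if v is None or pd.isna(v):
            return ""
        return f"{100 * v:.1f}% ({100 * lo:.1f}%-{100 * hi:.1f}%)"

    rows = []
    for _, row in metrics.iterrows():
        out = {
            "diagnosis": row["diagnosis"],
            "subgroup": row["subgroup"],
            "n": row["n"],
            "follow_up_median_y": row["fu_median_y"],
        }
        for age in ages:
            out[f"survival_{age}y"] = cell(row, "surv", age)
        for age in ages:
            out[f"reintervention_any_{age}y"] = cell(row, "reint_any", age)
        rows.append(out)
    return pd.DataFrame(rows)


def write_bundle(bundle: ReportBundle, out_dir: Union[str, Path]) -> dict:
    """Persist the bundle as CSVs plus a JSON manifest with checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "flowchart.csv": bundle.flowchart,
        "cohort.csv": bundle.cohort,
        "metrics.csv": bundle.metrics,
        "metrics_formatted.csv": format_outcome_table(bundle.metrics)
        if len(bundle.metrics)
        else pd.DataFrame(),
        "completion.csv": bundle.completion,
        "scoping.csv": bundle.scoping,
    }
    checksums = {}
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, index=False)
        checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = dict(bundle.manifest)
    manifest["checksums"] = checksums
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
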