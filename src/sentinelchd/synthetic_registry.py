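"""Seeded synthetic procedure-registry cohorts with known ground truth.

The generator emulates the statistical structure a national congenital
cardiac audit exhibits, so that every downstream stage — phenotyping,
pathway classification, quality flagging and survival/reintervention
estimation — is testable without access-controlled data:

* per-diagnosis cohort sizes, subgroup mixes, and log-normal age/weight at
  first procedure matched to published registry summaries;
* staged single-ventricle and biventricular treatment trajectories;
* death modelled as a piecewise-constant hazard on the age segments
  [0,1), [1,5), [5,10), [10,inf) years, calibrated so the closed-form
  survival at ages 1/5/10 equals the block's target survival;
* reinterventions as a Poisson process whose piecewise-constant intensity
  is calibrated (competing with the death hazard) so the implied cumulative
  incidence at 1/5/10 years equals the block's target;
* uniform cohort entry over the study window (administrative censoring),
  loss to follow-up censored at last hospital discharge, and a small
  corruption rate producing implausible sequences.

Randomness: one global seed expands to one Philox stream per diagnosis
block (keyed by the block name), so editing one block's parameters never
reshuffles another block's cohort.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .dictionary import ConceptDictionary, load_concept_dictionary
from .records import (
    DAYS_PER_YEAR,
    SURGICAL_MODALITIES,
    Diagnosis,
    LifeStatus,
    Modality,
    ProcedureRecord,
    Residency,
    Role,
    SUBGROUPS,
)

_Z75 = 0.6744897501960817  # 75th normal quantile; IQR -> log-normal sigma

#: age segments (years) carrying piecewise-constant hazards
SEGMENT_BOUNDS_Y = np.array([0.0, 1.0, 5.0, 10.0])
SEGMENT_LENGTHS_Y = np.array([1.0, 4.0, 5.0, np.inf])

#: canonical modality of each procedure concept the generator can emit
CONCEPT_MODALITY: dict[str, Modality] = {
    "balloon_atrial_septostomy": Modality.CATHETER,
    "norwood": Modality.BYPASS_SURGERY,
    "hybrid_stage1": Modality.HYBRID,
    "systemic_pulmonary_shunt": Modality.NONBYPASS_SURGERY,
    "pa_band": Modality.NONBYPASS_SURGERY,
    "glenn": Modality.BYPASS_SURGERY,
    "fontan": Modality.BYPASS_SURGERY,
    "arterial_switch": Modality.BYPASS_SURGERY,
    "rastelli": Modality.BYPASS_SURGERY,
    "tof_repair": Modality.BYPASS_SURGERY,
    "pa_repair": Modality.BYPASS_SURGERY,
    "pulmonary_valvotomy": Modality.CATHETER,
    "avsd_repair": Modality.BYPASS_SURGERY,
    "aortic_valvotomy": Modality.BYPASS_SURGERY,
    "balloon_aortic_valvuloplasty": Modality.CATHETER,
    "coarct_repair": Modality.NONBYPASS_SURGERY,
    "vsd_closure": Modality.BYPASS_SURGERY,
    "heart_transplant": Modality.BYPASS_SURGERY,
    "pacemaker_insertion": Modality.NONBYPASS_SURGERY,
    "balloon_dilation": Modality.CATHETER,
    "stent_implantation": Modality.CATHETER,
    "device_closure": Modality.CATHETER,
    "ep_ablation": Modality.ELECTROPHYSIOLOGY,
    "diagnostic_catheter": Modality.CATHETER,
}

#: diagnosis concepts each subgroup's records carry
SUBGROUP_DIAGNOSIS_CONCEPTS: dict[tuple[str, str], tuple[str, ...]] = {
    ("HLHS", "hlhs"): ("hlhs",),
    ("FUH", "double_inlet_ventricle"): ("double_inlet_ventricle",),
    ("FUH", "tricuspid_atresia"): ("tricuspid_atresia",),
    ("TGA", "complex_with_PS"): ("tga", "tga_complex", "pulmonary_stenosis"),
    ("TGA", "complex_without_PS"): ("tga", "tga_complex"),
    ("TGA", "intact_septum"): ("tga",),
    ("PA", "with_VSD"): ("pulmonary_atresia", "vsd"),
    ("PA", "intact_septum"): ("pulmonary_atresia",),
    ("AVSD", "tetralogy_AVSD"): ("avsd", "tof"),
    ("AVSD", "unbalanced"): ("avsd", "unbalanced_avsd"),
    ("AVSD", "partial"): ("avsd", "partial_avsd"),
    ("AVSD", "complete"): ("avsd",),
    ("TOF", "absent_pulm_valve"): ("tof", "absent_pulmonary_valve"),
    ("TOF", "DORV"): ("tof", "dorv"),
    ("TOF", "standard"): ("tof",),
    ("AS", "multilevel_LHO"): ("aortic_stenosis", "multilevel_lho"),
    ("AS", "isolated"): ("aortic_stenosis",),
    ("COARCT", "with_VSD"): ("coarctation", "vsd"),
    ("COARCT", "isolated"): ("coarctation",),
    ("VSD", "multiple"): ("vsd", "multiple_vsd"),
    ("VSD", "isolated"): ("vsd",),
}

_CATHETER_REINT_CONCEPTS = ("balloon_dilation", "stent_implantation", "device_closure")


class SpecError(ValueError):
    """The cohort specification is invalid."""


# ---------------------------------------------------------------------------
# specification dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogNormalSpec:
    """Median/IQR-parameterized log-normal."""

    median: float
    q1: float
    q3: float

    @property
    def mu(self) -> float:
        return float(np.log(self.median))

    @property
    def sigma(self) -> float:
        if self.q1 <= 0 or self.q3 <= self.q1:
            return 0.05
        return max(float(np.log(self.q3 / self.q1)) / (2 * _Z75), 0.05)


@dataclass(frozen=True)
class SubgroupSpec:
    name: str
    count: float  # relative weight (published subgroup size)
    age_first_proc_days: LogNormalSpec
    weight_first_proc_kg: LogNormalSpec


@dataclass(frozen=True)
class StageSpec:
    role: Role
    concepts: tuple[tuple[str, float], ...]  # (concept, weight)
    prob: float
    gap_days: Optional[LogNormalSpec] = None  # gap from previous pathway event
    concepts_by_subgroup: tuple[tuple[str, str], ...] = ()  # subgroup -> concept

    def concept_for(self, subgroup: str, rng: np.random.Generator) -> str:
        for sub, concept in self.concepts_by_subgroup:
            if sub == subgroup:
                return concept
        names = [c for c, _ in self.concepts]
        weights = np.array([w for _, w in self.concepts], dtype=float)
        weights = weights / weights.sum()
        return names[int(rng.choice(len(names), p=weights))]


@dataclass(frozen=True)
class DiagnosisBlock:
    diagnosis: Diagnosis
    n_patients: int
    subgroups: tuple[SubgroupSpec, ...]
    survival_targets: tuple[float, float, float]  # S at 1/5/10 years
    reint_targets: tuple[float, float, float]  # CIF at 1/5/10 years
    prematurity_rate: float
    comorbidity_rate: float
    sv_fraction: float
    pathway_sv: tuple[StageSpec, ...] = ()
    pathway_bv: tuple[StageSpec, ...] = ()
    reint_surgical_fraction: float = 0.5
    ltfu_rate: float = 0.02
    corruption_rate: float = 0.01

    def subgroup_fractions(self) -> np.ndarray:
        w = np.array([s.count for s in self.subgroups], dtype=float)
        return w / w.sum()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise SpecError(f"{self.diagnosis.value}: negative n_patients")
        if not self.subgroups:
            raise SpecError(f"{self.diagnosis.value}: no subgroups")
        fr = self.subgroup_fractions()
        if abs(fr.sum() - 1.0) > 1e-9 or (fr < 0).any():
            raise SpecError(f"{self.diagnosis.value}: bad subgroup mix")
        for s in self.subgroups:
            if s.name not in SUBGROUPS[self.diagnosis]:
                raise SpecError(
                    f"{self.diagnosis.value}: unknown subgroup {s.name!r}"
                )
        s1, s5, s10 = self.survival_targets
        if not (0 < s10 <= s5 <= s1 <= 1):
            raise SpecError(f"{self.diagnosis.value}: survival targets not monotone")
        f1, f5, f10 = self.reint_targets
        if not (0 <= f1 <= f5 <= f10 < 1):
            raise SpecError(f"{self.diagnosis.value}: reintervention targets not monotone")
        for rate in (
            self.prematurity_rate,
            self.comorbidity_rate,
            self.sv_fraction,
            self.ltfu_rate,
            self.corruption_rate,
            self.reint_surgical_fraction,
        ):
            if not 0.0 <= rate <= 1.0:
                raise SpecError(f"{self.diagnosis.value}: rate outside [0,1]")
        if self.sv_fraction > 0 and not self.pathway_sv:
            raise SpecError(f"{self.diagnosis.value}: sv_fraction > 0 without pathway_sv")
        if self.sv_fraction < 1 and not self.pathway_bv:
            raise SpecError(f"{self.diagnosis.value}: sv_fraction < 1 without pathway_bv")


@dataclass(frozen=True)
class CohortSpec:
    blocks: tuple[DiagnosisBlock, ...]
    study_years: float = 22.0
    born_outside_window_rate: float = 0.0
    nonresident_rate: float = 0.0
    non_nhs_rate: float = 0.0
    seed: int = 0

    @property
    def study_days(self) -> float:
        return self.study_years * DAYS_PER_YEAR

    def validate(self) -> None:
        if not self.blocks:
            raise SpecError("no diagnosis blocks")
        seen = set()
        for b in self.blocks:
            if b.diagnosis in seen:
                raise SpecError(f"duplicate block for {b.diagnosis.value}")
            seen.add(b.diagnosis)
            b.validate()
        excl = (
            self.born_outside_window_rate + self.nonresident_rate + self.non_nhs_rate
        )
        if excl > 1.0:
            raise SpecError("exclusion-injection rates sum above 1")

    def block(self, diagnosis: Union[str, Diagnosis]) -> DiagnosisBlock:
        dx = Diagnosis(diagnosis)
        for b in self.blocks:
            if b.diagnosis is dx:
                return b
        raise KeyError(dx)

    def modified(
        self,
        n_patients: Optional[int] = None,
        ltfu_rate: Optional[float] = None,
        corruption_rate: Optional[float] = None,
    ) -> "CohortSpec":
        """Copy with uniform overrides across blocks (test/benchmark helper)."""
        blocks = []
        for b in self.blocks:
            kw = {}
            if n_patients is not None:
                kw["n_patients"] = n_patients
            if ltfu_rate is not None:
                kw["ltfu_rate"] = ltfu_rate
            if corruption_rate is not None:
                kw["corruption_rate"] = corruption_rate
            blocks.append(replace(b, **kw))
        return replace(self, blocks=tuple(blocks))


# ---------------------------------------------------------------------------
# hazard calibration (closed form on the piecewise segments)
# ---------------------------------------------------------------------------


def death_hazards_from_survival(
    targets: Sequence[float],
) -> np.ndarray:
    """Per-year hazards on the four age segments implying the target survival.

    The tail segment (10+ years) reuses the 5-10 year hazard.
    """
    s1, s5, s10 = targets
    h1 = -np.log(s1)
    h2 = np.log(s1 / s5) / 4.0
    h3 = np.log(s5 / s10) / 5.0
    return np.array([h1, h2, h3, h3])


def reint_hazards_from_cif(
    targets: Sequence[float], death_hazards: np.ndarray
) -> np.ndarray:
    """Reintervention intensities implying the target cumulative incidence.

    Solved segment by segment: with constant reintervention intensity ``r``
    and death hazard ``d`` on a segment of length ``L`` starting with
    event-free probability ``S0`` and incidence ``F0``,
    ``F(end) = F0 + S0 * r/(r+d) * (1 - exp(-(r+d) L))``, which is monotone
    in ``r``.
    """
    f_targets = list(targets)
    hd = np.asarray(death_hazards, dtype=float)
    hr = np.zeros(4)
    F0, S0 = 0.0, 1.0
    for k in range(3):
        L = SEGMENT_LENGTHS_Y[k]
        d = hd[k]
        target = f_targets[k]
        dF = target - F0
        if dF <= 1e-12:
            hr[k] = 0.0
        else:
            def gap(r: float) -> float:
                tot = r + d
                if tot <= 0:
                    return -dF
                return S0 * (r / tot) * (1.0 - np.exp(-tot * L)) - dF

            hi = 1.0
            while gap(hi) < 0 and hi < 1e4:
                hi *= 2.0
            if gap(hi) < 0:
                raise SpecError("reintervention target not attainable")
            hr[k] = brentq(gap, 0.0, hi, xtol=1e-12, rtol=1e-12)
        S0 *= np.exp(-(hr[k] + d) * L)
        F0 = target
    hr[3] = hr[2]
    return hr


def piecewise_survival(hazards: np.ndarray, t_years: np.ndarray) -> np.ndarray:
    """S(t) = exp(-integral of the piecewise-constant hazard)."""
    t = np.atleast_1d(np.asarray(t_years, dtype=float))
    cum = np.zeros_like(t)
    for k in range(4):
        lo = SEGMENT_BOUNDS_Y[k]
        hi = SEGMENT_BOUNDS_Y[k + 1] if k < 3 else np.inf
        cum += hazards[k] * np.clip(t - lo, 0.0, hi - lo)
    return np.exp(-cum)


def piecewise_cif(
    reint_hazards: np.ndarray,
    death_hazards: np.ndarray,
    t_years: Sequence[float],
) -> np.ndarray:
    """Closed-form competing-risks incidence of reintervention at given ages."""
    out = []
    for t in t_years:
        F, S, pos = 0.0, 1.0, 0.0
        for k in range(4):
            hi_bound = SEGMENT_BOUNDS_Y[k + 1] if k < 3 else np.inf
            L = min(t, hi_bound) - pos
            if L <= 0:
                break
            r, d = reint_hazards[k], death_hazards[k]
            tot = r + d
            if tot > 0:
                F += S * (r / tot) * (1.0 - np.exp(-tot * L))
                S *= np.exp(-tot * L)
            pos += L
        out.append(F)
    return np.array(out)


def implied_survival(block: DiagnosisBlock, ages_years: Sequence[float]) -> np.ndarray:
    return piecewise_survival(
        death_hazards_from_survival(block.survival_targets), np.asarray(ages_years)
    )


def implied_reint_cif(block: DiagnosisBlock, ages_years: Sequence[float]) -> np.ndarray:
    hd = death_hazards_from_survival(block.survival_targets)
    hr = reint_hazards_from_cif(block.reint_targets, hd)
    return piecewise_cif(hr, hd, ages_years)


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------


def _cum_hazard_bounds(h_year: np.ndarray) -> np.ndarray:
    """Cumulative hazard at segment boundaries 0,1,5,10 years."""
    return np.concatenate(
        ([0.0], np.cumsum(h_year[:3] * SEGMENT_LENGTHS_Y[:3]))
    )


def sample_piecewise_exponential(
    rng: np.random.Generator, h_year: np.ndarray, size: int
) -> np.ndarray:
    """Event times (years) for a piecewise-constant hazard; inf if never."""
    E = rng.exponential(size=size)
    cumb = _cum_hazard_bounds(h_year)
    seg = np.searchsorted(cumb, E, side="right") - 1
    seg = np.clip(seg, 0, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = SEGMENT_BOUNDS_Y[seg] + (E - cumb[seg]) / h_year[seg]
    t = np.where(h_year[seg] > 0, t, np.inf)
    return t


def _cum_hazard_at(h_year: np.ndarray, cumb: np.ndarray, t_years: float) -> float:
    k = int(np.searchsorted(SEGMENT_BOUNDS_Y, t_years, side="right")) - 1
    k = min(max(k, 0), 3)
    return float(cumb[k] + h_year[k] * (t_years - SEGMENT_BOUNDS_Y[k]))


def _invert_cum_hazard(h_year: np.ndarray, cumb: np.ndarray, target: float) -> float:
    k = int(np.searchsorted(cumb, target, side="right")) - 1
    k = min(max(k, 0), 3)
    if h_year[k] <= 0:
        return np.inf
    return float(SEGMENT_BOUNDS_Y[k] + (target - cumb[k]) / h_year[k])


def sample_poisson_process(
    rng: np.random.Generator,
    h_year: np.ndarray,
    stop_years: float,
    max_events: int = 50,
) -> list[float]:
    """Event times (years) of a Poisson process with piecewise intensity."""
    if not np.any(h_year > 0) or stop_years <= 0:
        return []
    cumb = _cum_hazard_bounds(h_year)
    times: list[float] = []
    H = 0.0
    t = 0.0
    for _ in range(max_events):
        H = _cum_hazard_at(h_year, cumb, t) + rng.exponential()
        t = _invert_cum_hazard(h_year, cumb, H)
        if not np.isfinite(t) or t > stop_years:
            break
        times.append(t)
    return times


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

TRUTH_SLOT_COLUMNS = {
    Role.PREPATHWAY: "prepathway_age",
    Role.STAGE1: "stage1_age",
    Role.STAGE2: "stage2_age",
    Role.STAGE3: "stage3_age",
    Role.REPAIR: "repair_age",
}


@dataclass
class GroundTruth:
    """True per-patient labels and event times, pre-corruption."""

    patients: pd.DataFrame
    reinterventions: pd.DataFrame

    def slots_for(self, patient_id: str) -> dict[Role, Optional[int]]:
        row = self.patients.loc[self.patients["patient_id"] == patient_id].iloc[0]
        out: dict[Role, Optional[int]] = {}
        for role, col in TRUTH_SLOT_COLUMNS.items():
            v = row[col]
            out[role] = None if pd.isna(v) else int(v)
        return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _block_rng(seed: int, tag: str) -> np.random.Generator:
    key = np.array(
        [np.uint64(seed & 0x7FFFFFFF), np.uint64(zlib.crc32(tag.encode()))],
        dtype=np.uint64,
    )
    return np.random.Generator(np.random.Philox(key=key))


def _pick_reint_concept(
    rng: np.random.Generator,
    surgical: bool,
    diagnosis: Diagnosis,
    dictionary: ConceptDictionary,
    slot_events: list[tuple[Role, str, int]],
    t_days: int,
) -> tuple[str, Modality]:
    roles = dictionary.roles.get(diagnosis, {})
    if surgical:
        # reoperation: repeat an earlier pathway procedure, else pacemaker
        earlier = [
            (role, concept, age)
            for role, concept, age in slot_events
            if age < t_days
            and role in (Role.STAGE1, Role.STAGE2, Role.STAGE3, Role.REPAIR)
            and CONCEPT_MODALITY[concept] in SURGICAL_MODALITIES
        ]
        if earlier and rng.random() < 0.4:
            _, concept, _ = earlier[-1]
            return concept, CONCEPT_MODALITY[concept]
        return "pacemaker_insertion", Modality.NONBYPASS_SURGERY
    candidates = [
        c for c in _CATHETER_REINT_CONCEPTS if roles.get(c, Role.OTHER) is Role.OTHER
    ]
    concept = candidates[int(rng.integers(len(candidates)))]
    return concept, CONCEPT_MODALITY[concept]


def _sample_stage_events(
    rng: np.random.Generator,
    template: Sequence[StageSpec],
    subgroup: str,
    first_proc_age: int,
) -> list[tuple[Role, str, int]]:
    """(role, concept, age_days) for attained pathway procedures, in order."""
    events: list[tuple[Role, str, int]] = []
    attained: set[Role] = set()
    cur_age: Optional[int] = None
    for stage in template:
        if stage.role is Role.STAGE2 and Role.STAGE1 not in attained:
            continue
        if stage.role is Role.STAGE3 and Role.STAGE2 not in attained:
            continue
        if rng.random() >= stage.prob:
            continue
        concept = stage.concept_for(subgroup, rng)
        if cur_age is None:
            age = first_proc_age
        else:
            gap_spec = stage.gap_days
            if gap_spec is None:
                gap = max(1, int(round(rng.lognormal(np.log(5.0), 0.5))))
            else:
                gap = max(1, int(round(rng.lognormal(gap_spec.mu, gap_spec.sigma))))
            age = cur_age + gap
        events.append((stage.role, concept, age))
        attained.add(stage.role)
        cur_age = age
    return events


def generate_cohort(
    spec: CohortSpec,
    seed: Optional[int] = None,
    dictionary: Optional[ConceptDictionary] = None,
) -> tuple[list[ProcedureRecord], list[LifeStatus], GroundTruth]:
    """Generate a full synthetic registry extract.

    Deterministic given ``seed`` (falls back to ``spec.seed``).  Corruption
    is applied per block at the block's ``corruption_rate`` via
    :func:`inject_data_issues`; corrupted patients are labelled in the
    ground truth, whose event fields describe the pre-corruption records.
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    if dictionary is None:
        dictionary = load_concept_dictionary()

    all_records: list[ProcedureRecord] = []
    all_life: list[LifeStatus] = []
    patient_rows: list[dict] = []
    reint_rows: list[dict] = []

    for block in spec.blocks:
        records, life, p_rows, r_rows = _generate_block(block, spec, seed, dictionary)
        if block.corruption_rate > 0 and p_rows:
            truth_block = GroundTruth(
                patients=pd.DataFrame(p_rows),
                reinterventions=pd.DataFrame(
                    r_rows, columns=["patient_id", "age_days", "concept", "modality", "category"]
                ),
            )
            corrupt_seed = (seed * 1000003 + zlib.crc32(block.diagnosis.value.encode())) % (
                2**31
            )
            records = inject_data_issues(
                records, truth_block, block.corruption_rate, corrupt_seed
            )
            for row, corrupted in zip(
                p_rows, truth_block.patients["corrupted"].tolist()
            ):
                row["corrupted"] = corrupted
        all_records.extend(records)
        all_life.extend(life)
        patient_rows.extend(p_rows)
        reint_rows.extend(r_rows)

    patients = pd.DataFrame(
        patient_rows,
        columns=[
            "patient_id",
            "diagnosis",
            "subgroup",
            "sv_pathway",
            "prematurity",
            "comorbidity",
            "weight_kg",
            "first_proc_age_days",
            "death_age_days",
            "terminal_kind",
            "terminal_age_days",
            "ltfu",
            "corrupted",
            "excluded_reason",
            "prepathway_age",
            "stage1_age",
            "stage2_age",
            "stage3_age",
            "repair_age",
            "first_reint_age_days",
            "n_reints",
        ],
    )
    reints = pd.DataFrame(
        reint_rows, columns=["patient_id", "age_days", "concept", "modality", "category"]
    )
    return all_records, all_life, GroundTruth(patients=patients, reinterventions=reints)


def _generate_block(
    block: DiagnosisBlock,
    spec: CohortSpec,
    seed: int,
    dictionary: ConceptDictionary,
) -> tuple[list[ProcedureRecord], list[LifeStatus], list[dict], list[dict]]:
    rng = _block_rng(seed, block.diagnosis.value)
    n = block.n_patients
    records: list[ProcedureRecord] = []
    life: list[LifeStatus] = []
    p_rows: list[dict] = []
    r_rows: list[dict] = []
    if n == 0:
        return records, life, p_rows, r_rows

    study_days = spec.study_days
    hd = death_hazards_from_survival(block.survival_targets)
    hr = reint_hazards_from_cif(block.reint_targets, hd)

    fractions = block.subgroup_fractions()
    sub_idx = rng.choice(len(block.subgroups), size=n, p=fractions)
    age_mu = np.array([s.age_first_proc_days.mu for s in block.subgroups])
    age_sigma = np.array([s.age_first_proc_days.sigma for s in block.subgroups])
    w_mu = np.array([s.weight_first_proc_kg.mu for s in block.subgroups])
    w_sigma = np.array([s.weight_first_proc_kg.sigma for s in block.subgroups])
    first_proc = np.round(rng.lognormal(age_mu[sub_idx], age_sigma[sub_idx])).astype(int)
    first_proc = np.clip(first_proc, 0, int(study_days) - 2)
    weight = np.round(rng.lognormal(w_mu[sub_idx], w_sigma[sub_idx]), 2)

    premature = rng.random(n) < block.prematurity_rate
    comorbid = rng.random(n) < block.comorbidity_rate
    sv_flag = rng.random(n) < block.sv_fraction
    ltfu = rng.random(n) < block.ltfu_rate
    death_years = sample_piecewise_exponential(rng, hd, n)
    entry_u = rng.random(n)
    excl_u = rng.random(n)
    centers = rng.integers(0, 12, size=n)

    for i in range(n):
        pid = f"{block.diagnosis.value}-{i:05d}"
        subgroup = block.subgroups[int(sub_idx[i])].name
        dx_concepts = SUBGROUP_DIAGNOSIS_CONCEPTS[(block.diagnosis.value, subgroup)]

        death_day: Optional[int] = None
        if np.isfinite(death_years[i]):
            death_day = max(1, int(round(death_years[i] * DAYS_PER_YEAR)))
        fp = int(first_proc[i])
        if death_day is not None and fp >= death_day:
            # registry cohorts condition on entry: very early deaths still
            # receive their first procedure, just earlier
            fp = max(0, death_day // 2)

        c_admin = fp + 1 + int(entry_u[i] * (study_days - fp - 1))
        record_limit = min(death_day, c_admin) if death_day is not None else c_admin

        # exclusion injection (disjoint, in spec-rate order)
        u = excl_u[i]
        excluded_reason = ""
        born_in_window = True
        residency = Residency.ENGLAND_WALES
        if u < spec.born_outside_window_rate:
            excluded_reason = "born_outside_window"
            born_in_window = False
        elif u < spec.born_outside_window_rate + spec.nonresident_rate:
            excluded_reason = "outside_england_wales"
            residency = Residency.OTHER
        elif u < (
            spec.born_outside_window_rate + spec.nonresident_rate + spec.non_nhs_rate
        ):
            excluded_reason = "non_nhs"
            residency = Residency.NON_NHS

        template = block.pathway_sv if sv_flag[i] else block.pathway_bv
        if not template:
            template = block.pathway_bv or block.pathway_sv
        stage_events = _sample_stage_events(rng, template, subgroup, fp)
        if not stage_events:
            # keep the patient in the registry: a diagnostic catheter only
            stage_events = [(Role.OTHER, "diagnostic_catheter", fp)]

        reint_years = sample_poisson_process(
            rng, hr, record_limit / DAYS_PER_YEAR
        )
        slot_only = [e for e in stage_events if e[0] is not Role.OTHER]
        reint_events: list[tuple[Role, str, int, Modality]] = []
        for ty in reint_years:
            t_days = max(1, int(round(ty * DAYS_PER_YEAR)))
            surgical = rng.random() < block.reint_surgical_fraction
            concept, modality = _pick_reint_concept(
                rng, surgical, block.diagnosis, dictionary, slot_only, t_days
            )
            reint_events.append((Role.OTHER, concept, t_days, modality))

        # merge, keeping pathway procedures ahead of reinterventions on ties,
        # then force strictly increasing ages so adjudication is unambiguous
        merged: list[list] = [
            [role, concept, age, CONCEPT_MODALITY[concept]]
            for role, concept, age in stage_events
        ]
        merged.extend([list(e) for e in reint_events])
        merged.sort(key=lambda e: e[2])
        prev_age = -1
        for ev in merged:
            if ev[2] <= prev_age:
                ev[2] = prev_age + 1
            prev_age = ev[2]
        merged = [ev for ev in merged if ev[2] <= record_limit]
        if not merged:
            merged = [[Role.OTHER, "diagnostic_catheter", fp, Modality.CATHETER]]
        fp = merged[0][2]

        # emit procedure records
        first_rec_concepts = set(dx_concepts)
        if premature[i]:
            first_rec_concepts.add("prematurity")
        if comorbid[i]:
            first_rec_concepts.add("congenital_comorbidity")
        last_discharge = fp
        for j, (role, concept, age, modality) in enumerate(merged):
            los = max(2, int(round(rng.lognormal(np.log(12.0), 0.6))))
            discharge = age + los
            if death_day is not None:
                discharge = min(discharge, death_day)
            discharge = max(discharge, age)
            last_discharge = max(last_discharge, discharge)
            records.append(
                ProcedureRecord(
                    patient_id=pid,
                    age_days=int(age),
                    procedure_concepts=frozenset({concept}),
                    diagnosis_concepts=frozenset(
                        first_rec_concepts if j == 0 else dx_concepts
                    ),
                    modality=modality,
                    discharge_age_days=int(discharge),
                    center_id=f"C{int(centers[i]):02d}",
                    residency=residency,
                    born_in_window=born_in_window,
                )
            )

        # observed life status under the ascertainment precedence
        in_hospital_death = death_day is not None and death_day <= last_discharge
        death_observed = death_day is not None and death_day <= c_admin
        nchda_death = death_day if in_hospital_death else None
        ons_death = None
        ons_alive = None
        if not ltfu[i]:
            if death_observed:
                ons_death = death_day
            else:
                ons_alive = c_admin
        if ltfu[i] and not in_hospital_death:
            terminal_kind, terminal_age = "censored", last_discharge
        elif death_observed or in_hospital_death:
            terminal_kind, terminal_age = "dead", death_day
        else:
            terminal_kind, terminal_age = "censored", c_admin
        life.append(
            LifeStatus(
                patient_id=pid,
                nchda_death_age_days=nchda_death,
                ons_death_age_days=ons_death,
                ons_alive_confirm_age_days=ons_alive,
            )
        )

        # true slots = first kept occurrence of each role; everything the
        # reintervention process emitted is a true reintervention
        slot_ages: dict[Role, int] = {}
        true_reints: list[tuple[int, str, Modality]] = []
        for role, concept, age, modality in merged:
            if role is Role.OTHER:
                if concept != "diagnostic_catheter":
                    true_reints.append((age, concept, modality))
            elif role not in slot_ages:
                slot_ages[role] = age
        for age, concept, modality in true_reints:
            r_rows.append(
                {
                    "patient_id": pid,
                    "age_days": age,
                    "concept": concept,
                    "modality": modality.value,
                    "category": (
                        "surgical" if modality in SURGICAL_MODALITIES else "catheter"
                    ),
                }
            )
        first_reint = min((a for a, _, _ in true_reints), default=None)

        p_rows.append(
            {
                "patient_id": pid,
                "diagnosis": block.diagnosis.value,
                "subgroup": subgroup,
                "sv_pathway": bool(sv_flag[i]),
                "prematurity": bool(premature[i]),
                "comorbidity": bool(comorbid[i]),
                "weight_kg": float(weight[i]),
                "first_proc_age_days": fp,
                "death_age_days": death_day if death_day is not None else np.nan,
                "terminal_kind": terminal_kind,
                "terminal_age_days": terminal_age,
                "ltfu": bool(ltfu[i]),
                "corrupted": False,
                "excluded_reason": excluded_reason,
                "prepathway_age": slot_ages.get(Role.PREPATHWAY, np.nan),
                "stage1_age": slot_ages.get(Role.STAGE1, np.nan),
                "stage2_age": slot_ages.get(Role.STAGE2, np.nan),
                "stage3_age": slot_ages.get(Role.STAGE3, np.nan),
                "repair_age": slot_ages.get(Role.REPAIR, np.nan),
                "first_reint_age_days": first_reint if first_reint is not None else np.nan,
                "n_reints": len(true_reints),
            }
        )
    return records, life, p_rows, r_rows


# ---------------------------------------------------------------------------
# corruption injection
# ---------------------------------------------------------------------------


def inject_data_issues(
    records: list[ProcedureRecord],
    ground_truth: GroundTruth,
    corruption_rate: float,
    seed: int,
) -> list[ProcedureRecord]:
    """Make a random subset of patients' sequences implausible.

    For each selected patient, in order of applicability: delete the stage-1
    record while keeping stage 2; delete the stage-2 record while keeping
    stage 3; otherwise duplicate the latest filled pathway procedure as a
    same-day row.  Corruption labels are updated in the ground truth.
    """
    if not 0.0 <= corruption_rate <= 1.0:
        raise SpecError("corruption_rate outside [0,1]")
    if corruption_rate == 0.0 or not records:
        return list(records)
    rng = _block_rng(seed, "corruption")
    by_patient: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        by_patient.setdefault(rec.patient_id, []).append(idx)

    patients = ground_truth.patients
    selected = rng.random(len(patients)) < corruption_rate
    drop: set[int] = set()
    duplicate_after: dict[int, ProcedureRecord] = {}
    corrupted_flags = patients["corrupted"].to_numpy().copy()

    def _record_at(pid: str, age: float) -> Optional[int]:
        for idx in by_patient.get(pid, []):
            if records[idx].age_days == int(age):
                return idx
        return None

    for row_i, row in enumerate(patients.itertuples(index=False)):
        if not selected[row_i]:
            continue
        pid = row.patient_id
        s1, s2, s3 = row.stage1_age, row.stage2_age, row.stage3_age
        rep = row.repair_age
        applied = False
        if not pd.isna(s1) and not pd.isna(s2):
            idx = _record_at(pid, s1)
            if idx is not None:
                drop.add(idx)
                applied = True
        elif not pd.isna(s2) and not pd.isna(s3):
            idx = _record_at(pid, s2)
            if idx is not None:
                drop.add(idx)
                applied = True
        else:
            for age in (rep, s3, s2, s1):
                if not pd.isna(age):
                    idx = _record_at(pid, age)
                    if idx is not None:
                        duplicate_after[idx] = records[idx]
                        applied = True
                    break
        if applied:
            corrupted_flags[row_i] = True

    out: list[ProcedureRecord] = []
    for idx, rec in enumerate(records):
        if idx in drop:
            continue
        out.append(rec)
        if idx in duplicate_after:
            out.append(duplicate_after[idx])
    ground_truth.patients["corrupted"] = corrupted_flags
    return out


# ---------------------------------------------------------------------------
# fixture serialization
# ---------------------------------------------------------------------------


def write_fixture(
    records: Iterable[ProcedureRecord],
    life: Iterable[LifeStatus],
    truth: GroundTruth,
    directory: Union[str, Path],
    dictionary: Optional[ConceptDictionary] = None,
) -> dict[str, Path]:
    """Write a cohort as CSVs (registry dialect) plus ground-truth JSON."""
    from .registry_io import write_life_status_table, write_procedure_table

    if dictionary is None:
        dictionary = load_concept_dictionary()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "procedures": directory / "procedures.csv",
        "life_status": directory / "life_status.csv",
        "ground_truth": directory / "ground_truth.json",
    }
    write_procedure_table(records, paths["procedures"], dictionary)
    write_life_status_table(life, paths["life_status"])

    def _clean(df: pd.DataFrame) -> list[dict]:
        out = []
        for row in df.to_dict(orient="records"):
            out.append(
                {
                    k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in row.items()
                }
            )
        return out

    doc = {
        "patients": _clean(truth.patients),
        "reinterventions": _clean(truth.reinterventions),
    }
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, indent=None, default=float)
    return paths


def read_ground_truth(path: Union[str, Path]) -> GroundTruth:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return GroundTruth(
        patients=pd.DataFrame(doc["patients"]),
        reinterventions=pd.DataFrame(
            doc["reinterventions"],
            columns=["patient_id", "age_days", "concept", "modality", "category"],
        ),
    )


# ---------------------------------------------------------------------------
# spec loading
# ---------------------------------------------------------------------------


def _parse_lognormal(raw) -> LogNormalSpec:
    if isinstance(raw, dict):
        return LogNormalSpec(float(raw["median"]), float(raw["q1"]), float(raw["q3"]))
    med, q1, q3 = raw
    return LogNormalSpec(float(med), float(q1), float(q3))


def _parse_stage(raw: dict) -> StageSpec:
    role = Role(raw["role"])
    if "concept" in raw:
        concepts = ((str(raw["concept"]), 1.0),)
    else:
        concepts = tuple((str(c), float(w)) for c, w in raw["concepts"].items())
    by_sub = tuple(
        (str(s), str(c)) for s, c in (raw.get("concepts_by_subgroup") or {}).items()
    )
    gap = raw.get("gap_days")
    gap_spec = None
    if gap is not None:
        med, sigma = gap
        # gap given as (median days, log-sigma)
        q1 = med * np.exp(-_Z75 * sigma)
        q3 = med * np.exp(_Z75 * sigma)
        gap_spec = LogNormalSpec(float(med), float(q1), float(q3))
    return StageSpec(
        role=role,
        concepts=concepts,
        prob=float(raw["prob"]),
        gap_days=gap_spec,
        concepts_by_subgroup=by_sub,
    )


def _parse_block(raw: dict) -> DiagnosisBlock:
    subgroups = tuple(
        SubgroupSpec(
            name=str(name),
            count=float(sub["n"]),
            age_first_proc_days=_parse_lognormal(sub["age_days"]),
            weight_first_proc_kg=_parse_lognormal(sub["weight_kg"]),
        )
        for name, sub in raw["subgroups"].items()
    )
    return DiagnosisBlock(
        diagnosis=Diagnosis(raw["diagnosis"]),
        n_patients=int(raw["n_patients"]),
        subgroups=subgroups,
        survival_targets=tuple(float(x) for x in raw["survival"]),
        reint_targets=tuple(float(x) for x in raw["reintervention"]),
        prematurity_rate=float(raw["prematurity_rate"]),
        comorbidity_rate=float(raw["comorbidity_rate"]),
        sv_fraction=float(raw["sv_fraction"]),
        pathway_sv=tuple(_parse_stage(s) for s in raw.get("pathway_sv", [])),
        pathway_bv=tuple(_parse_stage(s) for s in raw.get("pathway_bv", [])),
        reint_surgical_fraction=float(raw.get("reint_surgical_fraction", 0.5)),
        ltfu_rate=float(raw.get("ltfu_rate", 0.02)),
        corruption_rate=float(raw.get("corruption_rate", 0.01)),
    )


def default_cohort_path() -> Path:
    return Path(resources.files("sentinelchd").joinpath("data/default_cohort.yaml"))


def load_cohort_spec(path: Union[str, Path, None] = None) -> CohortSpec:
    """Load a cohort spec; the bundled calibrated default when ``path`` is None."""
    p = Path(path) if path is not None else default_cohort_path()
    with open(p, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    spec = CohortSpec(
        blocks=tuple(_parse_block(b) for b in doc["blocks"]),
        study_years=float(doc.get("study_years", 22.0)),
        born_outside_window_rate=float(doc.get("born_outside_window_rate", 0.0)),
        nonresident_rate=float(doc.get("nonresident_rate", 0.0)),
        non_nhs_rate=float(doc.get("non_nhs_rate", 0.0)),
        seed=int(doc.get("seed", 0)),
    )
    spec.validate()
    return spec
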