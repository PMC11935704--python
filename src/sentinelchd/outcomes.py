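"""Life-status ascertainment, Kaplan-Meier survival, competing-risks CIF,
and the per-diagnosis outcome tables.

Time origin is birth (age scale), so "survival at 10 years" means survival
to the 10th birthday regardless of when treatment started.  Survival uses
the product-limit estimator with Greenwood variance and log(-log)
(complementary log-log) 95% confidence intervals, which stay inside [0,1].
Reintervention incidence uses the Aalen-Johansen cumulative incidence
function with death, and heart transplant without prior reintervention,
as competing events; its variance is the Marubini-Valsecchi estimator and
confidence intervals are delta-method on log(-log F).

Tie conventions: deaths are processed before censorings at the same age;
a reintervention and a competing event on the same day resolve as a
reintervention (it ends follow-up as the event of interest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .pathway_engine import (
    CATHETER_CATEGORY,
    SURGICAL_CATEGORY,
    PathwayAssignment,
)
from .records import (
    DAYS_PER_YEAR,
    REPORT_AGES_YEARS,
    Diagnosis,
    PatientHistory,
)

logger = logging.getLogger(__name__)

Z95 = float(norm.ppf(0.975))

REINT_CATEGORIES = ("any", SURGICAL_CATEGORY, CATHETER_CATEGORY)

#: cause labels for the competing-risks analysis
CAUSE_REINTERVENTION = "reintervention"
CAUSE_DEATH_OR_TRANSPLANT = "death_or_transplant"


class DataIntegrityError(ValueError):
    """An event sequence is internally inconsistent (e.g. procedure after death)."""


# ---------------------------------------------------------------------------
# life-status ascertainment
# ---------------------------------------------------------------------------

DEAD = "dead"
CENSORED = "censored"


@dataclass(frozen=True)
class Ascertainment:
    kind: str  # DEAD or CENSORED
    age_days: int
    lost_to_followup: bool = False


def ascertain_life_status(history: PatientHistory) -> Optional[Ascertainment]:
    """Resolve one patient's terminal state by source precedence.

    Precedence: audit-recorded death age, then national-register death age,
    then alive-confirmation age (censoring), then the latest hospital
    discharge age (censoring, marked lost to follow-up).  Returns ``None``
    (caller logs and excludes) when no age is resolvable at all.
    """
    ls = history.life_status
    if ls.nchda_death_age_days is not None:
        return Ascertainment(DEAD, ls.nchda_death_age_days)
    if ls.ons_death_age_days is not None:
        return Ascertainment(DEAD, ls.ons_death_age_days)
    if ls.ons_alive_confirm_age_days is not None:
        return Ascertainment(CENSORED, ls.ons_alive_confirm_age_days)
    last = history.last_discharge_age()
    if last is not None:
        return Ascertainment(CENSORED, last, lost_to_followup=True)
    logger.warning("patient %s has no resolvable life status", history.patient_id)
    return None


# ---------------------------------------------------------------------------
# event histories
# ---------------------------------------------------------------------------


@dataclass
class EventHistory:
    """Per-patient event ages on the age-in-days scale."""

    patient_id: str
    death_age_days: Optional[int]
    censor_age_days: Optional[int]
    first_reint_age_days: dict[str, Optional[int]]  # per REINT_CATEGORIES
    transplant_age_days: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.death_age_days is None) == (self.censor_age_days is None):
            raise DataIntegrityError(
                f"patient {self.patient_id!r}: exactly one of death/censor required"
            )

    @property
    def terminal_age_days(self) -> int:
        return (
            self.death_age_days
            if self.death_age_days is not None
            else self.censor_age_days  # type: ignore[return-value]
        )


def build_event_history(
    history: PatientHistory,
    assignment: PathwayAssignment,
    ascertainment: Ascertainment,
) -> EventHistory:
    """Combine pathway adjudication and life status into one event record."""
    terminal = ascertainment.age_days
    first: dict[str, Optional[int]] = {c: None for c in REINT_CATEGORIES}
    for reint in assignment.reinterventions:
        if ascertainment.kind == DEAD and reint.age_days > terminal:
            raise DataIntegrityError(
                f"patient {history.patient_id!r}: reintervention at "
                f"{reint.age_days}d after recorded death at {terminal}d"
            )
        for cat in ("any", reint.category):
            if first[cat] is None or reint.age_days < first[cat]:
                first[cat] = reint.age_days
    return EventHistory(
        patient_id=history.patient_id,
        death_age_days=terminal if ascertainment.kind == DEAD else None,
        censor_age_days=terminal if ascertainment.kind == CENSORED else None,
        first_reint_age_days=first,
        transplant_age_days=assignment.transplant_age_days,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class SurvivalEstimate:
    """Right-continuous product-limit step function on the age-days scale."""

    times: np.ndarray  # distinct death ages, ascending
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray  # S(t) just after each step
    greenwood: np.ndarray  # cumulative sum d/(n(n-d))
    n_total: int

    @property
    def variance(self) -> np.ndarray:
        return self.survival**2 * self.greenwood

    def _step_index(self, age_days: float) -> int:
        return int(np.searchsorted(self.times, age_days, side="right")) - 1

    def survival_at(self, age_days: float) -> float:
        i = self._step_index(age_days)
        return 1.0 if i < 0 else float(self.survival[i])

    def ci_at(self, age_days: float, z: float = Z95) -> tuple[float, float]:
        """log(-log) (exponential Greenwood) confidence interval at an age."""
        i = self._step_index(age_days)
        if i < 0:
            return (1.0, 1.0)
        s = float(self.survival[i])
        gw = float(self.greenwood[i])
        if s >= 1.0 or gw == 0.0:
            return (1.0, 1.0)  # degenerate: no deaths observed yet
        if s <= 0.0:
            return (0.0, 0.0)
        se_theta = np.sqrt(gw) / abs(np.log(s))
        lo = s ** np.exp(z * se_theta)
        hi = s ** np.exp(-z * se_theta)
        return (float(lo), float(hi))


def km_from_arrays(durations: np.ndarray, observed: np.ndarray) -> SurvivalEstimate:
    """Product-limit estimator from duration/event arrays.

    At a tied age, subjects censored at that age are still at risk for the
    deaths occurring then (deaths before censorings).
    """
    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if durations.size == 0:
        raise ValueError("need at least one subject")
    event_times = np.unique(durations[observed])
    if event_times.size == 0:
        return SurvivalEstimate(
            times=np.empty(0),
            n_risk=np.empty(0, dtype=int),
            n_event=np.empty(0, dtype=int),
            survival=np.empty(0),
            greenwood=np.empty(0),
            n_total=int(durations.size),
        )
    # at risk at t: duration >= t
    n_risk = (durations[None, :] >= event_times[:, None]).sum(axis=1)
    d = np.array(
        [(observed & (durations == t)).sum() for t in event_times], dtype=int
    )
    frac = 1.0 - d / n_risk
    survival = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
    greenwood = np.cumsum(gw_terms)
    return SurvivalEstimate(
        times=event_times,
        n_risk=n_risk.astype(int),
        n_event=d,
        survival=survival,
        greenwood=greenwood,
        n_total=int(durations.size),
    )


def km_survival(
    event_histories: Iterable[EventHistory],
    report_ages_years: Sequence[float] = REPORT_AGES_YEARS,
) -> SurvivalEstimate:
    """Kaplan-Meier all-cause survival from birth for a patient group."""
    histories = list(event_histories)
    durations = np.array([h.terminal_age_days for h in histories], dtype=float)
    observed = np.array([h.death_age_days is not None for h in histories])
    return km_from_arrays(durations, observed)


# ---------------------------------------------------------------------------
# competing-risks cumulative incidence (Aalen-Johansen)
# ---------------------------------------------------------------------------


@dataclass
class CIFEstimate:
    """Aalen-Johansen cumulative incidence for competing causes.

    ``cif[cause]`` is the non-decreasing step function F_k(t); at every step
    the identity sum_k F_k(t) + S_eventfree(t) = 1 holds.
    """

    times: np.ndarray  # distinct any-cause event ages
    cif: dict[str, np.ndarray]
    variance: dict[str, np.ndarray]
    eventfree: np.ndarray  # all-cause event-free KM just after each step
    n_risk: np.ndarray
    n_event: dict[str, np.ndarray]
    n_total: int

    def _step_index(self, age_days: float) -> int:
        return int(np.searchsorted(self.times, age_days, side="right")) - 1

    def cif_at(self, cause: str, age_days: float) -> float:
        i = self._step_index(age_days)
        return 0.0 if i < 0 else float(self.cif[cause][i])

    def ci_at(self, cause: str, age_days: float, z: float = Z95) -> tuple[float, float]:
        """Delta-method log(-log F) confidence interval at an age."""
        i = self._step_index(age_days)
        if i < 0:
            return (0.0, 0.0)
        f = float(self.cif[cause][i])
        v = float(self.variance[cause][i])
        if f <= 0.0:
            return (0.0, 0.0)
        if f >= 1.0 or v <= 0.0:
            return (f, f)
        se_theta = np.sqrt(v) / abs(f * np.log(f))
        lo = f ** np.exp(z * se_theta)
        hi = f ** np.exp(-z * se_theta)
        return (float(min(lo, hi)), float(max(lo, hi)))


def aalen_johansen(
    durations: np.ndarray,
    events: np.ndarray,
    causes: Sequence[str] = (CAUSE_REINTERVENTION, CAUSE_DEATH_OR_TRANSPLANT),
) -> CIFEstimate:
    """Aalen-Johansen CIF from durations and integer event codes.

    ``events`` codes: 0 = censored, k = 1-based index into ``causes``.
    F_k(t) = sum over event ages t_i <= t of S(t_i-) d_ki / n_i with S the
    all-cause event-free Kaplan-Meier.  Variances follow Marubini-Valsecchi.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if durations.size == 0:
        raise ValueError("need at least one subject")
    any_event = events > 0
    times = np.unique(durations[any_event])
    m = times.size
    n_total = int(durations.size)

    n_risk = (durations[None, :] >= times[:, None]).sum(axis=1).astype(float)
    d_all = np.array(
        [(any_event & (durations == t)).sum() for t in times], dtype=float
    )
    d_by_cause = {
        cause: np.array(
            [((events == k + 1) & (durations == t)).sum() for t in times],
            dtype=float,
        )
        for k, cause in enumerate(causes)
    }

    # all-cause event-free KM; S_minus[i] = S just before times[i]
    frac = 1.0 - d_all / n_risk
    eventfree = np.cumprod(frac)
    s_minus = np.concatenate(([1.0], eventfree[:-1]))

    cif: dict[str, np.ndarray] = {}
    variance: dict[str, np.ndarray] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(n_risk > d_all, d_all / (n_risk * (n_risk - d_all)), 0.0)
    for cause in causes:
        dk = d_by_cause[cause]
        jumps = s_minus * dk / n_risk
        F = np.cumsum(jumps)
        cif[cause] = F
        # Marubini-Valsecchi variance via cumulative expansions:
        # Var F(t) = sum_j [F(t)-F_j]^2 a_j
        #          + sum_j S_{j-}^2 ((n_j-d_kj)/n_j) d_kj/n_j^2
        #          - 2 sum_j [F(t)-F_j] S_{j-} d_kj/n_j^2
        b = s_minus * dk / n_risk**2
        c2 = s_minus**2 * ((n_risk - dk) / n_risk) * dk / n_risk**2
        ca = np.cumsum(a)
        cFa = np.cumsum(F * a)
        cF2a = np.cumsum(F**2 * a)
        cb = np.cumsum(b)
        cFb = np.cumsum(F * b)
        cc2 = np.cumsum(c2)
        var = (
            F**2 * ca - 2.0 * F * cFa + cF2a + cc2 - 2.0 * (F * cb - cFb)
        )
        variance[cause] = np.maximum(var, 0.0)

    return CIFEstimate(
        times=times,
        cif=cif,
        variance=variance,
        eventfree=eventfree,
        n_risk=n_risk.astype(int),
        n_event={c: d_by_cause[c].astype(int) for c in causes},
        n_total=n_total,
    )


def reint_durations_events(
    event_histories: Iterable[EventHistory],
    category: str = "any",
) -> tuple[np.ndarray, np.ndarray]:
    """First-event durations and codes for the reintervention CIF.

    Follow-up ends at the earliest of first reintervention (of the chosen
    category), death, transplant, or censoring.  Ties resolve as
    reintervention first; transplant without prior reintervention joins
    death as the competing cause.
    """
    durs: list[float] = []
    evs: list[int] = []
    for h in event_histories:
        t_r = h.first_reint_age_days.get(category)
        competing = [t for t in (h.death_age_days, h.transplant_age_days) if t is not None]
        t_comp = min(competing) if competing else None
        t_cens = h.censor_age_days
        candidates = [t for t in (t_r, t_comp, t_cens) if t is not None]
        t = min(candidates)
        if t_r is not None and t_r == t:
            code = 1
        elif t_comp is not None and t_comp == t:
            code = 2
        else:
            code = 0
        durs.append(float(t))
        evs.append(code)
    return np.array(durs), np.array(evs, dtype=int)


def cif_competing(
    event_histories: Iterable[EventHistory],
    category: str = "any",
    report_ages_years: Sequence[float] = REPORT_AGES_YEARS,
) -> CIFEstimate:
    """Cumulative incidence of reintervention with competing death/transplant."""
    durs, evs = reint_durations_events(list(event_histories), category)
    return aalen_johansen(durs, evs)


# ---------------------------------------------------------------------------
# outcome tables
# ---------------------------------------------------------------------------


def _fu_stats(ages_days: np.ndarray) -> dict[str, float]:
    years = ages_days / DAYS_PER_YEAR
    q1, med, q3 = np.percentile(years, [25, 50, 75])
    return {
        "fu_median_y": round(float(med), 1),
        "fu_q1_y": round(float(q1), 1),
        "fu_q3_y": round(float(q3), 1),
        "fu_min_y": round(float(years.min()), 1),
        "fu_max_y": round(float(years.max()), 1),
    }


def _survival_cells(
    est: SurvivalEstimate, ages_years: Sequence[float]
) -> dict[str, float]:
    out = {}
    for y in ages_years:
        t = y * DAYS_PER_YEAR
        lo, hi = est.ci_at(t)
        label = f"{y:g}y"
        out[f"surv_{label}"] = est.survival_at(t)
        out[f"surv_{label}_lo"] = lo
        out[f"surv_{label}_hi"] = hi
    return out


def _cif_cells(
    est: CIFEstimate, category: str, ages_years: Sequence[float]
) -> dict[str, float]:
    out = {}
    for y in ages_years:
        t = y * DAYS_PER_YEAR
        lo, hi = est.ci_at(CAUSE_REINTERVENTION, t)
        label = f"{y:g}y"
        out[f"reint_{category}_{label}"] = est.cif_at(CAUSE_REINTERVENTION, t)
        out[f"reint_{category}_{label}_lo"] = lo
        out[f"reint_{category}_{label}_hi"] = hi
    return out


def metrics_table(
    cohort: pd.DataFrame,
    event_histories: Mapping[str, EventHistory],
    report_ages_years: Sequence[float] = REPORT_AGES_YEARS,
    exclude_flagged_from_survival: bool = False,
) -> pd.DataFrame:
    """Per-diagnosis and per-subgroup outcome rows.

    ``cohort`` needs columns patient_id, diagnosis, subgroup, flagged.
    Quality-flagged patients are always excluded from reintervention
    metrics; exclusion from survival metrics is a reporting option (off by
    default).  Groups with no patients are omitted with a log entry.
    """
    rows = []
    for dx, dx_df in cohort.groupby("diagnosis", sort=False):
        groups = [("total", dx_df)]
        for sub, sub_df in dx_df.groupby("subgroup", sort=False):
            groups.append((sub, sub_df))
        for label, df in groups:
            surv_df = df[~df["flagged"]] if exclude_flagged_from_survival else df
            reint_df = df[~df["flagged"]]
            if len(surv_df) == 0:
                logger.info("omitting empty group %s/%s", dx, label)
                continue
            surv_hist = [event_histories[p] for p in surv_df["patient_id"]]
            reint_hist = [event_histories[p] for p in reint_df["patient_id"]]
            terminal = np.array([h.terminal_age_days for h in surv_hist], dtype=float)
            row: dict = {
                "diagnosis": dx,
                "subgroup": label,
                "n": len(df),
                "n_reint_cohort": len(reint_df),
            }
            row.update(_fu_stats(terminal))
            km = km_survival(surv_hist)
            row.update(_survival_cells(km, report_ages_years))
            if reint_hist:
                for cat in REINT_CATEGORIES:
                    est = cif_competing(reint_hist, category=cat)
                    row.update(_cif_cells(est, cat, report_ages_years))
            rows.append(row)
    return pd.DataFrame(rows)


def scoping_metrics(
    cohort: pd.DataFrame,
    histories: Mapping[str, PatientHistory],
    ascertainments: Mapping[str, Ascertainment],
) -> pd.DataFrame:
    """Per-diagnosis scoping proportions used to select sentinel conditions.

    Infancy means first procedure before age 1 year; the procedure count
    includes every registry record; death before 5 years comes from the
    ascertained life status.
    """
    infancy_cut = DAYS_PER_YEAR
    five_years = 5 * DAYS_PER_YEAR
    rows = []
    for dx, df in cohort.groupby("diagnosis", sort=False):
        n = len(df)
        in_infancy = 0
        three_plus = 0
        died_lt5 = 0
        for pid in df["patient_id"]:
            h = histories[pid]
            first = h.first_procedure_age()
            if first is not None and first < infancy_cut:
                in_infancy += 1
            if len(h.records) >= 3:
                three_plus += 1
            asc = ascertainments.get(pid)
            if asc is not None and asc.kind == DEAD and asc.age_days < five_years:
                died_lt5 += 1
        rows.append(
            {
                "diagnosis": dx,
                "n": n,
                "pct_treated_in_infancy": round(100.0 * in_infancy / n, 1),
                "pct_3plus_procedures": round(100.0 * three_plus / n, 1),
                "pct_died_before_5y": round(100.0 * died_lt5 / n, 1),
            }
        )
    return pd.DataFrame(rows)


def plot_km(est: SurvivalEstimate, ax=None, label: Optional[str] = None):
    """Step plot of a survival estimate (age in years)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.concatenate(([0.0], est.times / DAYS_PER_YEAR))
    y = np.concatenate(([1.0], est.survival))
    ax.step(x, y, where="post", label=label)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("survival")
    ax.set_ylim(0, 1.02)
    return ax


def plot_cif(est: CIFEstimate, cause: str = CAUSE_REINTERVENTION, ax=None, label=None):
    """Step plot of a cumulative incidence function (age in years)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.concatenate(([0.0], est.times / DAYS_PER_YEAR))
    y = np.concatenate(([0.0], est.cif[cause]))
    ax.step(x, y, where="post", label=label)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("cumulative incidence")
    ax.set_ylim(0, 1.02)
    return ax
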