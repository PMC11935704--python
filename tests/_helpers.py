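"""Shared builders and independent brute-force oracles for the test suite.

The oracles re-derive the product-limit and cumulative-incidence values by
direct enumeration, independently of the package's vectorized estimators.
"""

from __future__ import annotations

import numpy as np

from sentinelchd import LifeStatus, Modality, PatientHistory, ProcedureRecord, Residency


def rec(
    pid: str,
    age: int,
    procs=(),
    diags=(),
    modality: Modality = Modality.BYPASS_SURGERY,
    **kw,
) -> ProcedureRecord:
    return ProcedureRecord(
        patient_id=pid,
        age_days=age,
        procedure_concepts=frozenset(procs),
        diagnosis_concepts=frozenset(diags),
        modality=modality,
        **kw,
    )


def history(pid: str, records, life: LifeStatus | None = None) -> PatientHistory:
    records = sorted(records, key=lambda r: r.age_days)
    return PatientHistory(
        patient_id=pid,
        records=list(records),
        life_status=life if life is not None else LifeStatus.empty(pid),
    )


# ---------------------------------------------------------------------------
# brute-force survival oracles
# ---------------------------------------------------------------------------


def brute_km(durations, observed, t) -> float:
    """Product-limit survival at t by direct enumeration."""
    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    s = 1.0
    for ti in sorted(set(durations[observed])):
        if ti > t:
            break
        n = int((durations >= ti).sum())
        d = int((observed & (durations == ti)).sum())
        s *= 1.0 - d / n
    return s


def brute_cif(durations, events, cause: int, t) -> float:
    """Aalen-Johansen cumulative incidence at t by direct enumeration."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    any_event = events > 0
    f = 0.0
    for ti in sorted(set(durations[any_event])):
        if ti > t:
            break
        n = int((durations >= ti).sum())
        dk = int(((events == cause) & (durations == ti)).sum())
        s_minus = brute_km(durations, any_event, ti - 1e-9)
        f += s_minus * dk / n
    return f
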