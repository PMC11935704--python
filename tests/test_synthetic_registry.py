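"""Generator determinism, calibration, corruption and fixture round-trips."""

import dataclasses
import hashlib

import numpy as np
import pandas as pd
import pytest

from sentinelchd import (
    DAYS_PER_YEAR,
    Diagnosis,
    generate_cohort,
    implied_reint_cif,
    implied_survival,
    inject_data_issues,
    km_from_arrays,
    load_cohort_spec,
    write_fixture,
)
from sentinelchd.registry_io import read_life_status_table, read_procedure_table
from sentinelchd.synthetic_registry import (
    SpecError,
    death_hazards_from_survival,
    piecewise_cif,
    piecewise_survival,
    read_ground_truth,
    reint_hazards_from_cif,
    sample_piecewise_exponential,
)

Y = DAYS_PER_YEAR


def _mini_spec(default_spec, n=300, **kw):
    return default_spec.modified(n_patients=n, **kw)


class TestCalibration:
    def test_closed_form_survival_hits_targets(self, default_spec):
        for block in default_spec.blocks:
            s = implied_survival(block, [1, 5, 10])
            assert s == pytest.approx(block.survival_targets, abs=1e-12)

    def test_closed_form_incidence_hits_targets(self, default_spec):
        for block in default_spec.blocks:
            f = implied_reint_cif(block, [1, 5, 10])
            assert f == pytest.approx(block.reint_targets, abs=1e-9)

    def test_hazards_nonnegative(self, default_spec):
        for block in default_spec.blocks:
            hd = death_hazards_from_survival(block.survival_targets)
            hr = reint_hazards_from_cif(block.reint_targets, hd)
            assert (hd >= 0).all() and (hr >= 0).all()

    def test_piecewise_sampler_matches_closed_form(self):
        h = np.array([0.3, 0.05, 0.02, 0.02])
        rng = np.random.default_rng(0)
        t = sample_piecewise_exponential(rng, h, 200_000)
        for age in (1.0, 5.0, 10.0):
            emp = (t > age).mean()
            expected = piecewise_survival(h, np.array([age]))[0]
            assert emp == pytest.approx(expected, abs=0.005)


class TestGeneration:
    def test_empty_spec_gives_empty_outputs(self, default_spec):
        spec = _mini_spec(default_spec, n=0)
        records, life, truth = generate_cohort(spec, seed=1)
        assert records == [] and life == [] and len(truth.patients) == 0

    def test_same_seed_is_byte_identical(self, default_spec, tmp_path, dictionary):
        spec = _mini_spec(default_spec, n=50)
        digests = []
        for run in ("a", "b"):
            records, life, truth = generate_cohort(spec, seed=7)
            paths = write_fixture(records, life, truth, tmp_path / run, dictionary)
            h = hashlib.sha256()
            for p in sorted(paths.values()):
                h.update(p.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_different_seeds_differ(self, default_spec):
        spec = _mini_spec(default_spec, n=50)
        r1, _, _ = generate_cohort(spec, seed=1)
        r2, _, _ = generate_cohort(spec, seed=2)
        assert r1 != r2

    def test_every_patient_has_a_record(self, default_spec):
        spec = _mini_spec(default_spec, n=200)
        records, life, truth = generate_cohort(spec, seed=3)
        with_records = {r.patient_id for r in records}
        assert with_records == set(truth.patients["patient_id"])
        assert len(life) == len(truth.patients)

    def test_stages_attained_in_order_in_clean_data(self, default_spec):
        spec = _mini_spec(default_spec, n=400, corruption_rate=0.0)
        _, _, truth = generate_cohort(spec, seed=4)
        p = truth.patients
        both12 = p.dropna(subset=["stage1_age", "stage2_age"])
        assert (both12["stage1_age"] < both12["stage2_age"]).all()
        both23 = p.dropna(subset=["stage2_age", "stage3_age"])
        assert (both23["stage2_age"] < both23["stage3_age"]).all()
        no1 = p[p["stage1_age"].isna()]
        assert no1["stage2_age"].isna().all()

    def test_death_truncates_subsequent_procedures(self, default_spec):
        spec = _mini_spec(default_spec, n=400)
        records, life, truth = generate_cohort(spec, seed=5)
        death = {
            row.patient_id: row.death_age_days
            for row in truth.patients.itertuples()
            if not pd.isna(row.death_age_days)
        }
        for r in records:
            if r.patient_id in death:
                assert r.age_days <= death[r.patient_id]

    def test_stage_attainment_fractions_binomial(self, default_spec):
        # with the death hazard silenced, attainment among stage-eligible
        # patients is a plain binomial around the template probability
        hlhs = default_spec.block(Diagnosis.HLHS)
        block = dataclasses.replace(
            hlhs,
            n_patients=2000,
            survival_targets=(0.999999, 0.999998, 0.999997),
            reint_targets=(0.0, 0.0, 0.0),
            ltfu_rate=0.0,
            corruption_rate=0.0,
            subgroups=hlhs.subgroups,
        )
        spec = dataclasses.replace(default_spec, blocks=(block,), study_years=60.0)
        _, _, truth = generate_cohort(spec, seed=6)
        p = truth.patients
        n = len(p)
        stage1 = p["stage1_age"].notna()
        probs = {s.role.value: s.prob for s in block.pathway_sv}
        se1 = np.sqrt(probs["stage1"] * (1 - probs["stage1"]) / n)
        assert abs(stage1.mean() - probs["stage1"]) < 3 * se1
        eligible2 = p[stage1]
        frac2 = eligible2["stage2_age"].notna().mean()
        se2 = np.sqrt(probs["stage2"] * (1 - probs["stage2"]) / len(eligible2))
        assert abs(frac2 - probs["stage2"]) < 3 * se2

    def test_flag_rates_recovered_binomially(self, default_spec):
        spec = _mini_spec(default_spec, n=2000, corruption_rate=0.0)
        blocks = {b.diagnosis: b for b in spec.blocks}
        _, _, truth = generate_cohort(spec, seed=8)
        for dx, df in truth.patients.groupby("diagnosis"):
            rate = blocks[Diagnosis(dx)].comorbidity_rate
            se = np.sqrt(rate * (1 - rate) / len(df))
            assert abs(df["comorbidity"].mean() - rate) <= 3 * se + 1e-9


class TestZeroHazardProperties:
    def _flat_spec(self, default_spec, survival=None, reint=None):
        blocks = []
        for b in default_spec.blocks:
            kw = {"n_patients": 300, "ltfu_rate": 0.0, "corruption_rate": 0.0}
            if survival is not None:
                kw["survival_targets"] = survival
            if reint is not None:
                kw["reint_targets"] = reint
            blocks.append(dataclasses.replace(b, **kw))
        return dataclasses.replace(default_spec, blocks=tuple(blocks))

    def test_no_death_hazard_means_flat_km(self, default_spec):
        spec = self._flat_spec(default_spec, survival=(1.0, 1.0, 1.0))
        _, life, truth = generate_cohort(spec, seed=9)
        assert truth.patients["death_age_days"].isna().all()
        dur = truth.patients["terminal_age_days"].to_numpy(float)
        obs = (truth.patients["terminal_kind"] == "dead").to_numpy()
        est = km_from_arrays(dur, obs)
        assert est.survival_at(25 * Y) == 1.0

    def test_no_reint_hazard_means_zero_incidence(self, default_spec):
        spec = self._flat_spec(default_spec, reint=(0.0, 0.0, 0.0))
        _, _, truth = generate_cohort(spec, seed=10)
        assert len(truth.reinterventions) == 0


class TestCorruption:
    def test_rate_zero_is_identity(self, default_spec):
        spec = _mini_spec(default_spec, n=100, corruption_rate=0.0)
        records, _, truth = generate_cohort(spec, seed=11)
        out = inject_data_issues(records, truth, 0.0, seed=1)
        assert out == records
        assert not truth.patients["corrupted"].any()

    def test_rate_one_corrupts_every_staged_patient(self, default_spec):
        spec = _mini_spec(default_spec, n=10, corruption_rate=0.0)
        block = dataclasses.replace(spec.block(Diagnosis.HLHS), n_patients=10)
        spec = dataclasses.replace(spec, blocks=(block,))
        records, _, truth = generate_cohort(spec, seed=12)
        staged = truth.patients[
            truth.patients[["stage1_age", "stage2_age", "stage3_age", "repair_age"]]
            .notna()
            .any(axis=1)
        ]
        out = inject_data_issues(records, truth, 1.0, seed=2)
        assert truth.patients["corrupted"].sum() == len(staged)
        assert len(out) != len(records) or out != records

    def test_corrupted_count_binomial_at_one_percent(self, default_spec):
        spec = default_spec  # full published block sizes, n = 29319
        _, _, truth = generate_cohort(spec, seed=13)
        n = len(truth.patients)
        assert n == 29319
        expected = 0.01 * n
        se = np.sqrt(n * 0.01 * 0.99)
        assert abs(truth.patients["corrupted"].sum() - expected) <= 3 * se


class TestFixtureFiles:
    def test_round_trip_through_registry_io(self, default_spec, tmp_path, dictionary):
        spec = _mini_spec(default_spec, n=40)
        records, life, truth = generate_cohort(spec, seed=14)
        paths = write_fixture(records, life, truth, tmp_path, dictionary)
        back = read_procedure_table(paths["procedures"], dictionary)
        assert back.records == records
        assert not back.report.untranslated
        assert read_life_status_table(paths["life_status"]) == life
        truth2 = read_ground_truth(paths["ground_truth"])
        assert len(truth2.patients) == len(truth.patients)
        assert len(truth2.reinterventions) == len(truth.reinterventions)

    def test_empty_cohort_writes_header_only_files(self, default_spec, tmp_path, dictionary):
        spec = _mini_spec(default_spec, n=0)
        records, life, truth = generate_cohort(spec, seed=15)
        paths = write_fixture(records, life, truth, tmp_path, dictionary)
        procs = pd.read_csv(paths["procedures"])
        assert len(procs) == 0 and "patient_id" in procs.columns


class TestSpecValidation:
    def test_non_monotone_survival_rejected(self, default_spec):
        block = dataclasses.replace(
            default_spec.blocks[0], survival_targets=(0.5, 0.6, 0.4)
        )
        spec = dataclasses.replace(default_spec, blocks=(block,))
        with pytest.raises(SpecError, match="monotone"):
            generate_cohort(spec, seed=1)

    def test_bad_rate_rejected(self, default_spec):
        block = dataclasses.replace(default_spec.blocks[0], ltfu_rate=1.5)
        spec = dataclasses.replace(default_spec, blocks=(block,))
        with pytest.raises(SpecError):
            spec.validate()
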