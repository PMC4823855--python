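"""Synthetic-data generator: round-trip staging, calibration, determinism,
exact planting."""

import numpy as np
import pytest

from akicode.cohort import filter_eligible
from akicode.errors import ConfigurationError, InconsistentCountsError
from akicode.performance import TwoByTwo, build_two_by_two, performance, positive_lr
from akicode.pipeline import RunConfig, run_pipeline
from akicode.simulate import (
    CodeProfile,
    PlantSpec,
    SimulationParams,
    TimingParams,
    generate_population,
    plant_exact_dataset,
    plant_spec_from_tables,
    sample_peak_for_stage,
    stage2_feasible,
)
from akicode.staging import akin_stage


def _run(pop, params, seed=0):
    return run_pipeline(RunConfig(simulation=params, seed=seed), population=pop)


class TestPeakSampling:
    def test_round_trip_recovers_stage_always(self):
        rng = np.random.default_rng(2)
        n = 10_000
        baseline = rng.lognormal(np.log(133.0), 0.39, n)
        stage = rng.integers(0, 4, n)
        # keep stage-2 assignments inside their feasibility region
        stage[(stage == 2) & ~stage2_feasible(baseline)] = 1
        peak = sample_peak_for_stage(baseline, stage, rng)
        assert (akin_stage(baseline, peak) == stage).all()

    def test_stage0_region(self):
        rng = np.random.default_rng(0)
        peaks = np.array([sample_peak_for_stage(100.0, 0, rng) for _ in range(200)])
        assert (peaks < 126.4).all() and (peaks / 100.0 < 1.5).all()

    def test_stage2_region_for_reference_baseline(self):
        rng = np.random.default_rng(0)
        peaks = np.array([sample_peak_for_stage(100.0, 2, rng) for _ in range(200)])
        assert (peaks > 200.0).all() and (peaks <= 300.0).all()

    def test_stage3_region(self):
        rng = np.random.default_rng(0)
        peaks = np.array([sample_peak_for_stage(100.0, 3, rng) for _ in range(200)])
        assert (peaks > 300.0).all()
        # high-baseline stage 3 can proceed via the absolute clause
        p = sample_peak_for_stage(320.0, 3, rng)
        assert p > 354.0 and p - 320.0 >= 44.0

    def test_stage2_infeasible_at_high_baseline(self):
        # beyond ~177 umol/L any doubling already meets the stage-3
        # absolute criterion, so stage 2 cannot be planted
        rng = np.random.default_rng(0)
        with pytest.raises(ConfigurationError, match="stage 2"):
            sample_peak_for_stage(200.0, 2, rng)


class TestGeneratePopulation:
    def test_degenerate_prevalence_all_stage_zero(self):
        params = SimulationParams(n_patients=100, stage_prevalence=(1.0, 0.0, 0.0, 0.0), seed=4)
        pop = generate_population(params)
        bundle = _run(pop, params)
        assert (bundle.assessments["stage"] == 0).all()
        assert len(bundle.assessments) == 100

    def test_calibration_at_large_n(self):
        params = SimulationParams(n_patients=50_000, seed=12)
        pop = generate_population(params)
        bundle = _run(pop, params)
        stages = bundle.assessments["stage"].to_numpy()
        n = len(stages)
        for s, pi in enumerate(params.stage_prevalence):
            observed = (stages == s).mean()
            se = np.sqrt(pi * (1 - pi) / n)
            assert abs(observed - pi) < 3 * se, f"stage {s}: {observed} vs {pi}"
        # any-AKI share within 1 % absolute of the configured 45 %
        assert abs((stages >= 1).mean() - 0.45) < 0.01

    def test_equal_seeds_byte_identical(self):
        params = SimulationParams(n_patients=300, seed=9)
        a = generate_population(params)
        b = generate_population(params)
        for name in ("patients", "transplants", "admissions", "diagnoses", "labs"):
            assert getattr(a, name).equals(getattr(b, name)), name
            assert (
                getattr(a, name).to_csv(index=False) == getattr(b, name).to_csv(index=False)
            )

    def test_different_seeds_differ(self):
        params = SimulationParams(n_patients=300)
        a = generate_population(params, seed=1)
        b = generate_population(params, seed=2)
        assert not a.labs.equals(b.labs)

    def test_everything_generated_is_eligible(self):
        params = SimulationParams(n_patients=500, seed=3)
        pop = generate_population(params)
        eligible, exclusions = filter_eligible(
            pop.patients, pop.transplants, pop.admissions, pop.labs, params.eligibility
        )
        assert len(eligible) == len(pop.admissions)
        assert all(v == 0 for k, v in exclusions.items() if k[1:2] == "_")

    def test_multi_admission_mode(self):
        params = SimulationParams(n_patients=400, extra_admission_prob=0.5, seed=6)
        pop = generate_population(params)
        assert len(pop.admissions) > 400
        bundle = _run(pop, params)
        assert len(bundle.index_cases) == 400  # still one index case per patient

    def test_infeasible_timing_rejected(self):
        with pytest.raises(ConfigurationError, match="post-transplant"):
            SimulationParams(timing=TimingParams(transplant_gap_days=(10, 100)))
        with pytest.raises(ConfigurationError, match="baseline window"):
            SimulationParams(timing=TimingParams(baseline_offset_days=(5, 90)))

    def test_prevalence_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            SimulationParams(stage_prevalence=(0.5, 0.3, 0.1, 0.2))

    def test_profile_must_be_nested(self):
        with pytest.raises(ConfigurationError, match="nested"):
            CodeProfile(
                any_diagnosis=(0.1, 0.1, 0.1, 0.1),
                admission_diagnosis=(0.2, 0.1, 0.1, 0.1),
                main_diagnosis=(0.0, 0.0, 0.0, 0.0),
            )

    def test_roundtrip_of_written_tables(self, tmp_path):
        params = SimulationParams(n_patients=50, seed=8)
        pop = generate_population(params)
        pop.write(tmp_path)
        back = type(pop).read(tmp_path)
        assert back.seed == 8
        assert len(back.labs) == len(pop.labs)
        bundle = _run(back, params)
        assert len(bundle.assessments) == 50


class TestPlanting:
    def test_planted_counts_survive_the_pipeline_exactly(self):
        spec = PlantSpec(
            stage_counts=(288, 160, 21, 55),
            positives={
                "any_diagnosis": (8, 34, 10, 22),
                "admission_diagnosis": (6, 22, 8, 18),
                "main_diagnosis": (2, 10, 3, 10),
            },
        )
        params = SimulationParams(n_patients=spec.n_total, seed=13)
        pop = plant_exact_dataset(spec, params)
        bundle = _run(pop, params)
        t = build_two_by_two(
            bundle.assessments, bundle.code_flags, "stage_ge1", "any_diagnosis"
        )
        assert t.as_tuple() == (66, 8, 170, 280)
        t2 = build_two_by_two(
            bundle.assessments, bundle.code_flags, "stage_ge2", "any_diagnosis"
        )
        assert t2.as_tuple() == (32, 42, 44, 406)

    def test_planted_stage_ge2_lr_plus(self):
        m = performance(TwoByTwo(32, 42, 44, 406))
        assert positive_lr(m["sn"].estimate, m["sp"].estimate, "paper_rounded") == 4.5

    def test_all_negative_cohort(self):
        spec = PlantSpec(
            stage_counts=(10, 0, 0, 0),
            positives={k: (0, 0, 0, 0) for k in ("any_diagnosis", "admission_diagnosis", "main_diagnosis")},
        )
        params = SimulationParams(n_patients=10, seed=1)
        bundle = _run(plant_exact_dataset(spec, params), params)
        t = build_two_by_two(bundle.assessments, bundle.code_flags, "stage_ge1", "any_diagnosis")
        assert t.as_tuple() == (0, 0, 0, 10)
        m = performance(t)
        assert not m["sn"].defined and m["sp"].estimate == 1.0

    def test_nesting_violation_rejected(self):
        with pytest.raises(InconsistentCountsError, match="stage 1"):
            PlantSpec(
                stage_counts=(10, 10, 5, 5),
                positives={
                    "any_diagnosis": (1, 2, 1, 1),
                    "admission_diagnosis": (1, 3, 1, 1),
                    "main_diagnosis": (0, 0, 0, 0),
                },
            )

    def test_plant_spec_from_tables_rejects_conflicting_marginals(self):
        tables = {
            ("any_diagnosis", "stage_ge1"): TwoByTwo(66, 8, 170, 280),
            ("any_diagnosis", "stage_ge2"): TwoByTwo(32, 42, 44, 406),
            # code-positive total 70 here conflicts with 74 above
            ("any_diagnosis", "stage_eq3"): TwoByTwo(22, 48, 33, 421),
            ("admission_diagnosis", "stage_ge1"): TwoByTwo(48, 6, 188, 282),
            ("admission_diagnosis", "stage_ge2"): TwoByTwo(26, 28, 50, 420),
            ("admission_diagnosis", "stage_eq3"): TwoByTwo(18, 36, 37, 433),
            ("main_diagnosis", "stage_ge2"): TwoByTwo(13, 12, 63, 436),
            ("main_diagnosis", "stage_eq3"): TwoByTwo(10, 15, 45, 454),
        }
        with pytest.raises(InconsistentCountsError, match="code-positive"):
            plant_spec_from_tables(tables)

    def test_study_spec_solution(self, study_spec):
        assert study_spec.stage_counts == (288, 160, 21, 55)
        assert study_spec.positives["any_diagnosis"] == (8, 34, 10, 22)
        assert sum(study_spec.positives["main_diagnosis"]) == 25
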