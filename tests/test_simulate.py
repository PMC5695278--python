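"""Synthetic cohort generator: determinism, boundaries, calibration."""

import dataclasses
import math

import numpy as np
import pytest

from agestage import (
    DurationDistribution,
    FecundityKernel,
    SimulationConfig,
    build_schedule,
    make_cohort,
    population_parameters,
    simulate_cohort,
    summarize_cohort,
    toy_cohort,
    write_cohort,
)
from agestage.simulate import (
    LARVAL_STAGES,
    config_from_dict,
    config_to_dict,
    load_config,
    random_config,
    save_config,
)


def deterministic_config(n0=100, hatch=1.0, sex_ratio=0.5, **overrides):
    base = dict(
        label="det",
        n0=n0,
        hatch_prob=hatch,
        durations={
            "egg": DurationDistribution(5.0),
            **{st: DurationDistribution(3.0) for st in LARVAL_STAGES},
            "PrP": DurationDistribution(8.0),
        },
        completion={st: 1.0 for st in (*LARVAL_STAGES, "PrP")},
        sex_ratio=sex_ratio,
        adult_longevity={"F": DurationDistribution(10.0), "M": DurationDistribution(8.0)},
        preovip_delay=DurationDistribution(2.0),
        fecundity=FecundityKernel(peak_day=1.0, peak_height=20.0, decay=2.0),
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestDegenerateConfigs:
    def test_all_survive_deterministic_durations(self):
        cohort = simulate_cohort(deterministic_config(), seed=3)
        s = summarize_cohort(cohort)
        # egg 5 + 5 instars x 3 + PrP 8 = 28 days for everyone
        assert s.pre_adult_time.mean == 28.0
        assert s.pre_adult_time.se == 0.0 or math.isnan(s.pre_adult_time.se)
        assert all(r.preadult_days == 28 for r in cohort.individuals)
        assert s.pre_adult_survival.mean == 100.0

    def test_hatch_prob_zero_boundary(self):
        cohort = simulate_cohort(deterministic_config(hatch=0.0), seed=1)
        assert all(r.stage_history == (("egg", d),) for r in cohort.individuals
                   for d in [r.lifespan])
        s = summarize_cohort(cohort)
        assert s.hatchability.mean == 0.0
        params = population_parameters(build_schedule(cohort))
        assert not params.estimable
        assert math.isnan(params.r) and math.isnan(params.T)


class TestDeterminism:
    def test_identical_seed_identical_csv(self, tmp_path, presets):
        a = write_cohort(simulate_cohort(presets["27C"], seed=9), tmp_path / "a.csv")
        b = write_cohort(simulate_cohort(presets["27C"], seed=9), tmp_path / "b.csv")
        assert a.read_bytes() == b.read_bytes()
        c = write_cohort(simulate_cohort(presets["27C"], seed=10), tmp_path / "c.csv")
        assert a.read_bytes() != c.read_bytes()

    def test_toy_preset_is_fixed(self, presets):
        for seed in (0, 1, 99):
            assert simulate_cohort(presets["toy"], seed=seed) == make_cohort("toy", toy_cohort())


class TestPresetCalibration:
    """Preset closed-form expectations equal the published cohort summaries."""

    @pytest.mark.parametrize(
        "name, survival, fecundity",
        [("20C", 11.25, 69.95), ("25C", 72.82, 111.74),
         ("27C", 48.04, 117.48), ("30C", 34.51, 18.88)],
    )
    def test_survival_and_fecundity_targets(self, presets, name, survival, fecundity):
        cfg = presets[name]
        assert 100 * cfg.expected_preadult_survival() == pytest.approx(survival, abs=1e-6)
        assert cfg.expected_lifetime_fecundity() == pytest.approx(fecundity, rel=1e-6)

    @pytest.mark.parametrize(
        "name, R0", [("20C", 3.32), ("25C", 45.56), ("27C", 31.10), ("30C", 2.17)]
    )
    def test_closed_form_R0_matches_published(self, presets, name, R0):
        # R0 = P(female) x P(emerge) x E[lifetime eggs] reproduces the
        # published net reproduction rates to print precision
        assert presets[name].expected_R0() == pytest.approx(R0, abs=0.05)

    def test_stage_duration_means_match_published(self, presets):
        from agestage.datasets import DEVELOPMENT_TIME

        for name, temp in [("25C", 25.0), ("30C", 30.0)]:
            cfg = presets[name]
            for stage in ("egg", "L1", "L5", "PrP"):
                assert cfg.durations[stage].expected == pytest.approx(
                    DEVELOPMENT_TIME[temp][stage][0]
                )


class TestRecovery:
    def test_stage_durations_recovered_at_large_n(self, presets):
        cfg = dataclasses.replace(presets["25C"], n0=2000)
        s = summarize_cohort(simulate_cohort(cfg, seed=77))
        for stage in ("egg", "L1", "L2", "L3", "L4", "L5", "PrP"):
            m = s.stage_durations[stage]
            assert abs(m.mean - cfg.durations[stage].expected) <= 3 * m.se

    def test_survival_and_fecundity_recovered(self, presets):
        cfg = dataclasses.replace(presets["27C"], n0=2000)
        s = summarize_cohort(simulate_cohort(cfg, seed=78))
        p = cfg.expected_preadult_survival()
        se_pct = 100 * math.sqrt(p * (1 - p) / 2000)
        assert abs(s.pre_adult_survival.mean - 100 * p) <= 3 * se_pct
        assert abs(s.fecundity.mean - cfg.expected_lifetime_fecundity()) <= 3 * s.fecundity.se


class TestRandomConfigs:
    @pytest.mark.parametrize("seed", range(10))
    def test_generated_cohorts_always_valid(self, seed):
        rng = np.random.default_rng(seed)
        cfg = random_config(rng)
        cohort = simulate_cohort(cfg, seed=seed)  # validation runs in the constructor
        assert cohort.initial_count == cfg.n0
        schedule = build_schedule(cohort)
        assert np.all(np.diff(schedule.l) <= 1e-12)


def test_config_yaml_round_trip(tmp_path, presets):
    cfg = presets["25C"]
    path = save_config(cfg, tmp_path / "c.yaml")
    loaded = load_config(path)
    assert config_to_dict(loaded) == config_to_dict(cfg)
    assert simulate_cohort(loaded, seed=4) == simulate_cohort(cfg, seed=4)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="probability"):
        deterministic_config(hatch=1.5)
    with pytest.raises(ValueError, match=">= 1 day"):
        DurationDistribution(0.5)
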