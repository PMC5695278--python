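"""Age-stage schedule, Euler-Lotka solver and cohort summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agestage import (
    IndividualRecord,
    build_schedule,
    finite_rate,
    generation_time,
    make_cohort,
    population_parameters,
    solve_intrinsic_rate,
    summarize_cohort,
)
from agestage.lifetable import (
    FEMALE_ADULT,
    ReproductionAbsentError,
    curves_frame,
    euler_lotka_lhs,
    schedule_column,
)
from agestage.simulate import random_config, simulate_cohort


def grid_search_r(lxmx, lo=-5.0, hi=5.0):
    """Independent oracle: locate the Euler-Lotka root on a 1e-6 grid."""
    lxmx = np.asarray(lxmx, dtype=float)
    for step in (1e-2, 1e-4, 1e-6):
        grid = np.arange(lo, hi + step, step)
        x = np.arange(len(lxmx))
        vals = np.exp(-np.outer(grid, x + 1.0)) @ lxmx - 1.0
        i = int(np.argmin(np.abs(vals)))
        lo, hi = grid[i] - step, grid[i] + step
    return float(grid[i])


class TestHandCohort:
    """Every number checked by direct enumeration of the 3 life histories."""

    def test_survival_curve(self, hand_cohort):
        sch = build_schedule(hand_cohort)
        assert np.allclose(sch.l, [1, 1, 1, 2 / 3, 1 / 3, 1 / 3])

    def test_age_stage_entries(self, hand_cohort):
        sch = build_schedule(hand_cohort)
        assert sch.S[0, 0] == 1.0                      # all eggs at age 0
        assert sch.S[2, 1] == pytest.approx(2 / 3)     # A and B in L1 at age 2
        assert sch.S[4, FEMALE_ADULT] == pytest.approx(1 / 3)

    def test_fecundity_and_mx(self, hand_cohort):
        sch = build_schedule(hand_cohort)
        assert sch.F[4, FEMALE_ADULT] == 4.0  # B's 4 eggs / 1 female alive
        assert sch.mvec[4] == pytest.approx(4.0)
        assert sch.mvec[5] == pytest.approx(2.0)

    def test_population_parameters(self, hand_cohort):
        pp = population_parameters(build_schedule(hand_cohort))
        assert pp.R0 == pytest.approx(2.0)  # 6 eggs / 3 individuals
        assert abs(pp.solver_residual) <= 1e-12
        assert pp.lam == pytest.approx(math.exp(pp.r))
        assert pp.T == pytest.approx(math.log(pp.R0) / pp.r)
        assert pp.r == pytest.approx(grid_search_r(build_schedule(hand_cohort).lxmx), abs=2e-6)


class TestSolver:
    def test_single_reproductive_age_closed_form(self):
        # e^{-4r} * 8 = 1  =>  r = ln(8)/4
        lxmx = np.array([0.0, 0.0, 0.0, 8.0])
        r, res = solve_intrinsic_rate(lxmx)
        assert r == pytest.approx(math.log(8.0) / 4.0, abs=1e-10)
        assert abs(res) <= 1e-12

    def test_two_term_schedule_matches_grid_oracle(self):
        lxmx = np.array([0.0, 0.5, 0.0, 0.5])
        r, _ = solve_intrinsic_rate(lxmx)
        assert r == pytest.approx(grid_search_r(lxmx), abs=2e-6)

    def test_r_zero_when_R0_is_one(self):
        r, res = solve_intrinsic_rate(np.array([1.0]))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_reproduction_absent(self):
        with pytest.raises(ReproductionAbsentError):
            solve_intrinsic_rate(np.zeros(4))

    def test_residual_brackets_one(self):
        lxmx = np.array([0.0, 0.3, 0.9, 0.4])
        r, _ = solve_intrinsic_rate(lxmx, tol=1e-12)
        assert euler_lotka_lhs(r - 1e-11, lxmx) > 1.0 > euler_lotka_lhs(r + 1e-11, lxmx)

    @given(
        vals=st.lists(st.floats(0.0, 5.0), min_size=1, max_size=12),
        offset=st.integers(0, 5),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_sign_of_r_matches_sign_of_R0_minus_one(self, vals, offset):
        lxmx = np.concatenate([np.zeros(offset), np.asarray(vals)])
        R0 = lxmx.sum()
        if R0 <= 1e-6:  # root drifts beyond any practical bracket as R0 -> 0
            return
        r, res = solve_intrinsic_rate(lxmx)
        assert abs(res) <= 1e-12
        assert np.sign(r) == np.sign(R0 - 1.0) or abs(R0 - 1.0) < 1e-12


class TestScheduleProperties:
    def test_immortal_single_stage_cohort(self):
        recs = [IndividualRecord(f"E{i}", (("egg", 7),)) for i in range(5)]
        sch = build_schedule(make_cohort("c", recs))
        assert np.all(sch.S[:, 0] == 1.0)
        assert np.all(sch.l == 1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_lx_is_stage_sum_and_R0_is_egg_ratio(self, seed):
        rng = np.random.default_rng(seed)
        cohort = simulate_cohort(random_config(rng), seed=seed + 1000)
        sch = build_schedule(cohort)
        assert np.allclose(sch.S.sum(axis=1), sch.l)
        total_eggs = sum(r.total_eggs for r in cohort.individuals)
        assert sch.lxmx.sum() == pytest.approx(total_eggs / cohort.initial_count)

    @pytest.mark.parametrize("seed", range(4))
    def test_brute_force_head_count_small_cohorts(self, seed):
        rng = np.random.default_rng(100 + seed)
        cohort = simulate_cohort(random_config(rng, n0=5), seed=seed)
        sch = build_schedule(cohort)
        for x in range(sch.S.shape[0]):
            counts = np.zeros(len(sch.stage_labels))
            for rec in cohort.individuals:
                if x < rec.lifespan:
                    counts[schedule_column(rec.stage_on_day(x + 1), rec.sex)] += 1
            assert np.allclose(sch.S[x], counts / cohort.initial_count)

    def test_extending_a_life_never_decreases_lx(self, hand_cohort):
        recs = list(hand_cohort.individuals)
        for i, rec in enumerate(recs):
            if rec.individual_id == "A":  # A died in L1; let it linger longer
                hist = list(rec.stage_history)
                hist[-1] = (hist[-1][0], hist[-1][1] + 3)
                recs[i] = IndividualRecord("A", tuple(hist))
        extended = build_schedule(make_cohort("toy", recs))
        base = build_schedule(hand_cohort)
        n = len(base.l)
        assert np.all(extended.l[:n] >= base.l - 1e-12)

    def test_censored_individuals_excluded(self, hand_cohort):
        recs = list(hand_cohort.individuals) + [
            IndividualRecord("Z", (("egg", 1),), fate="censored")
        ]
        with pytest.warns(UserWarning, match="censored"):
            sch = build_schedule(make_cohort("toy", recs))
        assert sch.n0 == 3
        assert np.allclose(sch.l, build_schedule(hand_cohort).l)

    def test_curves_frame_columns(self, hand_cohort):
        frame = curves_frame(build_schedule(hand_cohort))
        assert list(frame.columns) == ["age", "lx", "fx8", "mx", "lxmx"]
        assert frame["lxmx"].sum() == pytest.approx(2.0)


class TestSummaries:
    def test_apop_tpop_definitions(self):
        # emerges on day 31 (1-based), first egg day 34: APOP 3, TPOP 33
        rec = IndividualRecord(
            "F1", (("egg", 5), ("L1", 10), ("PrP", 15), ("adult", 8)),
            sex="F", fate="survived_to_natural_death", daily_eggs={34: 2},
        )
        filler = IndividualRecord("X", (("egg", 2),))
        s = summarize_cohort(make_cohort("c", [rec, filler]))
        assert s.apop.mean == pytest.approx(3.0)
        assert s.tpop.mean == pytest.approx(33.0)
        assert s.tpop.mean == pytest.approx(s.pre_adult_time.mean + s.apop.mean)

    def test_survival_and_fecundity_accounting(self, cohort_25c):
        s = summarize_cohort(cohort_25c)
        # percentage * n0 / 100 is the integer emergence count
        assert s.pre_adult_survival.mean * s.n0 / 100 == pytest.approx(s.n_emerged)
        total_eggs = sum(r.total_eggs for r in cohort_25c.individuals)
        assert s.fecundity.mean * s.n_females == pytest.approx(total_eggs)

    def test_stage_means_use_completers_only(self):
        recs = [
            IndividualRecord("A", (("egg", 4), ("L1", 2))),      # completed egg in 4 d
            IndividualRecord("B", (("egg", 9),)),                # died as egg
            IndividualRecord("C", (("egg", 2), ("L1", 5))),      # completed egg in 2 d
        ]
        s = summarize_cohort(make_cohort("c", recs))
        assert s.stage_durations["egg"].mean == pytest.approx(3.0)
        assert s.stage_durations["egg"].n == 2
        assert s.stage_durations["L1"].n == 0  # nobody moulted out of L1
        assert s.hatchability.mean == pytest.approx(200 / 3)
        assert s.median_egg_time == pytest.approx(3.0)

    def test_empty_subgroups_not_estimable(self):
        s = summarize_cohort(make_cohort("c", [IndividualRecord("A", (("egg", 2),))]))
        assert s.n_emerged == 0
        assert math.isnan(s.fecundity.mean) and s.fecundity.n == 0
        assert math.isnan(s.tpop.mean)

    def test_merged_L56_duration(self):
        rec = IndividualRecord(
            "A",
            (("egg", 1), ("L1", 1), ("L2", 1), ("L3", 1), ("L4", 1),
             ("L5", 4), ("L6", 3), ("PrP", 2), ("adult", 1)),
            sex="M", fate="survived_to_natural_death",
        )
        s = summarize_cohort(make_cohort("c", [rec]))
        assert s.stage_durations["L5-6"].mean == pytest.approx(7.0)
        assert s.stage_durations["L5"].mean == pytest.approx(4.0)
        assert s.stage_durations["L6"].mean == pytest.approx(3.0)


def test_identities_lambda_and_T(cohort_25c):
    pp = population_parameters(build_schedule(cohort_25c))
    assert pp.lam == pytest.approx(finite_rate(pp.r), rel=1e-15)
    assert pp.T == pytest.approx(generation_time(pp.R0, pp.r), rel=1e-15)
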