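"""Age-stage, two-sex life table construction and population parameters.

The age-stage survival rate S_xj is the probability that a newly laid egg is
alive and in stage j at age x (ages in days, indexed from 0).  Stages are
indexed 1..9 in the conventional order egg, L1, L2, L3, L4, L5-6 (fifth and
facultative sixth instar merged), PrP (prepupa + pupa), female adult (j = 8),
male adult (j = 9).  From the schedule follow

    l_x = sum_j S_xj                       age-specific survival
    m_x = sum_j S_xj f_xj / l_x            age-specific fecundity

and the population parameters: the intrinsic rate of increase r solving the
Euler-Lotka equation

    sum_x exp(-r (x+1)) l_x m_x = 1,

the finite rate lambda = exp(r), the net reproduction rate R0 = sum_x l_x m_x
and the mean generation time T = ln(R0) / r.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .records import CohortData, IndividualRecord

#: Schedule stage columns; the female adult stage is j = 8 (column index 7).
SCHEDULE_STAGES: tuple[str, ...] = (
    "egg", "L1", "L2", "L3", "L4", "L5-6", "PrP", "female adult", "male adult",
)
FEMALE_ADULT = 7  # 0-based column of the female adult stage (j = 8)
MALE_ADULT = 8

_RAW_TO_COL = {"egg": 0, "L1": 1, "L2": 2, "L3": 3, "L4": 4, "L5": 5, "L6": 5, "PrP": 6}


class ReproductionAbsentError(ValueError):
    """No eggs were laid: r, lambda and T are not estimable."""


class ConvergenceError(RuntimeError):
    """The bisection solver failed to reach the requested tolerance."""


def schedule_column(record_stage: str, sex: str) -> int:
    """Map a raw record stage (and sex, for adults) to a schedule column."""
    if record_stage == "adult":
        if sex == "F":
            return FEMALE_ADULT
        if sex == "M":
            return MALE_ADULT
        raise ValueError("adult stage with undetermined sex")
    return _RAW_TO_COL[record_stage]


@dataclass
class AgeStageSchedule:
    """S_xj and f_xj matrices with the derived l_x / m_x vectors."""

    stage_labels: tuple[str, ...]
    S: np.ndarray          # (X_max+1, m) age-stage survival rates
    F: np.ndarray          # (X_max+1, m) age-stage fecundities (col 7 only)
    l: np.ndarray          # (X_max+1,) age-specific survival
    mvec: np.ndarray       # (X_max+1,) age-specific fecundity
    n0: int                # effective initial cohort size

    @property
    def lxmx(self) -> np.ndarray:
        return self.l * self.mvec

    def validate(self) -> None:
        if np.any(self.S < 0) or np.any(self.S > 1 + 1e-12):
            raise ValueError("S_xj outside [0, 1]")
        if not np.allclose(self.S.sum(axis=1), self.l):
            raise ValueError("l_x != sum_j S_xj")
        if np.any(np.diff(self.l) > 1e-12):
            raise ValueError("l_x must be non-increasing")


def _occupancy(rec: IndividualRecord) -> tuple[np.ndarray, np.ndarray]:
    """0-based ages and schedule columns occupied over this record's life."""
    cols = np.concatenate(
        [np.full(d, schedule_column(s, rec.sex), dtype=np.intp) for s, d in rec.stage_history]
    )
    ages = np.arange(len(cols), dtype=np.intp)
    return ages, cols


def build_schedule(cohort: CohortData) -> AgeStageSchedule:
    """Build the age-stage, two-sex life table of a cohort.

    S_xj is the head count alive in stage j at age x divided by the initial
    cohort size; f_x8 is the total eggs laid at age x divided by the number
    of adult females alive at age x.  Censored individuals are excluded from
    every count (with a warning).
    """
    observed = cohort.observed()
    if cohort.n_censored:
        warnings.warn(
            f"cohort {cohort.treatment_label!r}: {cohort.n_censored} censored "
            "individuals excluded from all denominators",
            UserWarning,
            stacklevel=2,
        )
    if not observed:
        raise ValueError(f"cohort {cohort.treatment_label!r}: no non-censored individuals")
    n0 = len(observed)
    xmax = max(r.lifespan for r in observed) - 1
    m = len(SCHEDULE_STAGES)
    counts = np.zeros((xmax + 1, m))
    eggs_at_age = np.zeros(xmax + 1)
    for rec in observed:
        ages, cols = _occupancy(rec)
        np.add.at(counts, (ages, cols), 1.0)
        for day, n in rec.daily_eggs.items():
            eggs_at_age[day - 1] += n

    S = counts / n0
    F = np.zeros_like(S)
    females = counts[:, FEMALE_ADULT]
    nz = females > 0
    F[nz, FEMALE_ADULT] = eggs_at_age[nz] / females[nz]

    l = S.sum(axis=1)
    mvec = np.zeros(xmax + 1)
    pos = l > 0
    mvec[pos] = (S[pos] * F[pos]).sum(axis=1) / l[pos]

    return AgeStageSchedule(
        stage_labels=SCHEDULE_STAGES, S=S, F=F, l=l, mvec=mvec, n0=n0
    )


# ---------------------------------------------------------------------------
# Euler-Lotka solver and population parameters
# ---------------------------------------------------------------------------

def euler_lotka_lhs(r: float, lxmx: np.ndarray) -> float:
    """Left-hand side of the Euler-Lotka equation at growth rate *r*."""
    x = np.arange(len(lxmx))
    return float(np.sum(np.exp(-r * (x + 1.0)) * lxmx))


def solve_intrinsic_rate(
    lxmx: np.ndarray | "AgeStageSchedule",
    tol: float = 1e-12,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Solve the Euler-Lotka equation for r by bisection.

    Accepts either a schedule or a raw l_x * m_x vector.  The left-hand side
    is strictly decreasing in r (for a non-negative, non-zero net maternity
    schedule), so the root is unique.  The initial bracket [-1, 1] is doubled
    until the residual changes sign, up to [-64, 64].

    Returns ``(r, residual)`` with ``|residual| <= tol``.
    """
    if isinstance(lxmx, AgeStageSchedule):
        lxmx = lxmx.lxmx
    lxmx = np.asarray(lxmx, dtype=float)
    if lxmx.sum() <= 0:
        raise ReproductionAbsentError("R0 = 0: the intrinsic rate of increase is undefined")

    def g(r: float) -> float:
        return euler_lotka_lhs(r, lxmx) - 1.0

    lo, hi = -1.0, 1.0
    while g(lo) < 0:  # need g(lo) > 0 (decreasing function)
        lo *= 2.0
        if lo < -64.0:
            raise ConvergenceError(f"no sign change: bracket [{lo}, {hi}]")
    while g(hi) > 0:
        hi *= 2.0
        if hi > 64.0:
            raise ConvergenceError(f"no sign change: bracket [{lo}, {hi}]")

    r = 0.5 * (lo + hi)
    res = g(r)
    for _ in range(max_iter):
        if abs(res) <= tol:
            return r, res
        if res > 0:
            lo = r
        else:
            hi = r
        r = 0.5 * (lo + hi)
        res = g(r)
    if abs(res) <= tol:
        return r, res
    raise ConvergenceError(f"bisection did not converge: bracket [{lo}, {hi}], residual {res:g}")


def finite_rate(r: float) -> float:
    """Finite (daily) rate of increase, lambda = e^r."""
    return math.exp(r)


def generation_time(R0: float, r: float) -> float:
    """Mean generation time T = ln(R0)/r (days)."""
    return math.log(R0) / r


@dataclass
class PopulationParameters:
    """r, lambda, R0 and T for one cohort; NaN where not estimable."""

    r: float
    lam: float
    R0: float
    T: float
    solver_residual: float
    estimable: bool = True

    def as_dict(self) -> dict[str, float]:
        return {"r": self.r, "lambda": self.lam, "R0": self.R0, "T": self.T}


def population_parameters(
    schedule: AgeStageSchedule, tol: float = 1e-12, max_iter: int = 200
) -> PopulationParameters:
    """Population parameters from a schedule (Euler-Lotka by bisection)."""
    lxmx = schedule.lxmx
    R0 = float(lxmx.sum())
    if R0 == 0.0:
        return PopulationParameters(
            r=math.nan, lam=math.nan, R0=0.0, T=math.nan,
            solver_residual=math.nan, estimable=False,
        )
    r, res = solve_intrinsic_rate(lxmx, tol=tol, max_iter=max_iter)
    T = generation_time(R0, r) if r != 0.0 else math.nan
    return PopulationParameters(r=r, lam=finite_rate(r), R0=R0, T=T, solver_residual=res)


# ---------------------------------------------------------------------------
# Cohort summary statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanSE:
    """Sample mean with its descriptive standard error (sd/sqrt(n))."""

    mean: float
    se: float
    n: int

    @staticmethod
    def of(values) -> "MeanSE":
        arr = np.asarray([v for v in values if v is not None], dtype=float)
        n = len(arr)
        if n == 0:
            return MeanSE(math.nan, math.nan, 0)
        se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        return MeanSE(float(arr.mean()), se, n)


@dataclass
class DemographicSummary:
    """Every per-cohort statistic of the development / reproduction tables."""

    treatment_label: str
    n0: int
    stage_durations: dict[str, MeanSE]        # egg, L1..L6, L5-6, PrP
    pre_adult_time: MeanSE                    # among emerged adults
    pre_adult_survival: MeanSE                # percent, n = n0
    hatchability: MeanSE                      # percent, n = n0
    adult_longevity: dict[str, MeanSE]        # by sex
    total_lifespan: dict[str, MeanSE]         # by sex
    tpop: MeanSE                              # ovipositing females only
    apop: MeanSE                              # ovipositing females only
    oviposition_days: MeanSE                  # all emerged females
    fecundity: MeanSE                         # eggs / emerged female (zeros included)
    median_egg_time: float
    n_emerged: int
    n_females: int


def summarize_cohort(cohort: CohortData) -> DemographicSummary:
    """Compute all development, survival, longevity and reproduction summaries.

    Stage-duration means use only individuals that completed the stage;
    pre-adult survival is emerged adults over the initial (non-censored) egg
    count; TPOP/APOP are over ovipositing females; oviposition days and
    lifetime fecundity are over all emerged females (zero-layers included).
    """
    obs = cohort.observed()
    n0 = len(obs)

    stage_durations: dict[str, MeanSE] = {}
    for stage in ("egg", "L1", "L2", "L3", "L4", "L5", "L6", "PrP"):
        stage_durations[stage] = MeanSE.of(
            r.stage_duration(stage) for r in obs if r.completed_stage(stage)
        )
    # merged fifth/sixth instar: total days spent in L5 and L6 by individuals
    # that completed the larval phase (i.e. completed L5, and L6 if present)
    merged = []
    for r in obs:
        last_larval = "L6" if r.stage_duration("L6") is not None else "L5"
        if r.completed_stage(last_larval):
            merged.append((r.stage_duration("L5") or 0) + (r.stage_duration("L6") or 0))
    stage_durations["L5-6"] = MeanSE.of(merged)

    emerged = [r for r in obs if r.emerged]
    pre_adult_time = MeanSE.of(r.preadult_days for r in emerged)
    surv_flags = [100.0 if r.emerged else 0.0 for r in obs]
    hatch_flags = [100.0 if r.hatched else 0.0 for r in obs]

    females = [r for r in emerged if r.sex == "F"]
    males = [r for r in emerged if r.sex == "M"]
    ovipositing = [r for r in females if r.daily_eggs]

    adult_longevity = {
        "F": MeanSE.of(r.stage_duration("adult") for r in females),
        "M": MeanSE.of(r.stage_duration("adult") for r in males),
    }
    total_lifespan = {
        "F": MeanSE.of(r.lifespan for r in females),
        "M": MeanSE.of(r.lifespan for r in males),
    }
    tpop = MeanSE.of(r.first_oviposition_day - 1 for r in ovipositing)
    apop = MeanSE.of(r.first_oviposition_day - r.adult_entry_day for r in ovipositing)

    egg_times = [r.stage_duration("egg") for r in obs if r.completed_stage("egg")]
    median_egg = float(np.median(egg_times)) if egg_times else math.nan

    return DemographicSummary(
        treatment_label=cohort.treatment_label,
        n0=n0,
        stage_durations=stage_durations,
        pre_adult_time=pre_adult_time,
        pre_adult_survival=MeanSE.of(surv_flags),
        hatchability=MeanSE.of(hatch_flags),
        adult_longevity=adult_longevity,
        total_lifespan=total_lifespan,
        tpop=tpop,
        apop=apop,
        oviposition_days=MeanSE.of(r.oviposition_days for r in females),
        fecundity=MeanSE.of(r.total_eggs for r in females),
        median_egg_time=median_egg,
        n_emerged=len(emerged),
        n_females=len(females),
    )


# ---------------------------------------------------------------------------
# Tidy exports for re-plotting the survival / fecundity curves
# ---------------------------------------------------------------------------

def schedule_frame(schedule: AgeStageSchedule):
    """Tidy (age, stage, Sxj, fxj) DataFrame of the full schedule."""
    import pandas as pd

    rows = []
    for x in range(schedule.S.shape[0]):
        for j, stage in enumerate(schedule.stage_labels):
            rows.append(
                {"age": x, "stage": stage,
                 "Sxj": schedule.S[x, j], "fxj": schedule.F[x, j]}
            )
    return pd.DataFrame(rows)


def curves_frame(schedule: AgeStageSchedule):
    """Tidy (age, lx, fx8, mx, lxmx) DataFrame of the derived vectors."""
    import pandas as pd

    return pd.DataFrame(
        {
            "age": np.arange(len(schedule.l)),
            "lx": schedule.l,
            "fx8": schedule.F[:, FEMALE_ADULT],
            "mx": schedule.mvec,
            "lxmx": schedule.lxmx,
        }
    )
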