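"""Bootstrap standard errors and the paired "pick 1 by 1" percentile test.

Every statistic's uncertainty is obtained by resampling whole individuals
with replacement (n0 draws per replicate) and recomputing the statistic; the
standard error is the standard deviation of the replicate values.  Two
treatments are compared by pairing replicate b of one cohort with replicate
b of the other and asking whether the 95% percentile interval of the
replicate-wise differences excludes zero.  No multiple-testing correction is
applied across the pairwise tests of a letter display.

Random streams are derived deterministically from (root seed, statistic
name, cohort label), so adding a statistic or a cohort to an analysis never
perturbs another's replicates.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .lifetable import (
    FEMALE_ADULT,
    finite_rate,
    generation_time,
    population_parameters,
    build_schedule,
    summarize_cohort,
    solve_intrinsic_rate,
)
from .records import CohortData, IndividualRecord, make_cohort

POPULATION_STATISTICS = ("r", "lambda", "R0", "T")


def derive_seed(root_seed: int, *tokens: str) -> np.random.SeedSequence:
    """Deterministic, collision-resistant stream key from a root seed."""
    keys = tuple(
        int.from_bytes(hashlib.blake2b(t.encode("utf-8"), digest_size=4).digest(), "little")
        for t in tokens
    )
    return np.random.SeedSequence(entropy=int(root_seed), spawn_key=keys)


# ---------------------------------------------------------------------------
# Compiled cohort: per-individual scalars + sparse egg events, so a replicate
# is a weighted aggregation instead of a rebuild of the record objects.
# ---------------------------------------------------------------------------

class CompiledCohort:
    """Per-individual arrays for fast bootstrap aggregation."""

    def __init__(self, cohort: CohortData):
        obs = cohort.observed()
        self.individuals = obs
        n = len(obs)
        self.n = n
        self.emerged = np.array([r.emerged for r in obs], dtype=float)
        self.hatched = np.array([r.hatched for r in obs], dtype=float)
        self.female = np.array([r.emerged and r.sex == "F" for r in obs], dtype=float)
        self.male = np.array([r.emerged and r.sex == "M" for r in obs], dtype=float)
        self.ovipositing = np.array([bool(r.daily_eggs) for r in obs], dtype=float)
        self.eggs_total = np.array([r.total_eggs for r in obs], dtype=float)
        self.lifespan = np.array([r.lifespan for r in obs], dtype=float)

        def opt(vals):
            return np.array([math.nan if v is None else float(v) for v in vals])

        self.preadult_days = opt(r.preadult_days for r in obs)
        self.adult_dur = opt(r.stage_duration("adult") for r in obs)
        self.tpop = opt(
            (r.first_oviposition_day - 1) if r.daily_eggs else None for r in obs
        )
        self.apop = opt(
            (r.first_oviposition_day - r.adult_entry_day) if r.daily_eggs else None
            for r in obs
        )
        self.ovip_days = np.array([float(r.oviposition_days) for r in obs])
        self.stage_dur: dict[str, np.ndarray] = {}
        for stage in ("egg", "L1", "L2", "L3", "L4", "L5", "L6", "PrP"):
            self.stage_dur[stage] = opt(
                r.stage_duration(stage) if r.completed_stage(stage) else None for r in obs
            )

        owners, ages0, counts = [], [], []
        for i, r in enumerate(obs):
            for day, cnt in r.daily_eggs.items():
                owners.append(i)
                ages0.append(day - 1)
                counts.append(cnt)
        self.egg_owner = np.asarray(owners, dtype=np.intp)
        self.egg_age0 = np.asarray(ages0, dtype=np.intp)
        self.egg_count = np.asarray(counts, dtype=float)
        self.max_egg_age = int(self.egg_age0.max()) if len(self.egg_age0) else -1

    def net_maternity(self, c: np.ndarray) -> np.ndarray:
        """l_x * m_x vector of the replicate with multiplicities *c*.

        Because f_x8 divides eggs by the adult-female head count and S_x8
        multiplies it back, l_x m_x at age x is simply (eggs laid at age x) /
        n0 — no survival matrix is needed for the population parameters.
        """
        if self.max_egg_age < 0:
            return np.zeros(0)
        w = self.egg_count * c[self.egg_owner]
        return np.bincount(self.egg_age0, weights=w, minlength=self.max_egg_age + 1) / self.n


def _wmean(values: np.ndarray, mask: np.ndarray, c: np.ndarray) -> float:
    den = float(np.sum(c * mask))
    if den == 0:
        return math.nan
    return float(np.nansum(c * mask * np.where(mask > 0, values, 0.0)) / den)


def _pop_params_fast(comp: CompiledCohort, c: np.ndarray) -> dict[str, float]:
    lxmx = comp.net_maternity(c)
    R0 = float(lxmx.sum())
    if R0 <= 0:
        return {"r": math.nan, "lambda": math.nan, "R0": R0, "T": math.nan}
    r, _ = solve_intrinsic_rate(lxmx)
    T = generation_time(R0, r) if r != 0.0 else math.nan
    return {"r": r, "lambda": finite_rate(r), "R0": R0, "T": T}


@dataclass(frozen=True)
class StatisticDef:
    name: str
    slow: Callable[[CohortData], float]
    fast: Callable[[CompiledCohort, np.ndarray], float]


def _registry() -> dict[str, StatisticDef]:
    defs = [
        StatisticDef(
            "preadult_survival",
            lambda co: summarize_cohort(co).pre_adult_survival.mean,
            lambda cc, c: 100.0 * float(np.sum(c * cc.emerged)) / cc.n,
        ),
        StatisticDef(
            "hatchability",
            lambda co: summarize_cohort(co).hatchability.mean,
            lambda cc, c: 100.0 * float(np.sum(c * cc.hatched)) / cc.n,
        ),
        StatisticDef(
            "fecundity",
            lambda co: summarize_cohort(co).fecundity.mean,
            lambda cc, c: _wmean(cc.eggs_total, cc.female, c),
        ),
        StatisticDef(
            "oviposition_days",
            lambda co: summarize_cohort(co).oviposition_days.mean,
            lambda cc, c: _wmean(cc.ovip_days, cc.female, c),
        ),
        StatisticDef(
            "TPOP",
            lambda co: summarize_cohort(co).tpop.mean,
            lambda cc, c: _wmean(cc.tpop, cc.ovipositing, c),
        ),
        StatisticDef(
            "APOP",
            lambda co: summarize_cohort(co).apop.mean,
            lambda cc, c: _wmean(cc.apop, cc.ovipositing, c),
        ),
        StatisticDef(
            "pre_adult_time",
            lambda co: summarize_cohort(co).pre_adult_time.mean,
            lambda cc, c: _wmean(cc.preadult_days, cc.emerged, c),
        ),
        StatisticDef(
            "female_longevity",
            lambda co: summarize_cohort(co).adult_longevity["F"].mean,
            lambda cc, c: _wmean(cc.adult_dur, cc.female, c),
        ),
        StatisticDef(
            "male_longevity",
            lambda co: summarize_cohort(co).adult_longevity["M"].mean,
            lambda cc, c: _wmean(cc.adult_dur, cc.male, c),
        ),
        StatisticDef(
            "female_lifespan",
            lambda co: summarize_cohort(co).total_lifespan["F"].mean,
            lambda cc, c: _wmean(cc.lifespan, cc.female, c),
        ),
        StatisticDef(
            "male_lifespan",
            lambda co: summarize_cohort(co).total_lifespan["M"].mean,
            lambda cc, c: _wmean(cc.lifespan, cc.male, c),
        ),
    ]
    for stage in ("egg", "L1", "L2", "L3", "L4", "L5", "L6", "PrP"):
        defs.append(
            StatisticDef(
                f"dev_time_{stage}",
                (lambda co, s=stage: summarize_cohort(co).stage_durations[s].mean),
                (lambda cc, c, s=stage: _wmean(
                    cc.stage_dur[s], np.isfinite(cc.stage_dur[s]).astype(float), c
                )),
            )
        )
    for pname in POPULATION_STATISTICS:
        defs.append(
            StatisticDef(
                pname,
                (lambda co, p=pname: _pop_param_slow(co, p)),
                (lambda cc, c, p=pname: _pop_params_fast(cc, c)[p]),
            )
        )
    return {d.name: d for d in defs}


def _pop_param_slow(cohort: CohortData, which: str) -> float:
    params = population_parameters(build_schedule(cohort))
    return {"r": params.r, "lambda": params.lam, "R0": params.R0, "T": params.T}[which]


STATISTICS: dict[str, StatisticDef] = _registry()


# ---------------------------------------------------------------------------
# Bootstrap driver
# ---------------------------------------------------------------------------

@dataclass
class BootstrapDistribution:
    """Replicate values of one statistic under one cohort's resampling."""

    statistic_name: str
    B: int
    replicates: np.ndarray  # length B; NaN marks a non-estimable replicate
    seed: int
    point_estimate: float
    high_invalid_warning: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.replicates[np.isfinite(self.replicates)]

    @property
    def n_invalid(self) -> int:
        return self.B - len(self.values)

    @property
    def SE(self) -> float:
        v = self.values
        return float(v.std(ddof=1)) if len(v) > 1 else math.nan

    @property
    def percentile_CI(self) -> tuple[float, float]:
        v = self.values
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))


def _resampled_cohort(obs: Sequence[IndividualRecord], idx: np.ndarray, label: str) -> CohortData:
    recs = [
        replace(obs[i], individual_id=f"{obs[i].individual_id}#{k}")
        for k, i in enumerate(idx)
    ]
    return make_cohort(label, recs)


def bootstrap_statistic(
    cohort: CohortData,
    statistic: str | Callable[[CohortData], float],
    B: int,
    seed: int = 0,
    name: str | None = None,
) -> BootstrapDistribution:
    """Bootstrap one scalar statistic of a cohort.

    *statistic* is either the name of a registered estimator (fast path) or
    any callable mapping a cohort to a scalar (general path).  Each replicate
    draws n0 individuals with replacement and recomputes the statistic;
    replicates where the statistic is not estimable (NaN) are dropped and
    counted.  Deterministic given (cohort, statistic name, B, seed).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if isinstance(statistic, str):
        if statistic not in STATISTICS:
            raise KeyError(f"unknown statistic {statistic!r}; registered: {sorted(STATISTICS)}")
        stat_name = statistic
        sdef = STATISTICS[statistic]
        fast, slow = sdef.fast, sdef.slow
    else:
        stat_name = name or getattr(statistic, "__name__", "custom")
        fast, slow = None, statistic

    comp = CompiledCohort(cohort)
    rng = np.random.default_rng(derive_seed(seed, stat_name, cohort.treatment_label))
    reps = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, comp.n, size=comp.n)
        if fast is not None:
            c = np.bincount(idx, minlength=comp.n).astype(float)
            reps[b] = fast(comp, c)
        else:
            try:
                reps[b] = slow(_resampled_cohort(comp.individuals, idx, cohort.treatment_label))
            except ValueError:
                reps[b] = math.nan

    dist = BootstrapDistribution(
        statistic_name=stat_name,
        B=B,
        replicates=reps,
        seed=seed,
        point_estimate=float(slow(cohort)) if fast is None else fast(comp, np.ones(comp.n)),
    )
    if dist.n_invalid == B:
        raise ValueError(f"{stat_name}: statistic not estimable in any of {B} replicates")
    if dist.n_invalid > 0.01 * B:
        dist.high_invalid_warning = True
        warnings.warn(
            f"{stat_name} ({cohort.treatment_label}): {dist.n_invalid}/{B} replicates "
            "not estimable",
            UserWarning,
            stacklevel=2,
        )
    return dist


def bootstrap_population_parameters(
    cohort: CohortData, B: int, seed: int = 0
) -> dict[str, BootstrapDistribution]:
    """Joint bootstrap of r, lambda, R0 and T from shared replicates.

    All four derive from the same resampled net-maternity schedule, so one
    replicate stream (named "population_parameters") serves the four
    statistics; their replicate values are therefore mutually consistent
    (lambda_b = exp(r_b), T_b = ln(R0_b)/r_b) within each replicate.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    comp = CompiledCohort(cohort)
    rng = np.random.default_rng(derive_seed(seed, "population_parameters", cohort.treatment_label))
    reps = {p: np.empty(B) for p in POPULATION_STATISTICS}
    for b in range(B):
        idx = rng.integers(0, comp.n, size=comp.n)
        c = np.bincount(idx, minlength=comp.n).astype(float)
        vals = _pop_params_fast(comp, c)
        for p in POPULATION_STATISTICS:
            reps[p][b] = vals[p]

    point = _pop_params_fast(comp, np.ones(comp.n))
    out = {}
    for p in POPULATION_STATISTICS:
        dist = BootstrapDistribution(
            statistic_name=p, B=B, replicates=reps[p], seed=seed, point_estimate=point[p]
        )
        if dist.n_invalid > 0.01 * B:
            dist.high_invalid_warning = True
        out[p] = dist
    return out


# ---------------------------------------------------------------------------
# Paired percentile test and compact letter display
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTestResult:
    """Pick-1-by-1 comparison of one statistic between two treatments."""

    statistic_name: str
    label_a: str
    label_b: str
    difference_point_estimate: float
    difference_CI: tuple[float, float]
    significant: bool
    n_pairs: int
    alpha: float = 0.05


def paired_difference_test(
    dist_a: BootstrapDistribution, dist_b: BootstrapDistribution,
    label_a: str = "A", label_b: str = "B",
) -> PairedTestResult:
    """Pair replicates by index, test whether the 95% CI of differences excludes 0."""
    if dist_a.B != dist_b.B:
        raise ValueError(f"unequal replicate counts: {dist_a.B} vs {dist_b.B}")
    d = dist_a.replicates - dist_b.replicates
    valid = d[np.isfinite(d)]
    if len(valid) < 100:
        raise ValueError(f"only {len(valid)} valid replicate pairs (need >= 100)")
    lo, hi = float(np.percentile(valid, 2.5)), float(np.percentile(valid, 97.5))
    return PairedTestResult(
        statistic_name=dist_a.statistic_name,
        label_a=label_a,
        label_b=label_b,
        difference_point_estimate=float(valid.mean()),
        difference_CI=(lo, hi),
        significant=not (lo <= 0.0 <= hi),
        n_pairs=len(valid),
    )


def _letters(i: int) -> str:
    out = ""
    while True:
        out = chr(ord("a") + i % 26) + out
        i = i // 26 - 1
        if i < 0:
            return out


def letter_groups(
    labels: Sequence[str],
    pairwise: Mapping[tuple[str, str], PairedTestResult],
    estimates: Mapping[str, float] | None = None,
) -> dict[str, str]:
    """Compact letter display: shared letter = not significantly different.

    Treatments are ordered by descending point estimate (supplied, or scored
    from the pairwise difference estimates), then maximal runs of mutually
    non-significant treatments become letter groups; redundant (subset)
    groups are dropped.  Intransitive patterns yield multi-letter entries.
    """
    labels = list(labels)

    def result(a: str, b: str) -> PairedTestResult:
        if (a, b) in pairwise:
            return pairwise[(a, b)]
        if (b, a) in pairwise:
            return pairwise[(b, a)]
        raise KeyError(f"missing pairwise result for ({a}, {b})")

    def sig(a: str, b: str) -> bool:
        return result(a, b).significant

    if estimates is None:
        estimates = {
            a: sum(
                (result(a, b).difference_point_estimate
                 if (a, b) in pairwise else -result(b, a).difference_point_estimate)
                for b in labels if b != a
            )
            for a in labels
        }
    order = sorted(labels, key=lambda a: (-estimates[a], a))

    groups: list[list[str]] = []
    for i in range(len(order)):
        run = [order[i]]
        for j in range(i + 1, len(order)):
            cand = order[j]
            if any(sig(cand, member) for member in run):
                break
            run.append(cand)
        if not any(set(run) <= set(g) for g in groups):
            groups.append(run)

    assignment: dict[str, str] = {a: "" for a in labels}
    for gi, grp in enumerate(groups):
        for member in grp:
            assignment[member] += _letters(gi)
    return assignment
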