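"""Individual life-history records and treatment cohorts.

The unit of observation is one insect followed daily from the day its egg
was laid until death: which developmental stage it occupied on every day of
life, its sex (known only if it emerged as an adult), and — for females —
how many eggs it laid on each adult day.  A cohort is the complete set of
such records for one treatment (here: one rearing temperature), including
the eggs that never hatched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

#: Fixed ontogenetic stage order.  PrP merges the prepupal and pupal stages;
#: L6 is a facultative extra instar (observed only at low temperature).
STAGES: tuple[str, ...] = ("egg", "L1", "L2", "L3", "L4", "L5", "L6", "PrP", "adult")
STAGE_ORDER: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

SEXES = ("F", "M", "U")
FATES = ("died", "survived_to_natural_death", "censored")


class CohortValidationError(ValueError):
    """Raised when a record or cohort violates a structural invariant."""


@dataclass(eq=True)
class IndividualRecord:
    """One insect's complete life history.

    Parameters
    ----------
    individual_id
        Unique identifier within the cohort.
    stage_history
        Ordered ``(stage, duration_in_days)`` pairs, starting at ``"egg"``
        and following the ontogenetic order.  Durations are whole days >= 1.
    sex
        ``"F"``, ``"M"``, or ``"U"`` (undetermined; only for individuals
        that died before reaching the adult stage).
    fate
        ``"died"`` (death before adulthood), ``"survived_to_natural_death"``
        (emerged and lived out its adult span), or ``"censored"``.
    daily_eggs
        Mapping from 1-based age-in-days to egg count (> 0 entries only);
        non-empty only for females, and only on adult days.
    """

    individual_id: str
    stage_history: tuple[tuple[str, int], ...]
    sex: str = "U"
    fate: str = "died"
    daily_eggs: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stage_history = tuple((s, int(d)) for s, d in self.stage_history)
        self.daily_eggs = {int(k): int(v) for k, v in self.daily_eggs.items() if int(v) != 0}
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def lifespan(self) -> int:
        """Total days alive (sum of stage durations)."""
        return sum(d for _, d in self.stage_history)

    @property
    def emerged(self) -> bool:
        """Whether the individual reached the adult stage."""
        return any(s == "adult" for s, _ in self.stage_history)

    @property
    def hatched(self) -> bool:
        """Whether the individual completed the egg stage."""
        return len(self.stage_history) > 1

    def stage_duration(self, stage: str) -> int | None:
        """Days spent in *stage*, or None if the stage was never entered."""
        for s, d in self.stage_history:
            if s == stage:
                return d
        return None

    def completed_stage(self, stage: str) -> bool:
        """True if the individual moulted out of *stage* (a later stage exists)."""
        for i, (s, _) in enumerate(self.stage_history):
            if s == stage:
                return i < len(self.stage_history) - 1
        return False

    @property
    def adult_entry_day(self) -> int | None:
        """1-based first day of adult life, or None if never emerged."""
        day = 1
        for s, d in self.stage_history:
            if s == "adult":
                return day
            day += d
        return None

    @property
    def preadult_days(self) -> int | None:
        """Days from egg to adult emergence (egg through PrP), if emerged."""
        entry = self.adult_entry_day
        return None if entry is None else entry - 1

    @property
    def total_eggs(self) -> int:
        return sum(self.daily_eggs.values())

    @property
    def first_oviposition_day(self) -> int | None:
        """1-based age at first egg laid, or None."""
        return min(self.daily_eggs) if self.daily_eggs else None

    @property
    def oviposition_days(self) -> int:
        """Number of days with at least one egg laid."""
        return len(self.daily_eggs)

    def stage_on_day(self, day: int) -> str:
        """Stage occupied on 1-based day-of-life *day*."""
        if not 1 <= day <= self.lifespan:
            raise ValueError(f"day {day} outside lifespan of {self.individual_id}")
        cum = 0
        for s, d in self.stage_history:
            cum += d
            if day <= cum:
                return s
        raise AssertionError("unreachable")

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        rid = self.individual_id
        if not self.stage_history:
            raise CohortValidationError(f"{rid}: empty stage history")
        if self.stage_history[0][0] != "egg":
            raise CohortValidationError(f"{rid}: stage history must begin with 'egg'")
        prev = -1
        for s, d in self.stage_history:
            if s not in STAGE_ORDER:
                raise CohortValidationError(f"{rid}: unknown stage {s!r}")
            if STAGE_ORDER[s] <= prev:
                raise CohortValidationError(f"{rid}: stage {s!r} out of ontogenetic order")
            prev = STAGE_ORDER[s]
            if not isinstance(d, int) or d < 1:
                raise CohortValidationError(f"{rid}: stage {s!r} has invalid duration {d!r}")
        if self.sex not in SEXES:
            raise CohortValidationError(f"{rid}: invalid sex {self.sex!r}")
        if self.fate not in FATES:
            raise CohortValidationError(f"{rid}: invalid fate {self.fate!r}")
        if (self.sex == "U") != (not self.emerged):
            raise CohortValidationError(
                f"{rid}: sex must be 'U' if and only if the adult stage was never reached"
            )
        if self.fate == "survived_to_natural_death" and not self.emerged:
            raise CohortValidationError(f"{rid}: fate 'survived_to_natural_death' requires emergence")
        if self.daily_eggs:
            if self.sex != "F":
                raise CohortValidationError(f"{rid}: eggs recorded for a non-female individual")
            entry = self.adult_entry_day
            for day, n in self.daily_eggs.items():
                if n < 0:
                    raise CohortValidationError(f"{rid}: negative egg count on day {day}")
                if not (entry <= day <= self.lifespan):
                    raise CohortValidationError(
                        f"{rid}: eggs recorded on day {day} outside the adult portion of life"
                    )


@dataclass(eq=True)
class CohortData:
    """A treatment cohort: every egg set up under one condition.

    ``initial_count`` always equals the number of records: eggs that never
    hatched are full records with a single-stage history.  Individuals are
    stored in canonical order (sorted by id) so that two cohorts containing
    the same records compare equal.
    """

    treatment_label: str
    individuals: tuple[IndividualRecord, ...]
    census_interval: int = 1

    def __post_init__(self) -> None:
        self.individuals = tuple(sorted(self.individuals, key=lambda r: r.individual_id))
        self.validate()

    @property
    def initial_count(self) -> int:
        return len(self.individuals)

    @property
    def n_censored(self) -> int:
        return sum(1 for r in self.individuals if r.fate == "censored")

    def observed(self) -> tuple[IndividualRecord, ...]:
        """Records entering every analysis denominator (censored excluded)."""
        return tuple(r for r in self.individuals if r.fate != "censored")

    def validate(self) -> None:
        if self.census_interval != 1:
            raise CohortValidationError("only a 1-day census interval is supported")
        if not self.individuals:
            raise CohortValidationError(f"cohort {self.treatment_label!r} is empty")
        seen: set[str] = set()
        for r in self.individuals:
            if r.individual_id in seen:
                raise CohortValidationError(f"duplicate individual_id {r.individual_id!r}")
            seen.add(r.individual_id)
            r.validate()


def make_cohort(label: str, individuals: Iterable[IndividualRecord]) -> CohortData:
    """Convenience constructor used throughout the tests and simulator."""
    return CohortData(treatment_label=label, individuals=tuple(individuals))
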