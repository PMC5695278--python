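"""Lossless CSV serialisation of cohorts.

Canonical long format, UTF-8, one row per individual per day of life:

    individual_id,day,stage,eggs,sex,fate

``day`` is 1-based; ``eggs`` is a non-negative integer (0 outside female
adult laying days); ``sex`` and ``fate`` are repeated on every row of an
individual.  Rows are ordered by (individual_id, day), which makes
write -> parse -> write byte-identical.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .records import (
    FATES,
    SEXES,
    STAGE_ORDER,
    CohortData,
    CohortValidationError,
    IndividualRecord,
)

HEADER = ["individual_id", "day", "stage", "eggs", "sex", "fate"]


def write_cohort(cohort: CohortData, path: str | Path) -> Path:
    """Write *cohort* to the canonical long CSV; returns the path."""
    path = Path(path)
    lines = [",".join(HEADER)]
    for rec in cohort.individuals:  # already sorted by id
        day = 1
        for stage, dur in rec.stage_history:
            for _ in range(dur):
                eggs = rec.daily_eggs.get(day, 0)
                lines.append(f"{rec.individual_id},{day},{stage},{eggs},{rec.sex},{rec.fate}")
                day += 1
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def parse_cohort(
    path: str | Path,
    strict: bool = True,
    treatment_label: str | None = None,
) -> CohortData:
    """Parse a canonical long-format cohort CSV into a validated CohortData.

    With ``strict=False``, egg counts recorded for a male or on a pre-adult
    day are dropped with a warning instead of raising.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"individual_id": str, "stage": str, "sex": str, "fate": str},
    )
    missing = [c for c in HEADER if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing columns {missing}")

    records: list[IndividualRecord] = []
    for rid, grp in df.groupby("individual_id", sort=True):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        for want, got in zip(range(1, len(days) + 1), days):
            if got != want:
                raise CohortValidationError(
                    f"individual {rid}: missing or duplicated census day {want} (found day {got})"
                )
        stages = grp["stage"].tolist()
        prev_order = -1
        history: list[tuple[str, int]] = []
        for day, stage in zip(days, stages):
            if stage not in STAGE_ORDER:
                raise CohortValidationError(f"individual {rid}: unknown stage {stage!r} on day {day}")
            order = STAGE_ORDER[stage]
            if history and stage == history[-1][0]:
                history[-1] = (stage, history[-1][1] + 1)
            elif order > prev_order:
                history.append((stage, 1))
                prev_order = order
            else:
                raise CohortValidationError(
                    f"individual {rid}: stage regression to {stage!r} on day {int(day)}"
                )
        sexes = set(grp["sex"])
        fates = set(grp["fate"])
        if len(sexes) != 1:
            raise CohortValidationError(f"individual {rid}: inconsistent sex values {sorted(sexes)}")
        if len(fates) != 1:
            raise CohortValidationError(f"individual {rid}: inconsistent fate values {sorted(fates)}")
        sex, fate = sexes.pop(), fates.pop()
        if sex not in SEXES:
            raise CohortValidationError(f"individual {rid}: invalid sex {sex!r}")
        if fate not in FATES:
            raise CohortValidationError(f"individual {rid}: invalid fate {fate!r}")

        adult_start = None
        cum = 0
        for s, d in history:
            if s == "adult":
                adult_start = cum + 1
            cum += d
        daily_eggs: dict[int, int] = {}
        for day, stage, eggs in zip(days, stages, grp["eggs"].to_numpy()):
            if eggs == 0:
                continue
            if eggs < 0:
                raise CohortValidationError(f"individual {rid}: negative egg count on day {int(day)}")
            bad = sex != "F" or adult_start is None or day < adult_start
            if bad:
                msg = f"individual {rid}: eggs recorded on day {int(day)} for a male or pre-adult day"
                if strict:
                    raise CohortValidationError(msg)
                warnings.warn(msg + " (dropped)", UserWarning, stacklevel=2)
                continue
            daily_eggs[int(day)] = int(eggs)

        records.append(
            IndividualRecord(
                individual_id=str(rid),
                stage_history=tuple(history),
                sex=sex,
                fate=fate,
                daily_eggs=daily_eggs,
            )
        )

    label = treatment_label if treatment_label is not None else path.stem
    return CohortData(treatment_label=label, individuals=tuple(records))


def write_individual_summary(cohort: CohortData, path: str | Path) -> Path:
    """Wide per-individual summary CSV for human inspection (not a parse input)."""
    from .records import STAGES

    path = Path(path)
    rows = []
    for rec in cohort.individuals:
        row: dict[str, object] = {"individual_id": rec.individual_id}
        for stage in STAGES:
            row[f"days_{stage}"] = rec.stage_duration(stage)
        row["lifespan"] = rec.lifespan
        row["sex"] = rec.sex
        row["fate"] = rec.fate
        row["total_eggs"] = rec.total_eggs
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
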