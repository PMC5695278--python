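"""Whole-analysis driver: life tables, bootstrap comparisons, report files.

`run_analysis` takes one cohort per treatment and produces a machine-readable
JSON report plus tidy CSV tables mirroring the standard presentation of a
temperature life-table study: development times, longevities, oviposition
statistics, population parameters with bootstrap SEs and letter groups, and
per-treatment schedule exports for re-plotting the survival/fecundity curves.
Outputs are deterministic given identical inputs, B and seed (no timestamps),
and nothing is written unless the whole analysis succeeds.
"""

from __future__ import annotations

import hashlib
import json
import math
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .bootstrap import (
    BootstrapDistribution,
    PairedTestResult,
    bootstrap_population_parameters,
    bootstrap_statistic,
    letter_groups,
    paired_difference_test,
    POPULATION_STATISTICS,
)
from .degree_day import fit_degree_day, fits_frame, rates_from_table, read_rates_csv
from .io import parse_cohort
from .lifetable import (
    DemographicSummary,
    MeanSE,
    build_schedule,
    curves_frame,
    population_parameters,
    schedule_frame,
    summarize_cohort,
)
from .records import CohortData

#: Statistics bootstrapped and letter-grouped by default (population
#: parameters are always added, resampled jointly).
DEFAULT_STATISTICS = (
    "preadult_survival",
    "pre_adult_time",
    "fecundity",
    "oviposition_days",
    "TPOP",
    "APOP",
    "female_longevity",
    "male_longevity",
)


def _clean(x):
    """JSON-safe scalar: non-finite floats become null."""
    if isinstance(x, float) and not math.isfinite(x):
        return None
    return x


def _meanse_dict(m: MeanSE) -> dict:
    return {"mean": _clean(m.mean), "se": _clean(m.se), "n": m.n}


def _summary_dict(s: DemographicSummary) -> dict:
    return {
        "n0": s.n0,
        "n_emerged": s.n_emerged,
        "n_females": s.n_females,
        "stage_durations": {k: _meanse_dict(v) for k, v in s.stage_durations.items()},
        "pre_adult_time": _meanse_dict(s.pre_adult_time),
        "pre_adult_survival": _meanse_dict(s.pre_adult_survival),
        "hatchability": _meanse_dict(s.hatchability),
        "adult_longevity": {k: _meanse_dict(v) for k, v in s.adult_longevity.items()},
        "total_lifespan": {k: _meanse_dict(v) for k, v in s.total_lifespan.items()},
        "TPOP": _meanse_dict(s.tpop),
        "APOP": _meanse_dict(s.apop),
        "oviposition_days": _meanse_dict(s.oviposition_days),
        "fecundity": _meanse_dict(s.fecundity),
        "median_egg_time": _clean(s.median_egg_time),
    }


def _dist_dict(d: BootstrapDistribution) -> dict:
    ci = d.percentile_CI
    return {
        "point": _clean(d.point_estimate),
        "SE": _clean(d.SE),
        "CI95": [_clean(ci[0]), _clean(ci[1])],
        "B": d.B,
        "n_invalid": d.n_invalid,
        "seed": d.seed,
        "high_invalid_warning": d.high_invalid_warning,
    }


def _pair_dict(p: PairedTestResult) -> dict:
    return {
        "a": p.label_a,
        "b": p.label_b,
        "difference": _clean(p.difference_point_estimate),
        "CI95": [_clean(p.difference_CI[0]), _clean(p.difference_CI[1])],
        "significant": p.significant,
        "n_pairs": p.n_pairs,
        "alpha": p.alpha,
    }


@dataclass
class AnalysisReport:
    """In-memory analysis result; `write` materialises the report files."""

    report: dict
    tables: dict[str, pd.DataFrame]
    replicates: dict[str, pd.DataFrame]

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.parent.mkdir(parents=True, exist_ok=True)
        staging = Path(tempfile.mkdtemp(prefix=".agestage-", dir=out_dir.parent))
        try:
            (staging / "report.json").write_text(
                json.dumps(self.report, sort_keys=True, indent=2) + "\n", encoding="utf-8"
            )
            for name, df in self.tables.items():
                df.to_csv(staging / f"{name}.csv", index=False)
            for name, df in self.replicates.items():
                df.to_csv(staging / f"replicates_{name}.csv", index=False)
            out_dir.mkdir(parents=True, exist_ok=True)
            for f in sorted(staging.iterdir()):
                shutil.move(str(f), str(out_dir / f.name))
        finally:
            shutil.rmtree(staging, ignore_errors=True)
        return out_dir


def run_analysis(
    inputs: Sequence[str | Path | CohortData],
    B: int = 100_000,
    seed: int = 0,
    out_dir: str | Path | None = None,
    strict: bool = True,
    dump_replicates: bool = False,
    statistics: Sequence[str] = DEFAULT_STATISTICS,
) -> AnalysisReport:
    """Full multi-treatment analysis; optionally writes the report files.

    All cohorts are parsed and validated up front, so an invalid input aborts
    before anything is written.
    """
    cohorts: list[CohortData] = []
    provenance_inputs: dict[str, str | None] = {}
    for item in inputs:
        if isinstance(item, CohortData):
            cohorts.append(item)
            provenance_inputs[item.treatment_label] = None
        else:
            path = Path(item)
            cohort = parse_cohort(path, strict=strict)
            cohorts.append(cohort)
            provenance_inputs[cohort.treatment_label] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    if not cohorts:
        raise ValueError("no input cohorts")
    labels = [c.treatment_label for c in cohorts]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate treatment labels: {labels}")

    summaries: dict[str, DemographicSummary] = {}
    dists: dict[str, dict[str, BootstrapDistribution]] = {lab: {} for lab in labels}
    cohort_json: dict[str, dict] = {}
    tables: dict[str, pd.DataFrame] = {}
    replicates: dict[str, pd.DataFrame] = {}

    for cohort in cohorts:
        lab = cohort.treatment_label
        summary = summarize_cohort(cohort)
        summaries[lab] = summary
        schedule = build_schedule(cohort)
        params = population_parameters(schedule)
        for stat in statistics:
            try:
                dists[lab][stat] = bootstrap_statistic(cohort, stat, B=B, seed=seed)
            except ValueError:
                # statistic never estimable for this cohort (e.g. no males):
                # reported as absent rather than aborting the whole analysis
                continue
        dists[lab].update(bootstrap_population_parameters(cohort, B=B, seed=seed))
        cohort_json[lab] = {
            "summary": _summary_dict(summary),
            "population_parameters": {
                k: _clean(v) for k, v in params.as_dict().items()
            } | {"solver_residual": _clean(params.solver_residual), "estimable": params.estimable},
            "bootstrap": {k: _dist_dict(d) for k, d in sorted(dists[lab].items())},
        }
        tables[f"schedule_{lab}"] = schedule_frame(schedule)
        tables[f"curves_{lab}"] = curves_frame(schedule)
        if dump_replicates:
            for stat, d in sorted(dists[lab].items()):
                replicates[f"{lab}_{stat}"] = pd.DataFrame({stat: d.replicates})

    all_stats = list(statistics) + list(POPULATION_STATISTICS)
    comparisons: dict[str, dict] = {}
    if len(labels) > 1:
        for stat in all_stats:
            if any(stat not in dists[lab] for lab in labels):
                continue
            pairwise: dict[tuple[str, str], PairedTestResult] = {}
            ok = True
            for i, a in enumerate(labels):
                for b in labels[i + 1:]:
                    try:
                        pairwise[(a, b)] = paired_difference_test(
                            dists[a][stat], dists[b][stat], label_a=a, label_b=b
                        )
                    except ValueError:
                        ok = False
            if not ok or not pairwise:
                continue
            estimates = {lab: dists[lab][stat].point_estimate for lab in labels}
            finite = {k: (v if math.isfinite(v) else -math.inf) for k, v in estimates.items()}
            letters = letter_groups(labels, pairwise, estimates=finite)
            comparisons[stat] = {
                "letters": letters,
                "pairs": [_pair_dict(p) for _, p in sorted(pairwise.items())],
            }

    tables.update(_summary_tables(labels, summaries, dists, comparisons))

    report = {
        "schema_version": 1,
        "provenance": {
            "package_version": __version__,
            "B": B,
            "seed": seed,
            "inputs": provenance_inputs,
            "statistics": sorted(all_stats),
            "multiple_testing_correction": "none",
        },
        "cohorts": cohort_json,
        "comparisons": comparisons,
    }
    result = AnalysisReport(report=report, tables=tables, replicates=replicates)
    if out_dir is not None:
        result.write(out_dir)
    return result


def _summary_tables(labels, summaries, dists, comparisons) -> dict[str, pd.DataFrame]:
    """Tidy per-statistic tables with bootstrap SEs and letter groups."""
    def letter(stat, lab):
        return comparisons.get(stat, {}).get("letters", {}).get(lab, "")

    dev_rows = []
    for lab in labels:
        s = summaries[lab]
        for stage, m in s.stage_durations.items():
            dev_rows.append(
                {"treatment": lab, "stage": stage, "mean": m.mean, "se": m.se, "n": m.n}
            )
        dev_rows.append(
            {"treatment": lab, "stage": "preadult", "mean": s.pre_adult_time.mean,
             "se": s.pre_adult_time.se, "n": s.pre_adult_time.n}
        )
    tables = {"development_times": pd.DataFrame(dev_rows)}

    stat_rows = []
    for stat in ("preadult_survival", "pre_adult_time", "fecundity", "oviposition_days",
                 "TPOP", "APOP", "female_longevity", "male_longevity"):
        for lab in labels:
            if stat not in dists[lab]:
                continue
            d = dists[lab][stat]
            stat_rows.append(
                {"statistic": stat, "treatment": lab, "estimate": d.point_estimate,
                 "bootstrap_SE": d.SE, "letters": letter(stat, lab)}
            )
    tables["summary_statistics"] = pd.DataFrame(stat_rows)

    pop_rows = []
    for lab in labels:
        row: dict[str, object] = {"treatment": lab}
        for p in POPULATION_STATISTICS:
            d = dists[lab][p]
            row[p] = d.point_estimate
            row[f"{p}_SE"] = d.SE
            row[f"{p}_letters"] = letter(p, lab)
        pop_rows.append(row)
    tables["population_parameters"] = pd.DataFrame(pop_rows)
    return tables


def run_degree_day(
    rates: str | Path | Mapping[float, Mapping[str, float]],
    temps: Sequence[float],
    out: str | Path | None = None,
    stages: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fit the degree-day model per stage over the chosen temperature range."""
    table = read_rates_csv(rates) if isinstance(rates, (str, Path)) else rates
    if stages is None:
        stages = sorted({s for per_temp in table.values() for s in per_temp})
    fits = [fit_degree_day(rates_from_table(table, stage, list(temps))) for stage in stages]
    frame = fits_frame(fits)
    if out is not None:
        frame.to_csv(out, index=False)
    return frame
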