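"""Linear degree-day model: developmental thresholds and thermal constants.

Mean development rates y = 1/(mean development time) are regressed on
rearing temperature x over the analyst-chosen linear range:

    y = a + b x                     (ordinary least squares)

from which the lower developmental threshold t = -a/b (°C, the temperature
at which the fitted rate extrapolates to zero) and the thermal constant
K = 1/b (degree-days above t needed to complete the stage) follow, with
standard errors propagated by the delta method:

    SE_t = (ybar/b) * sqrt( s^2 / (N ybar^2) + (SE_b / b)^2 )
    SE_K = SE_b / b^2

where s^2 is the residual mean square of y, ybar the sample mean rate and N
the number of temperatures fitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lifetable import DemographicSummary


class DegreeDayError(ValueError):
    """Raised for unusable rate series or non-physical fits."""


class NonlinearRangeWarning(UserWarning):
    """The fitted temperature range extends past the rate optimum."""


@dataclass(frozen=True)
class RateSeries:
    """Mean development rates of one stage across temperatures."""

    stage_label: str
    temperatures: tuple[float, ...]   # °C, strictly increasing
    dev_times: tuple[float, ...]      # mean days per temperature

    def __post_init__(self) -> None:
        if len(self.temperatures) != len(self.dev_times):
            raise DegreeDayError("temperatures and dev_times differ in length")
        if any(b <= a for a, b in zip(self.temperatures, self.temperatures[1:])):
            raise DegreeDayError("temperatures must be strictly increasing")
        if any(d <= 0 for d in self.dev_times):
            raise DegreeDayError("development times must be positive")

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(1.0 / d for d in self.dev_times)

    @property
    def N(self) -> int:
        return len(self.temperatures)


@dataclass(frozen=True)
class DegreeDayFit:
    """OLS fit of the rate-temperature line with derived t and K."""

    stage_label: str
    a: float          # intercept, day^-1
    b: float          # slope, day^-1 °C^-1
    SE_b: float
    s2: float         # residual mean square of y
    y_bar: float
    R2: float
    t: float          # lower developmental threshold, °C
    K: float          # thermal constant, degree-days
    SE_t: float
    SE_K: float
    N: int
    temperatures: tuple[float, ...]


def fit_degree_day(series: RateSeries) -> DegreeDayFit:
    """Fit the linear rate model and derive t, K and their standard errors."""
    if series.N < 3:
        raise DegreeDayError(
            f"{series.stage_label}: need at least 3 temperatures, got {series.N}"
        )
    x = np.asarray(series.temperatures, dtype=float)
    y = np.asarray(series.rates, dtype=float)

    if int(np.argmax(y)) != len(y) - 1:
        warnings.warn(
            f"{series.stage_label}: maximum rate at an interior temperature "
            f"({x[np.argmax(y)]:g}°C) — the fitted range extends past the optimum",
            NonlinearRangeWarning,
            stacklevel=2,
        )

    res = stats.linregress(x, y)
    a, b = float(res.intercept), float(res.slope)
    if b <= 0:
        raise DegreeDayError(
            f"{series.stage_label}: non-positive slope {b:g} gives no physical threshold"
        )
    n = series.N
    yhat = a + b * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    s2 = ss_res / (n - 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    se_b = float(res.stderr)
    y_bar = float(y.mean())

    t = -a / b
    K = 1.0 / b
    se_k = se_b / b**2
    se_t = (y_bar / b) * math.sqrt(s2 / (n * y_bar**2) + (se_b / b) ** 2)

    return DegreeDayFit(
        stage_label=series.stage_label,
        a=a, b=b, SE_b=se_b, s2=s2, y_bar=y_bar, R2=r2,
        t=t, K=K, SE_t=se_t, SE_K=se_k,
        N=n, temperatures=series.temperatures,
    )


def threshold_from_coefficients(a: float, b: float) -> tuple[float, float]:
    """Closed forms t = -a/b and K = 1/b from published regression coefficients."""
    if b <= 0:
        raise DegreeDayError(f"non-positive slope {b:g} gives no physical threshold")
    return -a / b, 1.0 / b


_SUMMARY_STAGES = {"preadult": "pre_adult_time"}


def _stage_dev_time(summary: DemographicSummary, stage: str) -> float:
    if stage in _SUMMARY_STAGES:
        return getattr(summary, _SUMMARY_STAGES[stage]).mean
    if stage == "larva":
        # total larval phase: pre-adult time minus egg and prepupal-pupal time
        return (
            summary.pre_adult_time.mean
            - summary.stage_durations["egg"].mean
            - summary.stage_durations["PrP"].mean
        )
    if stage not in summary.stage_durations:
        raise DegreeDayError(f"unknown stage {stage!r}")
    return summary.stage_durations[stage].mean


def rates_from_summaries(
    summaries: Mapping[float, DemographicSummary],
    stage: str,
    temps: Sequence[float],
) -> RateSeries:
    """Rate series for *stage* restricted to the analyst-chosen temperatures.

    The linear range is an explicit choice, never auto-selected; *temps* is
    recorded on the series (and the fit) as provenance.
    """
    dev_times = []
    for tmp in temps:
        if tmp not in summaries:
            raise DegreeDayError(f"no summary available for temperature {tmp}°C")
        d = _stage_dev_time(summaries[tmp], stage)
        if not math.isfinite(d):
            raise DegreeDayError(f"{stage}: development time not estimable at {tmp}°C")
        dev_times.append(d)
    order = np.argsort(temps)
    return RateSeries(
        stage_label=stage,
        temperatures=tuple(float(temps[i]) for i in order),
        dev_times=tuple(dev_times[i] for i in order),
    )


def rates_from_table(
    table: Mapping[float, Mapping[str, float]], stage: str, temps: Sequence[float]
) -> RateSeries:
    """Rate series from a {temperature: {stage: mean days}} table."""
    dev_times = []
    for tmp in temps:
        if tmp not in table or stage not in table[tmp]:
            raise DegreeDayError(f"no mean development time for {stage!r} at {tmp}°C")
        dev_times.append(float(table[tmp][stage]))
    order = np.argsort(temps)
    return RateSeries(
        stage_label=stage,
        temperatures=tuple(float(temps[i]) for i in order),
        dev_times=tuple(dev_times[i] for i in order),
    )


def read_rates_csv(path: str | Path) -> dict[float, dict[str, float]]:
    """Read a `stage,temperature,mean_dev_time` CSV into a nested table."""
    df = pd.read_csv(path)
    needed = {"stage", "temperature", "mean_dev_time"}
    if not needed <= set(df.columns):
        raise DegreeDayError(f"{path}: expected columns {sorted(needed)}")
    if df.empty:
        raise DegreeDayError(f"{path}: no rate rows")
    table: dict[float, dict[str, float]] = {}
    for _, row in df.iterrows():
        table.setdefault(float(row["temperature"]), {})[str(row["stage"])] = float(
            row["mean_dev_time"]
        )
    return table


def fits_frame(fits: Sequence[DegreeDayFit]) -> pd.DataFrame:
    """Threshold/thermal-constant table (one row per stage)."""
    return pd.DataFrame(
        [
            {
                "stage": f.stage_label,
                "a": f.a,
                "b": f.b,
                "R2": f.R2,
                "t": f.t,
                "SE_t": f.SE_t,
                "K": f.K,
                "SE_K": f.SE_K,
                "N": f.N,
                "temperatures": ";".join(f"{x:g}" for x in f.temperatures),
            }
            for f in fits
        ]
    )
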