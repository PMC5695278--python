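"""Published summary tables bundled as example inputs and cross-checks.

Values are from a constant-temperature rearing study of the rice leaffolder
*Marasmia exigua* (Lepidoptera: Pyralidae), the system the simulator presets
emulate: stage-specific development times, pre-adult survival, adult
longevity, oviposition statistics, life-table population parameters, and the
published degree-day regressions.  Only summary statistics were published —
no individual-level records — which is why the synthetic-cohort generator,
not a data loader, feeds the end-to-end pipeline.
"""

from __future__ import annotations

#: Egg hatchability (%) by rearing temperature (°C).
HATCHABILITY: dict[float, float] = {
    10.0: 0.0, 15.0: 50.60, 20.0: 74.12, 25.0: 96.89, 27.0: 94.09, 30.0: 89.08, 35.0: 7.91,
}

#: Mean stage development times in days, {temperature: {stage: (mean, SE, n)}}.
DEVELOPMENT_TIME: dict[float, dict[str, tuple[float, float, int]]] = {
    20.0: {
        "egg": (8.26, 0.04, 300), "L1": (8.10, 0.12, 104), "L2": (7.75, 0.17, 61),
        "L3": (5.79, 0.25, 58), "L4": (5.10, 0.14, 58), "L5": (6.63, 0.28, 32),
        "L6": (6.92, 0.25, 18), "PrP": (16.89, 0.30, 45), "preadult": (61.58, 0.51, 45),
    },
    25.0: {
        "egg": (4.91, 0.03, 100), "L1": (3.59, 0.07, 94), "L2": (2.68, 0.07, 94),
        "L3": (2.86, 0.07, 93), "L4": (3.01, 0.08, 93), "L5": (5.07, 0.11, 89),
        "PrP": (9.57, 0.06, 75), "preadult": (31.63, 0.18, 75),
    },
    27.0: {
        "egg": (4.49, 0.05, 96), "L1": (3.56, 0.08, 88), "L2": (2.33, 0.07, 87),
        "L3": (3.45, 0.08, 85), "L4": (3.15, 0.07, 79), "L5": (5.38, 0.11, 64),
        "PrP": (8.12, 0.06, 49), "preadult": (30.35, 0.26, 49),
    },
    30.0: {
        "egg": (5.00, 0.04, 200), "L1": (3.39, 0.05, 176), "L2": (3.13, 0.07, 166),
        "L3": (3.36, 0.09, 160), "L4": (2.49, 0.06, 148), "L5": (4.44, 0.11, 118),
        "PrP": (7.46, 0.07, 78), "preadult": (28.94, 0.19, 78),
    },
}

#: Pre-adult survival: {temperature: (emerged adults, initial eggs, printed %)}.
PREADULT_SURVIVAL: dict[float, tuple[int, int, float]] = {
    20.0: (45, 400, 11.25),
    25.0: (75, 103, 72.82),
    27.0: (49, 102, 48.04),
    30.0: (78, 226, 34.51),
}

#: Printed bootstrap SEs of the pre-adult survival percentages.
PREADULT_SURVIVAL_SE: dict[float, float] = {20.0: 1.57, 25.0: 4.36, 27.0: 4.95, 30.0: 3.16}

#: Adult longevity and total lifespan (days), {temperature: {key: (mean, SE, n)}}.
LONGEVITY: dict[float, dict[str, tuple[float, float, int]]] = {
    20.0: {"female_longevity": (19.42, 1.70, 19), "male_longevity": (20.31, 1.14, 26),
           "female_lifespan": (79.53, 2.33, 19), "male_lifespan": (82.96, 1.34, 26)},
    25.0: {"female_longevity": (12.45, 0.86, 42), "male_longevity": (13.09, 0.91, 33),
           "female_lifespan": (44.62, 0.84, 42), "male_lifespan": (44.03, 1.02, 33)},
    27.0: {"female_longevity": (8.56, 0.60, 27), "male_longevity": (9.50, 0.87, 22),
           "female_lifespan": (38.81, 0.65, 27), "male_lifespan": (39.95, 1.09, 22)},
    30.0: {"female_longevity": (10.85, 0.64, 26), "male_longevity": (8.73, 0.61, 52),
           "female_lifespan": (40.77, 0.65, 26), "male_lifespan": (37.17, 0.65, 52)},
}

#: Oviposition statistics, {temperature: {key: (mean, SE, n)}}.
OVIPOSITION: dict[float, dict[str, tuple[float, float, int]]] = {
    20.0: {"TPOP": (68.25, 2.55, 12), "APOP": (8.42, 1.85, 12),
           "oviposition_days": (6.50, 1.27, 19), "fecundity": (69.95, 22.24, 19)},
    25.0: {"TPOP": (37.41, 0.50, 34), "APOP": (5.26, 0.46, 34),
           "oviposition_days": (6.44, 0.61, 42), "fecundity": (111.74, 13.02, 42)},
    27.0: {"TPOP": (33.19, 0.44, 21), "APOP": (2.81, 0.31, 21),
           "oviposition_days": (4.71, 0.57, 27), "fecundity": (117.48, 17.41, 27)},
    30.0: {"TPOP": (36.10, 0.88, 10), "APOP": (6.50, 0.86, 10),
           "oviposition_days": (2.60, 0.45, 26), "fecundity": (18.88, 8.58, 26)},
}

#: Life-table population parameters, {temperature: {name: (estimate, SE)}}.
POPULATION_PARAMETERS: dict[float, dict[str, tuple[float, float]]] = {
    20.0: {"r": (0.017, 0.006), "lambda": (1.017, 0.006), "R0": (3.32, 1.27), "T": (70.65, 2.25)},
    25.0: {"r": (0.094, 0.005), "lambda": (1.098, 0.005), "R0": (45.56, 7.57), "T": (40.67, 0.65)},
    27.0: {"r": (0.096, 0.007), "lambda": (1.101, 0.007), "R0": (31.10, 6.85), "T": (35.78, 0.56)},
    30.0: {"r": (0.020, 0.015), "lambda": (1.020, 0.016), "R0": (2.17, 1.05), "T": (38.41, 1.65)},
}

#: Published degree-day regressions (fitted over 20-27°C), per stage:
#: intercept a, slope b, R², threshold t ± SE (°C), thermal constant K ± SE (DD).
REGRESSION_COEFFICIENTS: dict[str, dict[str, float]] = {
    "egg":      {"a": -0.183, "b": 0.015, "R2": 0.952, "t": 12.20, "SE_t": 0.12, "K": 66.67, "SE_K": 0.78},
    "larva":    {"a": -0.064, "b": 0.005, "R2": 0.815, "t": 12.80, "SE_t": 0.29, "K": 200.00, "SE_K": 6.04},
    "PrP":      {"a": -0.131, "b": 0.009, "R2": 0.967, "t": 14.56, "SE_t": 0.15, "K": 111.11, "SE_K": 1.57},
    "preadult": {"a": -0.034, "b": 0.003, "R2": 0.904, "t": 11.33, "SE_t": 0.48, "K": 333.33, "SE_K": 7.22},
}


def degree_day_input_table() -> dict[float, dict[str, float]]:
    """Mean development times per stage for the degree-day fits.

    The total larval time is not tabulated directly; it is derived as
    pre-adult time minus egg and PrP times at each temperature.
    """
    table: dict[float, dict[str, float]] = {}
    for temp, stages in DEVELOPMENT_TIME.items():
        egg = stages["egg"][0]
        prp = stages["PrP"][0]
        pre = stages["preadult"][0]
        table[temp] = {
            "egg": egg,
            "larva": round(pre - egg - prp, 2),
            "PrP": prp,
            "preadult": pre,
        }
    return table
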