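# agestage

Age-stage, two-sex life table analysis for daily-census rearing cohorts,
with bootstrap inference and a linear degree-day phenology model.

## The problem

Laboratory demography of an insect population follows every individual of a
cohort — every egg set up — daily from oviposition to death: which stage it
occupies each day, its sex once it emerges, and (for females) daily egg
counts. Classical female-only, age-indexed life tables discard the males,
the immature stages and the between-individual variation in developmental
rate. The age-stage, two-sex framework keeps all of it: survival is tracked
jointly by age *x* (days, from 0) and stage *j*, with stages indexed
egg = 1, L1–L4 = 2–5, L5-6 = 6 (fifth and facultative sixth instar merged),
PrP = 7 (prepupa + pupa), female adult = 8, male adult = 9.

From the age-stage survival rates *S*<sub>xj</sub> (probability a newly laid
egg is alive in stage *j* at age *x*) and the age-stage fecundities
*f*<sub>x8</sub> (mean daily eggs per female adult of age *x*):

- age-specific survival  *l*<sub>x</sub> = Σ<sub>j</sub> *S*<sub>xj</sub>
- age-specific fecundity  *m*<sub>x</sub> = Σ<sub>j</sub> *S*<sub>xj</sub>*f*<sub>xj</sub> / *l*<sub>x</sub>
- intrinsic rate of increase *r* solving the Euler–Lotka equation
  Σ<sub>x</sub> e<sup>−r(x+1)</sup> *l*<sub>x</sub>*m*<sub>x</sub> = 1
  (iterative bisection; the left side is strictly decreasing in *r*)
- finite rate of increase λ = e<sup>r</sup>, net reproduction rate
  *R*<sub>0</sub> = Σ<sub>x</sub> *l*<sub>x</sub>*m*<sub>x</sub>, mean
  generation time *T* = ln *R*<sub>0</sub> / *r*.

Standard errors come from bootstrapping whole individuals (n₀ draws with
replacement per replicate), and treatments are compared with the paired
"pick 1 by 1" test: replicate *b* of one cohort minus replicate *b* of the
other, judged by the 95% percentile interval of the differences, summarised
as compact letter displays. Stage-specific lower developmental thresholds
*t* = −a/b and thermal constants *K* = 1/b (degree-days) come from an OLS
fit of mean development rate on temperature, with delta-method standard
errors.

Because studies of this kind publish summary tables but rarely the raw
rearing records, the package includes a seeded synthetic-cohort generator
whose presets are calibrated so their closed-form expectations equal the
published summaries for the rice leaffolder *Marasmia exigua* at 20, 25, 27
and 30 °C (`agestage.datasets` bundles those tables).

## Worked example

Three hand-traceable individuals: A dies as a first instar after 4 days of
life, B is a female (egg 2 d, L1 1 d, PrP 1 d, adult 2 d) laying 4 then 2
eggs, C dies as an egg after 3 days.

```python
from agestage import build_schedule, make_cohort, population_parameters, toy_cohort

cohort = make_cohort("toy", toy_cohort())
schedule = build_schedule(cohort)
print(schedule.l)                # [1. 1. 1. 0.6667 0.3333 0.3333]
print(schedule.F[4, 7])          # 4.0   (B's 4 eggs / 1 female alive at age 4)
p = population_parameters(schedule)
print(round(p.R0, 3), round(p.r, 4), round(p.lam, 4), round(p.T, 2))
# 2.0 0.1303 1.1392 5.32
```

*l*₃ = 2/3 because C (lifespan 3 d) is dead at age 3 while A and B survive;
*R*₀ = 2 is the 6 eggs laid divided by the 3 initial individuals; *r* solves
e^(−5r)·(4/3) + e^(−6r)·(2/3) = 1.

The same pipeline at study scale, via the numbered drivers:

```sh
python analysis/01_simulate_cohorts.py     # four cohorts at n0 = 400/103/102/226
python analysis/02_life_tables.py          # schedules + population parameters
python analysis/03_bootstrap_comparisons.py
python analysis/04_degree_day_model.py
```

`03` prints, for example (B = 2,000, seed = 1):

```
treatment     r  r_SE r_letters     R0  R0_SE R0_letters      T  T_SE T_letters
      20C 0.020 0.003         b  4.278  0.933          c 72.868 2.147         a
      25C 0.102 0.005         a 51.864  7.320          a 38.687 1.024         b
      27C 0.094 0.008         a 21.961  4.548          b 32.861 1.230         c
      30C 0.015 0.007         b  1.765  0.424          d 37.251 1.361         b
```

i.e. growth is fastest and statistically indistinguishable at 25–27 °C,
marginal at 20 and 30 °C, and generation time is longest in the cold —
the qualitative structure of the published study.

A CLI wraps the same operations: `agestage simulate 25C --seed 1 --out c.csv`,
`agestage analyze c.csv -B 100000 --seed 1 --out report/`,
`agestage ddmodel rates.csv --temps 20,25,27 --out dd.csv`,
`agestage compare a.csv b.csv --statistic R0`.

## Layout

- `src/agestage/` — library: `records`/`io` (cohort model + CSV round-trip),
  `lifetable` (schedule, Euler–Lotka, summaries), `bootstrap` (SEs, paired
  test, letters), `degree_day`, `simulate` (generator + presets),
  `datasets` (bundled published tables), `report`, `cli`.
- `analysis/` — numbered narrative drivers writing under `results/`.
- `docs/methods.md` — model assumptions, estimator definitions, numerical
  choices and known limitations.
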