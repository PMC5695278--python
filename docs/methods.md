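# Methods

## Data model

The unit of observation is an individual followed under a fixed 1-day
census from the day its egg was laid until death. A record is a stage
history (ordered `(stage, duration)` pairs along the fixed ontogeny
egg → L1…L5 → optional L6 → PrP → adult), a sex (`F`/`M`, or `U` exactly
when the adult stage was never reached), a fate, and a map of 1-based
age-in-days to egg counts (females, adult days only). A cohort is *every*
egg set up under one treatment, so eggs that never hatched are full records
and the initial count n₀ is always the denominator of pre-adult survival.
Files use a long CSV (one row per individual per day) with deterministic row
order, so `write ∘ parse` and `parse ∘ write` are identities; a `censored`
fate is representable but censored individuals are excluded from every
denominator with a warning (the analyses here assume no losses other than
death).

Ages are 1-based in files (day 1 = day of oviposition) and 0-based
internally, so the Euler–Lotka exponent is x + 1 with x indexed from 0.

## Life table

S_xj is a head count: the fraction of the n₀ individuals alive and in
schedule stage j at age x, with stage columns egg, L1–L4, L5-6 (fifth and
facultative sixth instar merged; the raw records keep them separate), PrP,
female adult (j = 8), male adult (j = 9). f_x8 divides the eggs laid at age
x by the number of adult females alive at age x; l_x = Σ_j S_xj and
m_x = Σ_j S_xj f_xj / l_x (defined as 0 where l_x = 0 — the convention is
inert, since those ages contribute nothing to any sum). Two consequences
used as test oracles: l_x m_x equals (eggs laid at age x)/n₀, and therefore
R₀ = Σ l_x m_x equals total eggs / n₀ exactly.

The intrinsic rate r solves Σ_x e^(−r(x+1)) l_x m_x = 1 by bisection: the
left side is strictly decreasing in r, the initial bracket [−1, 1] is
doubled until the residual changes sign (capped at ±64), and iteration stops
when |Σ e^(−r(x+1)) l_x m_x − 1| ≤ 1e−12 (max 200 iterations). λ = e^r and
T = ln R₀ / r are evaluated from the solved r at full precision. R₀ = 0
(no eggs) makes r, λ, T not estimable; they propagate as NaN with an
`estimable` flag. R₀ is summed from age 0; ages before first reproduction
contribute zero, so the lower summation index is immaterial.

Summary statistics follow the conventions of this literature: stage-duration
means use only individuals that completed the stage; pre-adult time and
survival are over emerged adults (survival = emerged/n₀); TPOP and APOP are
over ovipositing females; oviposition days and lifetime fecundity are over
all emerged females, zero-layers included. Displayed ± values on plain
means are descriptive sd/√n; inferential SEs come from the bootstrap.

## Bootstrap and comparisons

Each replicate draws n₀ individuals with replacement and recomputes the
statistic; the SE is the SD (ddof = 1) of the valid replicates and the CI
the 2.5/97.5 percentiles. Replicates where a statistic is not estimable
(e.g. a resample with no females) are dropped and counted; more than 1%
invalid flags the result. Streams are derived from
(root seed, statistic name, cohort label) via hashed `SeedSequence` spawn
keys, so adding a statistic or cohort never perturbs existing replicates;
r, λ, R₀ and T share one stream ("population_parameters") because all four
derive from the same resampled schedule, keeping them mutually consistent
within each replicate (λ_b = e^(r_b), T_b = ln R₀_b / r_b).

Two treatments are compared by the pick-1-by-1 paired percentile test:
d_b = a_b − c_b over replicate indices valid in both, significance when the
95% percentile interval of {d_b} excludes zero. The differences are used
raw (no studentisation) — the test is "based on percentile differences".
Letters are assigned by ordering treatments on descending point estimate,
taking maximal runs of mutually non-significant treatments as groups and
dropping subset groups; intransitive patterns yield multi-letter entries.
No multiple-testing correction is applied across the pairwise tests, and
the reports say so.

For bootstrap of the population parameters only the net maternity schedule
matters: l_x m_x of a resample is (resampled eggs at age x)/n₀, so each
replicate costs one weighted bincount plus a bisection solve.

## Degree-day model

Mean rates y = 1/(mean development time) are regressed on temperature by
OLS over an *explicitly chosen* temperature subset — the linear range is an
analyst's decision (here 20–27 °C; at 30 °C development slows again, and the
fit warns whenever the maximum rate is interior to the range). Then
t = −a/b, K = 1/b, SE_K = SE_b/b², and

SE_t = (ȳ/b) · sqrt( s²/(N ȳ²) + (SE_b/b)² ),

with s² the residual mean square and N the number of temperatures. This is
algebraically the delta-method SE of −a/b under OLS (using ȳ = a + b x̄),
which is why a parametric-resampling oracle (refit on y* ~ fitted line +
N(0, s²)) reproduces it; the test suite checks agreement within 15% at
100,000 draws. Fitting uses the *mean* rate per temperature, not
individual-level rates.

Note that published regression coefficients of this kind are generally not
recoverable exactly from published rounded development-time means (extra
precision or additional points behind the originals); the closed forms
t = −a/b and K = 1/b applied to published coefficients are exact, while
end-to-end refits from published means land in the neighbourhood only.

## Synthetic cohorts

The generator performs sequential stage sampling: per stage an integer
duration (shifted negative binomial, support ≥ 1 day, mean exactly the
configured value; deterministic option for exact tests) and a single
Bernoulli completion at stage entry, with death day uniform within the
stage. A sixth instar is added with probability p_L6 after L5. Sex is
assigned at emergence; adult longevity is drawn per sex; a female lays from
adult day D+1 (D the pre-oviposition delay) with daily means following a
discretised Gaussian kernel on days-since-first-oviposition (peak day, peak
height, width) and negative-binomial daily counts. Everything is
deterministic given (config, seed).

Because every component has a tractable expectation, the generator's
closed forms — P(emerge) = hatch × Π completions, E[lifetime eggs] summed
over the delay and longevity distributions, and
R₀ = P(female) · P(emerge) · E[lifetime eggs] — serve as independent oracles
for parameter-recovery tests (each preset's pipeline R₀ at n₀ = 2,000 over
20 seeds, within 3 Monte-Carlo SEs).

The four presets are calibrated to the published 20/25/27/30 °C cohorts:
duration means equal the published stage means; per-stage completion
probabilities start from the published stage-to-stage count ratios and are
rescaled by one solved factor so P(emerge) equals the published survival
percentage exactly (the published counts do not fully reconcile across
tables, so percentages are the targets); sex ratios are the observed adult
sex splits; the kernel height is solved so E[lifetime eggs] equals the
published mean fecundity. With those calibrations the closed-form R₀ values
reproduce the published net reproduction rates (3.32, 45.56, 31.10, 2.17)
to print precision — a strong internal-consistency check, since R₀ =
total eggs / n₀ is an identity of the framework.

What the simulator does *not* emulate, hence what passing tests do not show
about real data: published development-time SEs imply variances *below* the
mean (real stage durations are under-dispersed), which a negative binomial
cannot reach — preset durations therefore sit near the Poisson limit
(k = 80) and simulated SEs of development times run larger than published
ones. Longevity and APOP *are* over-dispersed in the published tables and
their k is matched to the printed SEs. Stage durations, survival, sex,
longevity and fecundity are mutually independent in the generator (no
frailty, no trade-offs); the pre-oviposition delay is applied
unconditionally while the published APOP is conditional on having oviposited;
and there is no mechanistic temperature→rate coupling — presets are four
separate parameterisations, not a thermal model.

## Problem sizes and numerical choices

Bootstrap default B = 100,000 in the CLI; the analysis drivers and the
acceptance script use B = 2,000 and the tests 200–10,000, with B always
recorded in every report. Parameter-recovery runs use n₀ = 2,000 and 20
seeds per preset; solver tolerance 1e−12 on the Euler–Lotka residual; the
grid-search oracle refines to 1e−6. Paired tests require ≥ 100 valid
replicate pairs. All report JSON is written with sorted keys, full float
precision and no timestamps, so identical inputs and seed are byte-identical.

## Known limitations

- T = ln R₀ / r is extremely sensitive to r near r ≈ 0: at small growth
  rates, a change of ±0.0005 in r (half a printed unit) moves T by ≈ 1 day,
  so generation times recomputed from 3-d.p. growth rates can differ from
  full-precision values by several tenths of a day. λ = e^r inherits the
  same print-rounding wobble in its third decimal.
- Only 1-day censuses are supported; no sub-day interpolation.
- No life-expectancy (e_xj) or reproductive-value (v_xj) matrices, and no
  nonlinear development-rate models (Brière, Lactin, Sharpe–Schoolfield).
- The letter display is the standard greedy insert-absorb construction; like
  all compact letter displays it can be non-unique under intransitive
  significance patterns (it is deterministic here).
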