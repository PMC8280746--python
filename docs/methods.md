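# Methods

This note documents the models implemented in `prolonger`, the assumptions
they make, the defaults and why, and what the synthetic-data tests do and do
not demonstrate about real data.

## Abridged life table (Chiang construction)

Life expectancy at birth is computed on grouped age bands (default 0–4,
5–9, …, 80–84, 85+) from central death rates `M_x = D_x / P_x`, where
deaths and person-years are **pooled over the observation window** (numerator
and denominator summed separately across years) rather than averaging
per-year tables — the convention used when multi-year small-area rates are
annualised. Per closed band of width `n_x`:

```
q_x = n_x·M_x / (1 + n_x·(1 − a_x)·M_x)        (clipped to [0, 1])
l_0 = 100,000;   l_{x+1} = l_x·(1 − q_x);   d_x = l_x·q_x
L_x = n_x·(l_{x+1} + a_x·d_x)
```

The open terminal band has `q = 1` and `L = l / M` (constant-hazard
closure), `T_x` is the reverse cumulative sum of `L`, and `e_x = T_x / l_x`.

**a_x defaults.** `a_x = 0.5` (deaths at mid-interval) for all closed bands.
If a schema with separate <1 and 1–4 bands is supplied, the conventional
infant adjustment `a_0 = 0.1`, `a_{1–4} = 0.4` is applied automatically.
The radix is fixed at 100,000; `e_0` is invariant to it.

**Accuracy.** Against an exact continuous-time cohort model (exponential
waiting times under piecewise-constant hazards), the `a = 0.5` convention
carries a small systematic discrepancy that grows with `n·M` in the oldest
closed bands: across human-range schedules (e₀ ≈ 66–86) it is +0.01 to
+0.07 years, always under 0.1 y. The test suite checks agreement with a
10⁶-agent microsimulation at the larger of 3 Monte-Carlo standard errors
and 0.1 y per schedule. Two regimes are exact and asserted exactly: a
single open interval (`e_0 = 1/M`) and zero mortality below the terminal
band (`e_0 = 85 + 1/M_{85+}`).

**Degenerate inputs.** A zero terminal rate makes `L = l/M` undefined and
raises an error — upstream smoothing is responsible for never producing an
empty open interval. Deaths in a band with zero population raise a
rate-undefined error naming the cell.

## Small-cell smoothing

Neighbourhood×band cells with few deaths of a cause make small-area LE
unstable (an empty old-age cell can inflate `e_0` badly). Cells with
**fewer than 5** cause-specific deaths (pooled over the window;
threshold configurable, 5 follows the small-area practice of national
life-expectancy projects) are replaced by predictions from a negative
binomial regression (log link, NB2 dispersion estimated by maximum
likelihood) of the cell count on six covariates: age at interval start,
age-specific population, proportion Black, proportion white, median
household income, proportion with education above high school.

Design choices:

- **One pooled model per cause** across all geounits and bands; refitted
  when the analysis switches cause.
- **Population enters as a covariate, not an offset** (matching the stated
  covariate list); an offset variant would force a rate model, which is a
  different estimand. Covariates are standardised internally for numerical
  stability; reported coefficients are back-transformed to the original
  scale.
- **Cap rule.** A prediction larger than the total deaths of the cause in
  that age band is replaced by that total. The total is taken
  **study-area-wide** by default — the only reading under which a prediction
  can plausibly exceed it (a per-geounit cap degenerates to the observed
  cell count); both options are exposed.
- **Fallbacks.** Zero-variance covariates are dropped with a warning
  (an all-constant design reduces to an intercept-only fit); remaining
  collinearity raises an error naming the offending columns. A degenerate
  dispersion estimate (no overdispersion) or a failed NB likelihood falls
  back to a Poisson GLM, recorded on the model object. Note that at least
  six geounits are needed before the four geounit-level covariates plus the
  intercept can be linearly independent.
- **Which table is smoothed.** Only the target cause's cells are replaced;
  the all-cause table used for LE is rebuilt as (observed other-cause
  deaths) + (smoothed cause cells). Smoothed counts stay fractional for
  rate computation.

## LISSO: the lives-saved simulation

A reduction scenario names a cause, a proportion `p` averted (0 is the null
scenario; the tool's menu is 5/10/15/20%), and a mode:

- **within-age**: avert `round_half_even(p·D_{x,y})` deaths in each band
  `x` and year `y`;
- **overall**: avert `round_half_even(p·D_y)` per year, allocated across
  bands proportionally to each band's share of the cause's deaths by
  largest-remainder apportionment (ties broken by band order), so the
  allocation sums exactly to the overall target.

Half-even rounding and largest-remainder apportionment were chosen for
reproducibility and exact conservation. The two modes' totals can differ by
at most 0.5 per nonzero band-year (accumulated rounding), which on
realistic counts leaves them essentially perfectly correlated across
geounits.

Each replicate then: selects the targeted decedents uniformly at random
without replacement within each (band, year); ages each saved agent one
integer year per calendar year (re-banding as the age crosses a boundary);
and in every subsequent year of the window kills the agent with probability
equal to the **annual all-cause central death rate of their peers** in the
agent's current band (Bernoulli draw; rates clipped to [0, 1]). Deaths in
follow-up are removed from the lives-saved tally — at the band of original
selection, keeping the accounting aligned with the band whose deaths were
reduced — and re-added to the expected table at the (band, year) where they
occurred. A variance-free deterministic mode (proportional weight decay)
exists for testing.

Over `n_replicates = 100` independent streams (replicate `r` of geounit `g`
draws from `SeedSequence([seed, g, r])`, so results are independent of
execution order and two comparison arms can share seed discipline), the
**median** net lives saved per band is taken, and

```
expected deaths per band = observed − median net averted   (floored at 0)
```

Decisions where the procedure was genuinely open:

- Survivors face **all-cause** peer mortality in follow-up (not
  cause-deleted rates): "the same mortality rate as their peers". A
  cause-specific-only attrition option is exposed.
- The reduction applies in **every year** of the window (each year is an
  index year for its own decedents); a single-index-year mode is available.
- The expectation of net lives saved has the closed form
  `Σ_y t_y · Π_{y′>y} (1 − M_{band(y′),y′})`, which the tests use as an
  oracle (mean over 500 replicates within 3 SE; the median of an
  integer-valued total is additionally checked within 1 — a discrete median
  cannot generally sit within fractions of a death of a fractional mean).

## Expected life expectancy and ranking

For one geounit and scenario, both arms share one smoothing fit:

1. observed LE: Chiang on (other-cause observed + smoothed cause cells);
2. expected LE: Chiang on (other-cause observed + max(smoothed cause −
   median net averted, 0)).

The smoothing **adjustment is held fixed between arms** rather than
re-running cell replacement on the expected table: re-smoothing would
overwrite the intervention's effect in exactly the small cells the scenario
targets. Holding it fixed isolates the intervention and makes the gain
structurally non-negative (bandwise-smaller rates never lower Chiang LE).
Peer rates driving agent attrition are the raw annual all-cause rates
(per-year cells are too sparse to smooth credibly and the two arms share
them, so no comparison is confounded).

Rankings sort geounits by gain, descending, ties broken by geounit id.
Distribution summaries (median, IQR of gains) use the linear-interpolation
quantile rule, so they are exactly reproducible.

R² throughout is the squared Pearson correlation between paired per-geounit
vectors (it is a correlation of two predictions, not a regression through
the origin), and requires at least 3 geounits.

## Aggregate-data mode

When only banded tables are available, each cell of `k` deaths in a band of
width `w` is expanded into pseudo-individuals: every single-year age
receives `k // w` records and the remaining `k % w` are placed at ages
drawn without replacement with a seeded generator — deterministic
round-robin plus a seeded remainder, which guarantees that re-aggregation
returns the input table *exactly* and that the same seed reproduces the
same records. The open 85+ band spreads over a configurable span, default
85–89, keeping symmetry with closed bands. Stratified (sex/race) cells
expand per stratum, reproducing observed stratum proportions within each
age group exactly. Fractional (smoothed) counts are not expandable.

## Synthetic city

The generator emulates the structure of a mid-sized US city's restricted
vital-statistics data; its defaults are the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| geounits | 55 | neighbourhood-statistical-area count of the motivating city |
| population per geounit | 5,000–20,000 (uniform) | neighbourhood-unit size range |
| window | 2012–2016 (5 y) | typical pooled vital-statistics window |
| leading cause share | 24.4% of deaths, age-increasing profile | leading-cause burden in the motivating city |
| other causes | cancer .213, stroke .049, drug/alcohol .045, CLRD .035, remainder "other" | published cause-mix proportions |
| mortality shape | Gompertz–Makeham, b = 0.085, c = 5·10⁻⁴ | adult hazard doubling ≈ every 8 y plus background |
| city-level e₀ | 73.2 y (Gompertz level A bisected to hit it) | city-level LE of the motivating setting |
| geounit heterogeneity | log-normal rate multiplier: effect 0.25 on a latent disadvantage factor + residual σ 0.15 | yields a ~10–20 y spread in true e₀ across geounits, matching observed neighbourhood gaps |
| cell counts | NB2, dispersion α = 0.3 | moderate overdispersion typical of small-area counts |

The latent disadvantage factor drives both the covariates (race
composition, income, education) and the mortality multiplier, so the
smoothing model has real signal and known truth. Ground truth (base
schedule, multipliers, true rates, true e₀) is returned for recovery tests.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: spatial autocorrelation between neighbouring
geounits, migration and population change over the window, cause-of-death
miscoding, age heaping, year-to-year trends, and causes with genuinely
different age profiles beyond the leading cause's ramp. Conclusions about
the *pipeline's arithmetic and invariances* transfer; conclusions about
*effect sizes* in any particular real city do not.

## Problem sizes in the test suite

The acceptance checks run the full default city (55 geounits, ~46,000
records, 100 replicates per geounit per arm, a few minutes total), the
Chiang oracle at 10⁶ agents × 50 schedules, the LISSO closed-form oracle at
500 replicates, and the smoothing recovery on the full 55×18 cell grid with
dispersion 1.5. Unit tests use an 8-geounit city and toy schedules chosen
to be hand-computable.

## Known limitations

- Single-cause scenarios; no competing-risk reassignment of averted deaths,
  so gains for causes with strong comorbidity are optimistic.
- No sampling variability on e₀ (no Chiang variance or CIs); the replicate
  spread of LISSO is available but not propagated into LE intervals.
- Peer mortality in follow-up is the *observed* rate, which still contains
  the targeted cause: survivors can die of the cause that was just
  prevented for them (consistent with the "same rate as their peers"
  modelling stance).
- The within-band uniform-age assumption for aggregate data is conservative
  and slightly misstates ages for causes with steep within-band gradients
  (mainly 85+).
- Projection stops at the window's end; saved agents' mortality after the
  window is not modelled, so "net lives saved" is window-relative.
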