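# Methods

## The problem

Published population-health summaries describe *averages*: life
expectancy (LE) and health-adjusted life expectancy (HALE) say how long
people live, and how long they live in good health, on average.  They say
nothing about the *variability* of those quantities across individuals.
A population in which everyone ceases to be healthy at 65 is very
different from one in which half do so at 55 and half at 75, yet both can
share the same HALE.

This package measures that variability.  From the abridged (5-year
age-group) quantities that the Global Burden of Disease (GBD) results
tool publishes — age-specific death probabilities `nqx`, remaining life
expectancies `ex`, and remaining HALE — it reconstructs:

1. the **mortality curve** `lx` (survivorship) and the full abridged life
   table, including the within-interval timing of deaths `nax`;
2. the **morbidity curve** `lstar_x`, the proportion of the cohort still
   in *good health* at age x, by inverting the Sullivan relationship
   between HALE and the healthy-survival curve;
3. the **age-at-death** distribution `ndx = lx − l_{x+n}` and the
   **age-at-morbidity-onset** distribution
   `ndstar = lstar_x − lstar_{x+n}`;
4. **lifespan inequality** LI and **healthy lifespan inequality** HLI —
   the standard deviations (alternatively CV or Gini) of those two
   distributions — plus the variants LI65/HLI65 conditioned on reaching
   age 65 (in the relevant state), and the HLI/LI ratio.

Uncertainty in the published inputs is propagated to every indicator by
Monte Carlo, and 80% empirical intervals are reported.

## Recovering the life table (and nax) from qx and ex

`lx` follows from `nqx` by cumulative survival.  The person-years
identity `Tx = ex · lx` then yields `nLx = Tx − T_{x+n}` by first
differences, and for each closed interval with deaths,

    nax = (nLx − n · l_{x+n}) / ndx .

This inversion is exact: a table built forward from any valid `(qx, nax)`
returns those `nax` to 1e−10 (machine-level; see the round-trip tests).
Conventions: `nax = n/2` when an interval has no deaths (the value is
then irrelevant to person-years but must exist); the open age group has
`nax = ex(last)`; once `lx = 0` all downstream columns are zero.  The
radix is 1 internally and only scales presentation.

Recovered `nax` outside `[0, n]` signals a mutually incoherent `(qx, ex)`
pair.  In `strict` mode (the default and the testing contract) excursions
beyond 1e−6 raise; smaller ones — rounding noise in published tables —
are clipped with a warning.  In `clamp` mode (used on sampled inputs, see
below) excursions are projected onto `[0.01·n, n]`; the floor keeps the
morbidity recursion's division well away from zero.

## Inverting the Sullivan relationship

Sullivan's method computes HALE from a prevalence-weighted life table; we
need the reverse: the healthy-survival curve implied by a published HALE
schedule.  Healthy person-years above x are `Tstar = hale · lx`, so
`nLstar` follows by first differences.  Exits from good health within a
closed interval are timed at the interval's mortality `nax` (no separate
onset timing is estimable from published data), giving

    nLstar = nax · lstar_x + (n − nax) · lstar_{x+n} ,

which is solved backwards from the open group, where
`lstar(last) = nLstar(last) / ex(last)` — the healthy share of the open
group equals the healthy share of its person-years, mirroring the exact
identity `lx(last) = nLx(last)/ex(last)`.

The forward operator (`sullivan_hale`) is implemented alongside and is
the inversion's oracle: reconstruct(sullivan(lstar)) = lstar to 1e−10 for
any valid curve.  Assumptions inherited from the Sullivan framework: no
recovery from the less-than-healthy state (the morbidity curve is
non-increasing), and period (synthetic-cohort) interpretation.  A curve
starting below the radix is allowed: `lstar(0) < lx(0)` means part of the
cohort is never in good health, and the onset distribution totals less
than the death distribution.

`strict` mode raises on any violation of `0 ≤ lstar ≤ lx` or of
monotonicity; `clamp` mode (the pipeline default, required for sampled
inputs) clips HALE to `[0, ex]`, projects the curve onto `[0, lx]`,
enforces monotonicity by a running maximum from the oldest age, and logs
every adjustment.  Healthy person-years are conserved in both modes
because `nLstar` comes from the telescoping `Tstar` differences, not from
the adjusted curve.

## Inequality statistics

Both event distributions place the mass of each closed interval at its
mean event age `x + nax`, and the open group's mass at `x_last +
ex(last)`.  The SD and CV additionally include **within-interval
variance** by the law of total variance: `n²/12` per closed interval
(uniform spread of event times inside the interval) and `ex(last)²` for
the open group (constant-hazard closing, i.e. exponential remaining
lifetimes matching the group mean).  Without this term the grouped SD
systematically understates the underlying spread — by up to ~20% for the
age-65-conditioned indicators, where the 5-year grouping is coarse
relative to the distribution — while with it the recovery battery (below)
lands within ~1% of continuous truth.  The Gini index is the standard
population Gini (mean absolute difference over twice the mean) computed
on the group mean ages; the mean-difference form has no law-of-total-
variance analogue without a full within-group age distribution, so it is
a between-group Gini.

Statistics normalise by the distribution's own total mass: onset
statistics are moments of the onset distribution, i.e. among those who
ever experience onset.  Conditioning at 65 drops the groups below 65 and
renormalises; the threshold must be a grid boundary.  All statistics use
population (not sample) denominators, are invariant to rescaling the mass
(radix independence), and satisfy the person-years identities exactly:
the mean age at death equals `e0`, and the 65-conditioned mean equals
`65 + e65`, to 1e−10.

## Monte Carlo uncertainty

GBD publishes 95% uncertainty intervals, not draws.  Each draw perturbs
the schedules with **split-normal** deviates: a standard-normal z scaled
by the upper half-width when positive and the lower half-width when
negative, so the published bounds sit at the ±1.96 quantiles.  One z is
shared across ages within a measure (schedule-level uncertainty;
age-independent noise would produce implausibly jagged schedules), and
the three measures get independent z's.

The three z's are applied **life-table-coherently**: `z_q` perturbs the
death probabilities; the draw's `ex` schedule is *derived* by rebuilding
the life table from the sampled `qx` with the point-estimate `nax`
values, with `z_e` entering through the sampled open-group expectancy;
`z_h` perturbs HALE, clipped to the draw's `ex`.  The published `qx` and
`ex` intervals are two views of one underlying life table's uncertainty;
sampling them independently of each other creates incoherent pairs whose
`nax` inversion error is amplified by `nLx/ndx` (hundreds at
low-mortality ages), which in measurement made every draw's morbidity
curve collapse through the clamp machinery and biased the whole draw
distribution below the point estimate.  A side effect of the coherent
scheme is that the marginal spread of the derived `ex(0)` draws is
governed by the `qx` intervals rather than the published `ex` intervals;
the latter still set the open-group spread.

Intervals are the 10th/90th empirical percentiles (type-7 interpolation)
of the indicator draws — 80% by default, reported instead of 95% because
of the substantial uncertainty inherent in HALE estimates; the point
estimate comes from the unperturbed run.  Draws on which the pipeline
raises are dropped and counted; more than 5% failures aborts.  Each
(location, sex, year) gets a substream seed derived by hashing the key,
so batch results are independent of processing order.

### Measured calibration, and a real limitation

The coverage experiment (tests and acceptance script) replicates
"observing" a known synthetic population 200 times — each observation is
one coherent draw re-equipped with intervals of the original absolute
widths — and checks that the 200-draw 80% interval covers the error-free
pipeline value in ≈80% of replications (±7% binomial tolerance).  The
error-free pipeline value, not the continuous fine-grid truth, is the
right target here: the ≤1–2% abridged-grid discretisation offset is a
property of the estimator, not of the interval machinery.

Calibration holds only **away from the `lstar ≤ lx` boundary**.  For a
population in which everyone is born healthy, the true morbidity curve
touches the mortality curve at young ages, and the HLI response to HALE
noise is one-sided: upward noise is absorbed by the boundary clamp,
downward noise converts into excluded never-healthy mass at birth; both
push HLI the same way, the draw distribution sits below the point
estimate, and percentile intervals undercover badly (we measured 8–62%
depending on the width profile — no interval width fixes this).  The
coverage study therefore uses a population with a 2% congenital
never-healthy fraction and a childhood onset term (both realistic:
published HALE at birth reflects congenital and childhood conditions)
and age-graded relative interval widths (HALE uncertainty grows strongly
with age in published estimates).  Under these interior conditions
measured coverage is 80%.  For real populations whose morbidity curve
hugs the mortality curve in childhood, reported HLI intervals should be
read as conservative in location (shifted down) rather than strictly
calibrated — a limitation of percentile intervals at a constraint
boundary, inherited from the method itself.

## The synthetic-data generator

The generator is the package's ground-truth oracle, not a fixture.  It
emulates the estimation process behind a GBD extract with a two-state
illness-death model without recovery: Gompertz–Makeham mortality hazard
`mu(x) = c + a·exp(b·x)` and onset hazard
`lam(x) = c* + a*·exp(b*·x) [+ k·exp(−r·x)]`, an optional congenital
never-healthy fraction, survival `l = exp(−∫mu)` and healthy survival
`lstar = (1 − p0)·exp(−∫(mu+lam))` — exit from health by onset *or*
death, so `lstar ≤ lx` and the no-recovery assumption hold by
construction.  Curves are evaluated in closed form on a fine monthly
grid extended until survival falls below ~1e−13; person-years are
trapezoidal integrals; the abridged emission (`qx`, `ex`,
Sullivan-consistent `hale`, on the GBD grid 0, 1, 5, …, 95+) introduces
no approximation beyond that quadrature.  Reference LE/HALE/LI/HLI
values and their 65-conditioned variants come from tail-integral
identities on the fine grid.  Emitted intervals are relative half-widths
per measure (defaults 5% / 2% / 3% for qx / ex / hale; an age-graded
GBD-like profile is available), centred on the truth — so tests can
calibrate the uncertainty machinery exactly.

Default demo hazards (`a=3e−5, b=0.095, c=8e−4; a*=6e−5, b*=0.095,
c*=2e−3`) give LE ≈ 76.3, HALE ≈ 61.1, HLI ≈ 19.6.  The random-model
battery samples a modal age at death `M ~ U(72, 90)` and slope
`b ~ U(0.08, 0.12)` and sets `a = b·exp(−b·M)` — the Strehler–Mildvan
pairing; sampling `a` and `b` independently produces mortality surfaces
no real population resembles (modal ages near 59 with empty open
groups).  The onset modal age runs 5–15 years ahead of death.

A microsimulation path provides an independent empirical oracle:
individual death ages and onset-candidate ages are drawn by
inverse-transform sampling of the two cumulative hazards, the recorded
onset age is the minimum of the two (so onset ≤ death always), and the
empirical SD of onset ages among the ever-healthy converges to the true
HLI.  The 10⁶-individual check uses the kurtosis-adjusted standard error
of a sample SD, `s·sqrt((kappa−1)/(4n))` — the normal-theory
`s/sqrt(2n)` understates the SE for this left-skewed distribution.

### What the generator does not emulate

Real GBD estimates carry age-correlated estimation error, non-GM hazard
shapes (infant mortality humps, accident bumps), cause structure, and
cross-measure dependence beyond the life-table identity.  Passing the
recovery battery shows the pipeline inverts its own model class
faithfully through the abridged bottleneck; it does not validate GBD's
own qx/ex/HALE estimation, which is out of scope.

## Problem sizes and numerical choices

Tests and the acceptance script use: 200 random curve pairs for the
Sullivan round-trip, 100 tables for the nax round-trip, a 20-model
recovery battery, one 10⁶-individual microsimulation, and 200×200
replications/draws for coverage; the whole suite runs in about a minute
on one core.  Tolerances: 1e−10 for operator round-trips and moment
identities, 2% relative for truth recovery (abridged-grid
discretisation), ±7% for coverage (binomial at n=200).  Ties and
degenerate cases: single-group distributions have zero spread; a zero
event total raises; `cv` and `gini` of an all-mass-at-age-zero
distribution are undefined and raise.

## Interpreting trends and fits

`compression_trend` classifies a multi-year HLI series by its end-point
difference against a stagnation band ε (default 0.1 years, configurable;
no canonical value exists): falling HLI = morbidity compression
(onset ages concentrating), rising = expansion.
`expectancy_inequality_fit` is an unweighted pooled OLS of an inequality
indicator on an expectancy (e.g. LI on LE, HLI on HALE) across
country-years, via `scipy.stats.linregress`; it takes the point cloud as
given and applies no weighting or year selection.
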