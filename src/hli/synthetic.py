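"""Synthetic populations with a known continuous-time ground truth.

A two-state (healthy -> unhealthy -> dead, no recovery) illness-death
model with Gompertz-Makeham hazards stands in for the estimation process
behind published abridged data:

* mortality hazard      ``mu(x) = c + a * exp(b * x)``
* onset hazard          ``lam(x) = c* + a* * exp(b* * x) [+ k * exp(-r x)]``

Survival is ``l(x) = exp(-integral of mu)``; survival *in good health* is
``lstar(x) = exp(-integral of (mu + lam))`` — exit from the healthy state
by onset or by death, which guarantees ``lstar <= l`` and no recovery, so
the Sullivan assumption holds in the generator by construction.

From the fine-grid curves the generator emits exactly the abridged
(qx, ex, hale) schedules a GBD results-tool extract would carry, plus the
fine-grid truth (LE, HALE, and the inequality statistics LI/HLI and their
age-65-conditioned variants) against which the whole reconstruction
pipeline can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .schedules import GBD_GRID, AbridgedSchedule

#: Relative half-widths of the emitted uncertainty intervals, by measure.
#: Orders of magnitude follow published abridged estimates: death
#: probabilities are the noisiest input, expectancies the tightest.
DEFAULT_UI_WIDTH = {
    "death_probability": 0.05,
    "life_expectancy": 0.02,
    "hale": 0.03,
}


@dataclass
class SyntheticModel:
    """Gompertz-Makeham mortality plus Gompertz-Makeham morbidity onset.

    Defaults give a schematic low-to-middle-mortality population: life
    expectancy in the high 70s with onset running roughly a decade ahead
    of death.  ``childhood_a``/``childhood_rate`` add an optional
    exponentially decaying early-life onset term ``k * exp(-r x)``;
    ``congenital_frac`` is the fraction never in good health (scales the
    healthy-survival curve, so the morbidity curve starts strictly below
    the mortality curve).  ``fine_step`` is the integration step in
    years.  ``ui_width`` maps each measure to the relative half-width of
    its emitted uncertainty interval — a scalar, or an array aligned to
    the grid for age-varying widths.
    """

    a: float = 3e-5
    b: float = 0.095
    c: float = 8e-4
    a_star: float = 6e-5
    b_star: float = 0.095
    c_star: float = 2e-3
    childhood_a: float = 0.0
    childhood_rate: float = 0.5
    congenital_frac: float = 0.0
    fine_step: float = 1.0 / 12.0
    grid: np.ndarray = field(default_factory=lambda: GBD_GRID.copy())
    ui_width: dict = field(default_factory=lambda: dict(DEFAULT_UI_WIDTH))

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.a_star, self.b_star, self.c_star,
               self.childhood_a) < 0:
            raise ValueError("hazard parameters must be nonnegative")
        if not 0 <= self.congenital_frac < 1:
            raise ValueError("congenital_frac must be in [0, 1)")
        if self.a == 0 and self.c == 0:
            raise ValueError("mortality hazard is identically zero")
        if not 0 < self.fine_step <= 1:
            raise ValueError("fine_step must be in (0, 1] years")
        self.grid = np.asarray(self.grid, dtype=float)

    # -- hazards and closed-form cumulative hazards ---------------------
    def mortality_hazard(self, x: np.ndarray) -> np.ndarray:
        return self.c + self.a * np.exp(self.b * np.asarray(x, float))

    def onset_hazard(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        lam = self.c_star + self.a_star * np.exp(self.b_star * x)
        if self.childhood_a > 0:
            lam = lam + self.childhood_a * np.exp(-self.childhood_rate * x)
        return lam

    def cum_mortality_hazard(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        gomp = self.a / self.b * np.expm1(self.b * x) if self.a > 0 else 0.0
        return self.c * x + gomp

    def cum_onset_hazard(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        out = self.c_star * x
        if self.a_star > 0:
            out = out + self.a_star / self.b_star * np.expm1(self.b_star * x)
        if self.childhood_a > 0:
            out = out + (self.childhood_a / self.childhood_rate
                         * (1.0 - np.exp(-self.childhood_rate * x)))
        return out

    def max_age(self) -> float:
        """Integration horizon: survival below ~1e-13, on a fine-step
        multiple past the end of the abridged grid."""
        target = 30.0  # cumulative hazard; exp(-30) ~ 9e-14

        def f(x: float) -> float:
            return float(self.cum_mortality_hazard(x)) - target

        lo = float(self.grid[-1]) + 5.0
        if f(lo) >= 0:
            age = lo
        else:
            hi = 2.0 * lo
            while f(hi) < 0:  # low flat hazards need a long horizon
                hi *= 2.0
            age = brentq(f, lo, hi)
        return float(np.ceil(age / self.fine_step) * self.fine_step)


@dataclass
class SyntheticTruth:
    """Fine-grid reference values for one synthetic model."""

    age_fine: np.ndarray
    lx_fine: np.ndarray
    lstar_fine: np.ndarray
    lx_abridged: np.ndarray
    lstar_abridged: np.ndarray
    nax_abridged: np.ndarray
    le: float
    hale0: float
    li: float
    hli: float
    le65: float
    hale65: float
    li65: float
    hli65: float

    def as_dict(self) -> dict:
        return {"le": self.le, "hale0": self.hale0, "li": self.li,
                "hli": self.hli, "le65": self.le65, "hale65": self.hale65,
                "li65": self.li65, "hli65": self.hli65}


@dataclass
class SyntheticPopulation:
    """Emitted abridged schedules plus the generating truth."""

    qx: AbridgedSchedule
    ex: AbridgedSchedule
    hale: AbridgedSchedule
    truth: SyntheticTruth
    model: SyntheticModel


def _conditional_sd(age: np.ndarray, surv: np.ndarray, i0: int) -> float:
    """SD of the event age conditional on the event occurring at or after
    ``age[i0]``, for a survival function ``surv`` on a uniform fine grid.

    Uses the tail-integration identities  E[X | X >= t] = t + T(t)/S(t)
    and  E[X^2 | X >= t] = t^2 + 2 * int_t x S(x) dx / S(t).
    """
    x = age[i0:]
    s = surv[i0:]
    t = x[0]
    s0 = s[0]
    if s0 <= 0:
        raise ValueError("no survivors at conditioning age")
    tail = np.trapezoid(s, x)
    tail_x = np.trapezoid(x * s, x)
    mean = t + tail / s0
    ex2 = (t * t * s0 + 2.0 * tail_x) / s0
    return float(np.sqrt(max(ex2 - mean * mean, 0.0)))


def make_synthetic_population(m: SyntheticModel) -> SyntheticPopulation:
    """Emit GBD-shaped (qx, ex, hale) schedules and the fine-grid truth.

    Person-years are fine-grid trapezoidal integrals of the closed-form
    survival curves; the abridged emission carries no secondary
    approximation beyond that quadrature.
    """
    h = m.fine_step
    top = m.max_age()
    age = np.arange(0.0, top + h / 2, h)
    lx = np.exp(-m.cum_mortality_hazard(age))
    lstar = (1.0 - m.congenital_frac) * np.exp(
        -(m.cum_mortality_hazard(age) + m.cum_onset_hazard(age))
    )

    # person-years above x: T(x) = int_x^top l, likewise Tstar for lstar
    def tail_integral(y: np.ndarray) -> np.ndarray:
        cum = cumulative_trapezoid(y, age, initial=0.0)
        return cum[-1] - cum

    T = tail_integral(lx)
    Tstar = tail_integral(lstar)

    gidx = np.array([int(round(g / h)) for g in m.grid])
    if not np.allclose(age[gidx], m.grid):
        raise ValueError("abridged grid ages must sit on the fine grid")
    lx_g = lx[gidx]
    lstar_g = lstar[gidx]
    ex_g = T[gidx] / lx_g
    hale_g = Tstar[gidx] / lx_g
    qx_g = np.empty_like(m.grid)
    qx_g[:-1] = 1.0 - lx_g[1:] / lx_g[:-1]
    qx_g[-1] = 1.0

    # true within-interval mean person-years of decedents, closed groups
    n = np.diff(m.grid)
    nLx = T[gidx[:-1]] - T[gidx[1:]]
    ndx = lx_g[:-1] - lx_g[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        nax = np.where(ndx > 0, (nLx - n * lx_g[1:]) / ndx, n / 2.0)
    nax_full = np.concatenate([nax, [T[gidx[-1]] / lx_g[-1]]])

    i65 = int(round(65.0 / h))
    truth = SyntheticTruth(
        age_fine=age, lx_fine=lx, lstar_fine=lstar,
        lx_abridged=lx_g, lstar_abridged=lstar_g, nax_abridged=nax_full,
        le=float(T[0]),                    # l(0) = 1
        hale0=float(Tstar[0]),
        li=_conditional_sd(age, lx, 0),
        hli=_conditional_sd(age, lstar, 0),
        le65=float(T[i65] / lx[i65]),
        hale65=float(Tstar[i65] / lx[i65]),
        li65=_conditional_sd(age, lx, i65),
        hli65=_conditional_sd(age, lstar, i65),
    )

    def with_interval(values: np.ndarray, measure: str) -> AbridgedSchedule:
        w = m.ui_width.get(measure)
        if w is None:
            return AbridgedSchedule(m.grid.copy(), values, measure)
        w = np.asarray(w, float)  # scalar or per-age array
        lower = values * (1.0 - w)
        upper = values * (1.0 + w)
        if measure == "death_probability":
            lower, upper = np.clip(lower, 0, 1), np.clip(upper, 0, 1)
        return AbridgedSchedule(m.grid.copy(), values, measure, lower, upper)

    return SyntheticPopulation(
        qx=with_interval(qx_g, "death_probability"),
        ex=with_interval(ex_g, "life_expectancy"),
        hale=with_interval(hale_g, "hale"),
        truth=truth,
        model=m,
    )


def make_cohort_microdata(
    m: SyntheticModel, n: int, seed: int
) -> pd.DataFrame:
    """Simulate ``n`` individual (onset_age, death_age) pairs.

    Death age and the onset-candidate age are drawn by inverse-transform
    sampling from the two hazards (piecewise-linear inversion of the
    closed-form cumulative hazards on the fine grid).  The recorded onset
    age is the exit from the healthy state, ``min(candidate, death)``, so
    onset_age <= death_age always and, among the ever-healthy, the
    empirical distribution of onset ages converges to the ``lstar``
    first-difference distribution.  Individuals never in good health
    (``congenital_frac``) get ``onset_age = nan`` and are excluded from
    onset statistics, matching the curve convention.
    """
    if n < 1:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(seed)
    h = min(m.fine_step, 1.0 / 24.0)  # finer inversion grid for accuracy
    top = m.max_age()
    age = np.arange(0.0, top + h / 2, h)
    cum_mu = m.cum_mortality_hazard(age)
    cum_lam = m.cum_onset_hazard(age)

    t_death = -np.log(rng.random(n))
    death = np.interp(t_death, cum_mu, age, right=float(age[-1]))
    if cum_lam[-1] > 0:
        t_onset = -np.log(rng.random(n))
        candidate = np.interp(t_onset, cum_lam, age, right=np.inf)
    else:
        candidate = np.full(n, np.inf)
    onset = np.minimum(candidate, death)
    if m.congenital_frac > 0:
        onset[rng.random(n) < m.congenital_frac] = np.nan
    return pd.DataFrame({"onset_age": onset, "death_age": death})


def random_model(rng: np.random.Generator, grid: np.ndarray | None = None
                 ) -> SyntheticModel:
    """A random but demographically plausible model for recovery batteries.

    Rather than sampling the Gompertz intercept directly, the battery
    samples a modal age at death ``M ~ U(72, 90)`` and slope
    ``b ~ U(0.08, 0.12)`` and sets ``a = b * exp(-b * M)`` — the
    Strehler-Mildvan-consistent pairing; independent (a, b) draws
    produce populations no real mortality surface resembles.  The onset
    modal age runs 5-15 years ahead of death.  Resulting life
    expectancies span roughly the mid-60s to low 80s with HALE < LE.
    """
    loguni = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    b = float(rng.uniform(0.08, 0.12))
    modal_death = float(rng.uniform(72.0, 90.0))
    b_star = float(rng.uniform(0.07, 0.11))
    modal_onset = modal_death - float(rng.uniform(5.0, 15.0))
    kwargs = dict(
        a=b * float(np.exp(-b * modal_death)),
        b=b,
        c=loguni(1e-4, 2e-3),
        a_star=b_star * float(np.exp(-b_star * modal_onset)),
        b_star=b_star,
        c_star=loguni(5e-4, 3e-3),
    )
    if grid is not None:
        kwargs["grid"] = np.asarray(grid, float)
    return SyntheticModel(**kwargs)


def gbd_like_ui_widths(grid: np.ndarray) -> dict:
    """Age-graded relative interval half-widths shaped like published
    abridged estimates: death-probability uncertainty grows mildly with
    age (5% to 10%), expectancy intervals are tight (2%) and HALE
    uncertainty — dominated by disability-weight and prevalence modelling
    — widens strongly at old ages (2% at birth to 12% for the open
    group)."""
    grid = np.asarray(grid, float)
    rel = grid / grid[-1]
    return {
        "death_probability": 0.05 + 0.05 * rel,
        "life_expectancy": np.full_like(grid, 0.02),
        "hale": 0.02 + 0.10 * rel**2,
    }


def coverage_study_population() -> SyntheticPopulation:
    """The fixed population used to check the calibration of the Monte
    Carlo uncertainty intervals.

    Demo hazards plus the realistic early-life morbidity features — a
    childhood onset term and a 2% congenital never-healthy fraction — so
    the true morbidity curve lies strictly inside the ``lstar <= lx``
    constraint, and age-graded interval widths.  (On the constraint
    boundary the HLI response to hale noise is one-sided and percentile
    intervals undercover; see the methods note.)
    """
    model = SyntheticModel(childhood_a=0.01, childhood_rate=0.15,
                           congenital_frac=0.02,
                           ui_width=gbd_like_ui_widths(GBD_GRID))
    return make_synthetic_population(model)


def to_gbd_frame(
    pop: SyntheticPopulation,
    location: str = "Synthetica",
    sex: str = "both",
    year: int = 2019,
) -> pd.DataFrame:
    """Long-format table in the CSV dialect the :mod:`hli.io` reader
    expects (one row per measure x age group, GBD-style age labels)."""
    grid = pop.qx.grid
    labels = age_labels(grid)
    rows = []
    for sched, measure_label in (
        (pop.qx, "Probability of death"),
        (pop.ex, "Life expectancy"),
        (pop.hale, "HALE (Healthy life expectancy)"),
    ):
        for i, lab in enumerate(labels):
            rows.append({
                "measure_name": measure_label,
                "location_name": location,
                "sex_name": sex,
                "year": year,
                "age_name": lab,
                "val": sched.values[i],
                "lower": sched.lower[i] if sched.lower is not None
                else sched.values[i],
                "upper": sched.upper[i] if sched.upper is not None
                else sched.values[i],
            })
    return pd.DataFrame(rows)


def age_labels(grid: np.ndarray) -> list[str]:
    """GBD-style labels for a start-age grid: ``<1 year``, ``1 to 4``,
    ..., ``95 plus``."""
    labels = []
    for i, start in enumerate(grid):
        s = int(start)
        if i == len(grid) - 1:
            labels.append(f"{s} plus")
        elif i + 1 < len(grid):
            end = int(grid[i + 1]) - 1
            if s == 0 and end == 0:
                labels.append("<1 year")
            else:
                labels.append(f"{s} to {end}")
    return labels
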