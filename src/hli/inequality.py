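"""Age-at-event distributions and their inequality statistics.

First differences of a survival curve give the distribution of ages at
death (``ndx``); first differences of a morbidity curve give the
distribution of ages at morbidity onset (``ndstar``).  Lifespan
inequality (LI) and healthy lifespan inequality (HLI) are the spread of
those distributions — by default the standard deviation, with the
coefficient of variation and the Gini index as alternatives.  Appending
"65" to an indicator name means the distribution is conditioned on the
event occurring at age 65 or later.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lifetable import LifeTable
from .morbidity import MorbidityCurve


class EmptyDistributionError(ValueError):
    """Raised when a distribution carries no event mass."""


@dataclass
class AgeAtEventDistribution:
    """Event masses per age group with within-group mean event ages.

    ``mass`` is ``ndx`` (deaths) or ``ndstar`` (onsets); ``mean_age`` is
    ``x + nax`` for closed groups and ``x + ex(last)`` for the open
    group.  ``within_var`` carries the variance of event ages *inside*
    each group (zero when a distribution is built by hand from explicit
    event ages); SD and CV add it by the law of total variance, so that
    grouping into wide intervals does not systematically understate the
    spread.  Statistics normalise by ``total``, the distribution's own
    mass (for onsets: those who ever leave good health).
    """

    x: np.ndarray
    mass: np.ndarray
    mean_age: np.ndarray
    kind: str  # "death" or "onset"
    within_var: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.mass < -1e-12):
            raise ValueError("event mass must be nonnegative")
        self.mass = np.maximum(self.mass, 0.0)
        if self.within_var is None:
            self.within_var = np.zeros_like(self.mass)
        else:
            self.within_var = np.asarray(self.within_var, float)
            if self.within_var.shape != self.mass.shape:
                raise ValueError("within_var must align with mass")
            if np.any(self.within_var < 0):
                raise ValueError("within_var must be nonnegative")
        if self.total <= 0:
            raise EmptyDistributionError(f"{self.kind} distribution has no mass")

    @property
    def total(self) -> float:
        return float(self.mass.sum())


@dataclass
class InequalityResult:
    """Spread of an age-at-event distribution."""

    sd: float
    cv: float
    gini: float
    mean: float
    conditioning_age: float | None
    kind: str

    def by_measure(self, measure: str) -> float:
        if measure not in ("sd", "cv", "gini"):
            raise ValueError(f"unknown inequality measure {measure!r}")
        return getattr(self, measure)


def event_distribution(
    curve: LifeTable | MorbidityCurve,
) -> AgeAtEventDistribution:
    """Ages at death (from a life table) or at onset (from a morbidity
    curve) by first differences of the curve.

    The open group's survivors (or still-healthy) all experience the
    event there, at mean age ``x_last + ex(last)``; total mass therefore
    equals the curve's value at the first grid age.  Within-group
    variances are ``n^2 / 12`` for closed groups (uniform spread of event
    times inside the interval) and ``ex(last)^2`` for the open group
    (constant-hazard closing, i.e. exponential remaining lifetimes with
    the matching mean).
    """
    if isinstance(curve, LifeTable):
        lt, mass, kind = curve, curve.ndx, "death"
    elif isinstance(curve, MorbidityCurve):
        lt, mass, kind = curve.lifetable, curve.ndstar, "onset"
    else:
        raise TypeError("expected a LifeTable or MorbidityCurve")
    mean_age = np.concatenate(
        [lt.x[:-1] + lt.nax[:-1], [lt.x[-1] + lt.ex[-1]]]
    )
    within_var = np.concatenate(
        [lt.n[:-1] ** 2 / 12.0, [lt.ex[-1] ** 2]]
    )
    return AgeAtEventDistribution(lt.x.copy(), np.asarray(mass, float).copy(),
                                  mean_age, kind, within_var)


def condition_on_age(
    d: AgeAtEventDistribution, threshold: float = 65.0
) -> AgeAtEventDistribution:
    """Restrict a distribution to events at or above a grid-boundary age.

    Masses above the threshold are kept unchanged; normalisation happens
    inside the statistics, which divide by the (new, smaller) total.
    """
    idx = np.flatnonzero(np.isclose(d.x, threshold))
    if idx.size == 0:
        raise ValueError(f"threshold {threshold:g} is not on the age grid")
    i = int(idx[0])
    return AgeAtEventDistribution(d.x[i:].copy(), d.mass[i:].copy(),
                                  d.mean_age[i:].copy(), d.kind,
                                  d.within_var[i:].copy())


def _moments(d: AgeAtEventDistribution) -> tuple[float, float]:
    """Mean and total variance (between-group + within-group)."""
    w = d.mass / d.total
    mu = float(w @ d.mean_age)
    var = float(w @ (d.mean_age - mu) ** 2 + w @ d.within_var)
    return mu, var


def sd_age_at_event(
    d: AgeAtEventDistribution, conditioning_age: float | None = None
) -> InequalityResult:
    """Standard deviation (and companions) of the age-at-event distribution.

    Population moments: weights are ``mass / total``; no sample
    correction.  Within-group variance enters by the law of total
    variance.  A single-group point distribution has sd = cv = gini = 0.
    """
    mu, var = _moments(d)
    sd = float(np.sqrt(max(var, 0.0)))
    if mu > 0:
        cv = sd / mu
        gini = gini_age_at_event(d)
    elif sd == 0.0:
        cv = gini = 0.0
    else:
        raise ValueError("mean age is zero; cv and gini undefined")
    return InequalityResult(sd=sd, cv=cv, gini=gini, mean=mu,
                            conditioning_age=conditioning_age, kind=d.kind)


def cv_age_at_event(d: AgeAtEventDistribution) -> float:
    """Coefficient of variation, sd / mean."""
    mu, var = _moments(d)
    if mu <= 0:
        if var == 0.0:
            return 0.0
        raise ValueError("mean age is zero; cv undefined")
    return float(np.sqrt(max(var, 0.0)) / mu)


def gini_age_at_event(d: AgeAtEventDistribution) -> float:
    """Gini index of the age-at-event distribution.

    Direct double sum over the (few) age groups:
    ``sum_ij w_i w_j |y_i - y_j| / (2 mu)``.  Computed on the group mean
    ages (between-group Gini); within-group spread does not enter, as the
    mean-difference form has no law-of-total-variance analogue without a
    full within-group age distribution.
    """
    w = d.mass / d.total
    y = d.mean_age
    mu = float(w @ y)
    if mu <= 0:
        if float(w @ (y - mu) ** 2) == 0.0:
            return 0.0
        raise ValueError("mean age is zero; gini undefined")
    diff = np.abs(y[:, None] - y[None, :])
    return float(w @ diff @ w / (2.0 * mu))
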