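"""Per-population indicator computation and cross-indicator summaries.

One call to :func:`compute_indicators` takes the three published
schedules for a (location, sex, year) and returns the full indicator row:
LE, HALE at birth, lifespan inequality (LI) and healthy lifespan
inequality (HLI), their age-65-conditioned variants, and the HLI/LI
ratio — optionally with Monte Carlo uncertainty intervals.  Trend
classification (morbidity compression vs expansion) and the pooled
expectancy-inequality regression live here too.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .inequality import condition_on_age, event_distribution, sd_age_at_event
from .lifetable import recover_ax
from .morbidity import reconstruct_morbidity_curve
from .schedules import AbridgedSchedule, check_same_grid
from .uncertainty import IntervalSummary, UncertaintySpec, monte_carlo_ui

#: Indicator column order for tidy output.
INDICATOR_NAMES = ("le", "hale0", "li", "hli", "le65", "hale65", "li65",
                   "hli65", "hli_li_ratio")


def indicator_values(
    qx: AbridgedSchedule,
    ex: AbridgedSchedule,
    hale: AbridgedSchedule,
    measure: str = "sd",
    age_threshold: float = 65.0,
    mode: str = "strict",
) -> dict[str, float]:
    """Run the reconstruction pipeline once and return plain scalars.

    Stages: recover the life table (and its nax) from (qx, ex); invert
    the Sullivan operator to get the morbidity curve from hale; take
    first differences of both curves; measure their spread, whole-life
    and conditioned at ``age_threshold``.  ``measure`` picks which
    statistic (sd, cv or gini) populates the LI/HLI slots.  ``mode`` is
    passed to both inversion stages (``clamp`` for sampled, possibly
    incoherent, inputs).
    """
    check_same_grid(qx, ex, hale)
    lt = recover_ax(qx, ex, mode=mode)
    mc = reconstruct_morbidity_curve(lt, hale, mode=mode)

    deaths = event_distribution(lt)
    onsets = event_distribution(mc)
    li = sd_age_at_event(deaths)
    hli = sd_age_at_event(onsets)
    li_c = sd_age_at_event(condition_on_age(deaths, age_threshold),
                           conditioning_age=age_threshold)
    hli_c = sd_age_at_event(condition_on_age(onsets, age_threshold),
                            conditioning_age=age_threshold)

    li_v = li.by_measure(measure)
    hli_v = hli.by_measure(measure)
    i_thr = int(np.flatnonzero(np.isclose(lt.x, age_threshold))[0])
    return {
        "le": float(lt.ex[0]),
        "hale0": float(mc.hale[0]),
        "li": li_v,
        "hli": hli_v,
        "le65": float(lt.ex[i_thr]),
        "hale65": float(mc.hale[i_thr]),
        "li65": li_c.by_measure(measure),
        "hli65": hli_c.by_measure(measure),
        "hli_li_ratio": hli_v / li_v if li_v > 0 else float("nan"),
    }


@dataclass
class IndicatorRow:
    """All indicators for one (location, sex, year), optionally with
    uncertainty intervals keyed by indicator name."""

    location: str
    sex: str
    year: int
    values: dict[str, float]
    inequality_measure: str = "sd"
    intervals: dict[str, IntervalSummary] | None = None

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.location, self.sex, self.year)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_record(self) -> dict:
        rec = {"location": self.location, "sex": self.sex, "year": self.year,
               "inequality_measure": self.inequality_measure}
        for name in INDICATOR_NAMES:
            rec[name] = self.values[name]
            if self.intervals is not None:
                rec[f"{name}_lower"] = self.intervals[name].lower
                rec[f"{name}_upper"] = self.intervals[name].upper
        return rec


def compute_indicators(
    qx: AbridgedSchedule,
    ex: AbridgedSchedule,
    hale: AbridgedSchedule,
    key: tuple[str, str, int] = ("unknown", "both", 0),
    measure: str = "sd",
    age_threshold: float = 65.0,
    mode: str = "clamp",
    uncertainty: UncertaintySpec | None = None,
) -> IndicatorRow:
    """Full indicator row for one population, with optional Monte Carlo
    uncertainty intervals.

    A pure function of its inputs (and the uncertainty seed): identical
    arguments give bitwise-identical rows regardless of batch order.
    """
    try:
        values = indicator_values(qx, ex, hale, measure=measure,
                                  age_threshold=age_threshold, mode=mode)
        intervals = None
        if uncertainty is not None:
            indicator = lambda q, e, h: indicator_values(
                q, e, h, measure=measure, age_threshold=age_threshold,
                mode="clamp")
            intervals = monte_carlo_ui(qx, ex, hale, uncertainty, indicator)
    except Exception as err:
        raise type(err)(f"{key}: {err}") from err
    return IndicatorRow(location=key[0], sex=str(key[1]), year=int(key[2]),
                        values=values, inequality_measure=measure,
                        intervals=intervals)


def _key_seed(root_seed: int, key: tuple) -> int:
    """Deterministic per-key substream seed, invariant to batch order."""
    digest = hashlib.sha256(repr(tuple(key)).encode()).digest()
    child = int.from_bytes(digest[:8], "big") ^ (root_seed * 0x9E3779B1)
    return child & 0x7FFFFFFF


def run_batch(
    data: dict[tuple, tuple[AbridgedSchedule, AbridgedSchedule, AbridgedSchedule]],
    measure: str = "sd",
    age_threshold: float = 65.0,
    uncertainty: UncertaintySpec | None = None,
) -> list[IndicatorRow]:
    """Indicators for every (location, sex, year) in a keyed collection.

    Each key gets its own uncertainty substream derived by hashing the
    key, so results do not depend on processing order.
    """
    rows = []
    for key in sorted(data):
        qx, ex, hale = data[key]
        spec = None
        if uncertainty is not None:
            spec = replace(uncertainty, seed=_key_seed(uncertainty.seed, key))
        rows.append(compute_indicators(qx, ex, hale, key=key, measure=measure,
                                       age_threshold=age_threshold,
                                       uncertainty=spec))
    return rows


@dataclass
class TrendAssessment:
    """Direction of change in HLI over a period: morbidity compression
    (HLI falling), expansion (rising), or stagnation (within epsilon)."""

    location: str
    sex: str
    period: tuple[int, int]
    delta_hli: float
    classification: str
    epsilon: float


def compression_trend(
    series: list[IndicatorRow], epsilon: float = 0.1
) -> TrendAssessment:
    """Classify a multi-year HLI series for one location and sex.

    ``delta_hli = HLI(last year) - HLI(first year)``; compressing if it
    falls below ``-epsilon`` years, expanding if above ``+epsilon``,
    stagnant otherwise.
    """
    if len(series) < 2:
        raise ValueError("need at least two years to assess a trend")
    ordered = sorted(series, key=lambda r: r.year)
    first, last = ordered[0], ordered[-1]
    delta = last["hli"] - first["hli"]
    if delta < -epsilon:
        label = "compressing"
    elif delta > epsilon:
        label = "expanding"
    else:
        label = "stagnant"
    return TrendAssessment(location=first.location, sex=first.sex,
                           period=(first.year, last.year),
                           delta_hli=float(delta), classification=label,
                           epsilon=epsilon)


@dataclass
class FitResult:
    """Unweighted pooled OLS of an inequality indicator on an expectancy."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def expectancy_inequality_fit(points: np.ndarray | list) -> FitResult:
    """OLS fit of inequality (y) on expectancy (x) over pooled
    country-year points, e.g. the LE-LI or HALE-HLI cloud."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y) pairs")
    if pts.shape[0] < 3:
        raise ValueError("need at least three points")
    x, y = pts[:, 0], pts[:, 1]
    if np.var(x) == 0:
        raise ValueError("degenerate fit: no variance in expectancy")
    res = stats.linregress(x, y)
    return FitResult(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue ** 2), n_points=pts.shape[0])
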