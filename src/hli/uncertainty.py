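"""Monte Carlo propagation of published interval uncertainty.

Published abridged estimates come with (asymmetric) uncertainty
intervals, not draws.  Each Monte Carlo draw perturbs a whole schedule
with a split-normal deviate: a standard-normal ``z`` is scaled by the
upper half-width when positive and the lower half-width when negative,
so the published bounds sit at the input coverage level's quantiles.  By
default one ``z`` is shared across ages within a measure (schedule-level,
not age-level, uncertainty) and the three measures (qx, ex, hale) get
independent z's — applied life-table-coherently, see
:func:`sample_inputs`.  Output intervals are empirical quantiles of the
indicator draws; 80% intervals are reported by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .schedules import AbridgedSchedule

logger = logging.getLogger(__name__)

CORRELATION_MODES = ("shared-z", "independent-by-age")


@dataclass
class UncertaintySpec:
    """Monte Carlo configuration.

    ``input_level`` is the coverage of the *input* intervals (0.95, the
    GBD convention); ``level`` the coverage of the reported output
    intervals (0.80).  ``correlation`` controls whether one ``z`` per
    (measure, draw) is shared across ages (default) or each age gets an
    independent ``z``.
    """

    n_draws: int = 1000
    level: float = 0.80
    seed: int = 0
    input_level: float = 0.95
    correlation: str = "shared-z"
    max_failure_rate: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if not 0 < self.input_level < 1:
            raise ValueError("input_level must be in (0, 1)")
        if self.n_draws < 2:
            raise ValueError("need at least 2 draws")
        if self.correlation not in CORRELATION_MODES:
            raise ValueError(f"unknown correlation mode {self.correlation!r}")

    @property
    def input_quantile(self) -> float:
        """Standard-normal quantile matching the input interval bounds
        (1.959964 for 95% inputs)."""
        return float(norm.ppf(0.5 * (1.0 + self.input_level)))


@dataclass
class IntervalSummary:
    """Point estimate with an empirical uncertainty interval.

    ``point`` comes from the point-estimate run, the bounds from draw
    quantiles, so ``lower <= point <= upper`` is not guaranteed — but
    ``lower <= upper`` always is.
    """

    point: float
    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def sample_schedule(
    s: AbridgedSchedule,
    z: float | np.ndarray,
    spec: UncertaintySpec,
) -> AbridgedSchedule:
    """One split-normal perturbation of a schedule.

    For ``z >= 0`` the value moves towards (and at ``z = q`` exactly
    onto) the upper bound; for ``z < 0`` towards the lower bound, where
    ``q`` is the input-level normal quantile.  Schedules without
    intervals are returned unchanged.  Death probabilities are clipped to
    [0, 1] and expectancies to nonnegative, with clip counts logged; the
    cross-measure constraint hale <= ex is applied by the caller, which
    sees both sampled schedules.
    """
    if not s.has_interval:
        return s.replace_values(s.values)
    z = np.asarray(z, dtype=float)
    if z.ndim not in (0, 1) or (z.ndim == 1 and z.size != s.n_groups):
        raise ValueError("z must be scalar or one value per age group")
    if np.any(s.upper < s.lower):
        raise ValueError("upper bound below lower bound")
    q = spec.input_quantile
    up = (s.upper - s.values) / q
    down = (s.values - s.lower) / q
    vals = s.values + np.where(z >= 0, z * up, z * down)
    if s.measure == "death_probability":
        clipped = np.clip(vals, 0.0, 1.0)
    else:
        clipped = np.maximum(vals, 0.0)
    n_clip = int(np.sum(clipped != vals))
    if n_clip:
        logger.debug("clipped %d sampled %s value(s) to domain", n_clip,
                     s.measure)
    return s.replace_values(clipped)


def _draw_z(rng: np.random.Generator, spec: UncertaintySpec,
            n_ages: int) -> float | np.ndarray:
    if spec.correlation == "shared-z":
        return float(rng.standard_normal())
    return rng.standard_normal(n_ages)


def sample_inputs(
    qx: AbridgedSchedule,
    ex: AbridgedSchedule,
    hale: AbridgedSchedule,
    rng: np.random.Generator,
    spec: UncertaintySpec,
    nax: np.ndarray | None = None,
) -> tuple[AbridgedSchedule, AbridgedSchedule, AbridgedSchedule]:
    """One life-table-coherent joint draw of the three input schedules.

    Three independent z's are drawn, one per measure, but applied so that
    every draw remains an internally consistent life table: ``z_q``
    perturbs the death probabilities; the draw's ``ex`` schedule is then
    *derived* by rebuilding the life table from the sampled ``qx`` with
    the point-estimate ``nax`` values, with ``z_e`` entering through the
    sampled open-group expectancy; ``z_h`` perturbs ``hale``, clipped to
    the draw's ``ex``.

    Sampling the published qx and ex intervals independently of each
    other would be incoherent — both derive from one underlying life
    table — and the ``nax`` recovery amplifies any mismatch by a factor
    of order ``nLx/ndx``, which dwarfs the signal at low-mortality ages.

    ``nax`` defaults to the values recovered from the point estimates.
    """
    from .lifetable import build_life_table, recover_ax

    k = qx.n_groups
    if nax is None:
        nax = recover_ax(qx, ex, mode="clamp").nax
    q_s = sample_schedule(qx, _draw_z(rng, spec, k), spec)
    e_s = sample_schedule(ex, _draw_z(rng, spec, k), spec)
    h_s = sample_schedule(hale, _draw_z(rng, spec, k), spec)
    lt = build_life_table(qx.grid, q_s.values, nax.copy(),
                          e_last=float(e_s.values[-1]))
    e_d = AbridgedSchedule(qx.grid.copy(), lt.ex, "life_expectancy")
    clipped = np.minimum(h_s.values, lt.ex)
    n_clip = int(np.sum(clipped != h_s.values))
    if n_clip:
        logger.debug("clipped %d sampled hale value(s) to the draw's ex",
                     n_clip)
    return q_s, e_d, h_s.replace_values(clipped)


def perturb_inputs(
    qx: AbridgedSchedule,
    ex: AbridgedSchedule,
    hale: AbridgedSchedule,
    rng: np.random.Generator,
    spec: UncertaintySpec,
) -> tuple[AbridgedSchedule, AbridgedSchedule, AbridgedSchedule]:
    """Simulate *observing* noisy inputs: one coherent joint draw,
    re-equipped with intervals of the original absolute half-widths
    centred on the drawn values (clipped to each measure's domain).

    This is the replication operator for coverage studies: data generated
    this way carry intervals calibrated to the very noise process the
    Monte Carlo machinery assumes.
    """
    drawn = sample_inputs(qx, ex, hale, rng, spec)
    out = []
    for orig, new in zip((qx, ex, hale), drawn):
        lo_w = orig.values - orig.lower
        hi_w = orig.upper - orig.values
        lower = new.values - lo_w
        upper = new.values + hi_w
        if orig.measure == "death_probability":
            lower, upper = np.clip(lower, 0, 1), np.clip(upper, 0, 1)
        else:
            lower = np.maximum(lower, 0.0)
        lower = np.minimum(lower, new.values)
        upper = np.maximum(upper, new.values)
        out.append(AbridgedSchedule(orig.grid.copy(), new.values,
                                    orig.measure, lower, upper))
    return tuple(out)


class UnstableDrawsError(RuntimeError):
    """Raised when too many Monte Carlo draws fail the pipeline."""


def monte_carlo_ui(
    qx: AbridgedSchedule,
    ex: AbridgedSchedule,
    hale: AbridgedSchedule,
    spec: UncertaintySpec,
    indicator=None,
) -> dict[str, IntervalSummary]:
    """Empirical uncertainty intervals for every indicator.

    Runs ``indicator`` (a callable mapping (qx, ex, hale) schedules to a
    dict of scalars; defaults to the full reconstruction pipeline in
    clamp mode) once on the point estimates and once per draw.  Bounds
    are the (1 - level)/2 and (1 + level)/2 empirical quantiles across
    successful draws (linear, "type 7", interpolation).  Draws on which
    the pipeline raises are dropped and counted; more than
    ``spec.max_failure_rate`` failures aborts with diagnostics.
    """
    from .lifetable import recover_ax

    if indicator is None:
        from .pipeline import indicator_values

        indicator = lambda q, e, h: indicator_values(q, e, h, mode="clamp")

    point = indicator(qx, ex, hale)
    names = list(point)
    nax_point = recover_ax(qx, ex, mode="clamp").nax
    rng = np.random.default_rng(spec.seed)
    draws = np.full((spec.n_draws, len(names)), np.nan)
    failures: list[str] = []
    for d in range(spec.n_draws):
        q_s, e_s, h_s = sample_inputs(qx, ex, hale, rng, spec, nax=nax_point)
        try:
            vals = indicator(q_s, e_s, h_s)
        except (ValueError, ZeroDivisionError, FloatingPointError) as err:
            failures.append(str(err))
            continue
        draws[d] = [vals[n] for n in names]
    ok = ~np.isnan(draws[:, 0])
    n_fail = spec.n_draws - int(ok.sum())
    if n_fail > spec.max_failure_rate * spec.n_draws:
        examples = "; ".join(failures[:3])
        raise UnstableDrawsError(
            f"{n_fail}/{spec.n_draws} Monte Carlo draws failed "
            f"(first errors: {examples})"
        )
    if n_fail:
        logger.warning("dropped %d/%d failed Monte Carlo draws", n_fail,
                       spec.n_draws)
    lo_q, hi_q = (1.0 - spec.level) / 2.0, (1.0 + spec.level) / 2.0
    lower = np.quantile(draws[ok], lo_q, axis=0)
    upper = np.quantile(draws[ok], hi_q, axis=0)
    return {
        name: IntervalSummary(point=float(point[name]), lower=float(lower[i]),
                              upper=float(upper[i]), level=spec.level)
        for i, name in enumerate(names)
    }
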