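"""Morbidity curves: survival in good health, recovered from HALE.

Health-adjusted life expectancy (HALE) is published as an age schedule,
but the underlying morbidity curve — the proportion of a cohort still in
good health at each age, written ``lstar`` here — is not.  Under the
Sullivan no-recovery assumption (once an individual leaves good health
they do not return), the healthy person-years identity

    Tstar(x) = hale(x) * lx

determines the healthy person-years lived in each interval by first
differences, and the within-interval timing of exits from health (taken
to be the mortality ``nax``) then determines ``lstar`` by a backward
recursion from the open age group.

The forward operator :func:`sullivan_hale` (morbidity curve -> HALE) is
the exact inverse and serves as the oracle for the reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .schedules import AbridgedSchedule

logger = logging.getLogger(__name__)

#: Curve-consistency tolerance, per unit radix.
CURVE_TOL = 1e-8


@dataclass
class MorbidityCurve:
    """Survival in good health on an abridged grid.

    ``lstar`` is the number still in good health at exact age ``x`` (same
    radix as the life table); ``ndstar = lstar_x - lstar_{x+n}`` are
    morbidity onsets in the interval; ``nLstar`` / ``Tstar`` are healthy
    person-years within / above the interval; ``hale`` is the remaining
    health-adjusted life expectancy.  The source life table rides along so
    onset distributions can reuse its ``nax`` and open-group ``ex``.
    """

    x: np.ndarray
    n: np.ndarray
    lstar: np.ndarray
    ndstar: np.ndarray
    nLstar: np.ndarray
    Tstar: np.ndarray
    hale: np.ndarray
    lifetable: LifeTable

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "n": self.n, "lstar": self.lstar,
             "ndstar": self.ndstar, "nLstar": self.nLstar,
             "Tstar": self.Tstar, "hale": self.hale}
        )


def sullivan_hale(lt: LifeTable, lstar: np.ndarray) -> AbridgedSchedule:
    """Forward Sullivan operator: HALE schedule from a morbidity curve.

    Healthy person-years in a closed interval combine those who stay
    healthy through it with those who exit during it, exits being timed at
    the interval's ``nax``::

        nLstar = nax * lstar_x + (n - nax) * lstar_{x+n}
               = n * lstar_{x+n} + nax * (lstar_x - lstar_{x+n})

    Those entering the open group in good health are assigned its mean
    remaining lifetime ``ex(last)`` as healthy time.  Then
    ``hale(x) = sum of nLstar at and above x, divided by lx``.
    """
    lstar = np.asarray(lstar, float)
    if lstar.shape != lt.x.shape:
        raise ValueError("lstar must align with the life table grid")
    tol = CURVE_TOL * lt.radix
    if np.any(lstar < -tol) or np.any(lstar > lt.lx + tol):
        raise ValueError("lstar must satisfy 0 <= lstar <= lx")
    if np.any(np.diff(lstar) > tol):
        raise ValueError("lstar must be non-increasing (no recovery)")

    k = lt.n_groups
    nLstar = np.empty(k)
    nLstar[:-1] = lt.nax[:-1] * lstar[:-1] + (lt.n[:-1] - lt.nax[:-1]) * lstar[1:]
    nLstar[-1] = lt.ex[-1] * lstar[-1]
    Tstar = np.cumsum(nLstar[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        hale = np.where(lt.lx > 0, Tstar / lt.lx, 0.0)
    return AbridgedSchedule(lt.x.copy(), hale, "hale")


def reconstruct_morbidity_curve(
    lt: LifeTable,
    hale: AbridgedSchedule,
    mode: str = "clamp",
) -> MorbidityCurve:
    """Invert the Sullivan operator: morbidity curve from a HALE schedule.

    The healthy person-years columns follow from ``Tstar = hale * lx`` by
    first differences.  The open group's curve value is its healthy
    person-years spread over the group's mean lifetime,
    ``lstar(last) = nLstar(last) / ex(last)``, mirroring the exact
    identity ``lx(last) = nLx(last) / ex(last)``.  Closed groups then
    follow backwards::

        lstar_x = (nLstar - (n - nax) * lstar_{x+n}) / nax

    Parameters
    ----------
    mode
        ``strict``: any violation of ``0 <= lstar <= lx`` or of
        monotonicity beyond tolerance raises, naming the first offending
        age — used in tests and on coherent data.  ``clamp`` (default):
        ``hale`` is first clipped to ``[0, ex]``, the reconstructed curve
        is projected onto ``[0, lx]``, and monotone non-increase is
        enforced by a running maximum from the oldest age; every
        adjustment is logged.  Healthy person-years are conserved in both
        modes because ``nLstar`` comes from the telescoping ``Tstar``
        differences, not from the (possibly adjusted) curve.
    """
    if mode not in ("strict", "clamp"):
        raise ValueError(f"unknown mode {mode!r}")
    if hale.grid.shape != lt.x.shape or not np.allclose(hale.grid, lt.x):
        raise ValueError("hale schedule is not on the life table grid")
    h = hale.values.astype(float).copy()
    tol = CURVE_TOL * lt.radix

    excess = (h > lt.ex + tol) | (h < -tol)
    if mode == "strict":
        if np.any(excess):
            i = int(np.argmax(excess))
            raise ValueError(
                f"hale = {h[i]:.6g} outside [0, ex = {lt.ex[i]:.6g}] at age "
                f"{lt.x[i]:g}"
            )
    elif np.any(excess):
        logger.info("clamp mode: clipped hale to [0, ex] at %d age(s)",
                    int(excess.sum()))
    h = np.clip(h, 0.0, lt.ex)

    k = lt.n_groups
    Tstar = h * lt.lx
    nLstar = np.concatenate([Tstar[:-1] - Tstar[1:], [Tstar[-1]]])

    if mode == "strict" and np.any(lt.nax[:-1] <= 0):
        i = int(np.argmax(lt.nax[:-1] <= 0))
        raise ValueError(f"degenerate interval: nax = 0 at age {lt.x[i]:g}")

    lstar = np.empty(k)
    lstar[-1] = (nLstar[-1] / lt.ex[-1]
                 if lt.lx[-1] > 0 and lt.ex[-1] > 0 else 0.0)
    for i in range(k - 2, -1, -1):
        ax = lt.nax[i]
        if ax <= 0:  # only reachable in clamp mode
            lstar[i] = lstar[i + 1]
            continue
        lstar[i] = (nLstar[i] - (lt.n[i] - ax) * lstar[i + 1]) / ax

    violations = (
        (lstar < -tol) | (lstar > lt.lx + tol)
        | np.concatenate([np.diff(lstar) > tol, [False]])
    )
    if mode == "strict":
        if np.any(violations):
            i = int(np.argmax(violations))
            raise ValueError(
                f"reconstructed morbidity curve invalid at age {lt.x[i]:g} "
                f"(lstar = {lstar[i]:.6g}, lx = {lt.lx[i]:.6g})"
            )
        lstar = np.clip(lstar, 0.0, lt.lx)
    else:
        n_adjust = int(violations.sum())
        lstar = np.clip(lstar, 0.0, lt.lx)
        # no-recovery projection: sweep from the oldest age upwards
        lstar = np.maximum.accumulate(lstar[::-1])[::-1]
        lstar = np.minimum(lstar, lt.lx)
        if n_adjust:
            logger.info("clamp mode: adjusted morbidity curve at %d age(s)",
                        n_adjust)

    ndstar = np.concatenate([lstar[:-1] - lstar[1:], [lstar[-1]]])
    return MorbidityCurve(lt.x.copy(), lt.n.copy(), lstar, ndstar, nLstar,
                          Tstar, h, lt)
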