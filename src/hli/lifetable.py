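"""Abridged period life tables, forwards and backwards.

The forward direction is classical: given death probabilities ``nqx`` and
the mean person-years ``nax`` lived in each interval by those dying in it,
build the survivorship column ``lx`` and the person-years columns ``nLx``,
``Tx`` and remaining expectancy ``ex``.

The backward direction is the step this package exists for: published
abridged tables (e.g. GBD results-tool extracts) report ``nqx`` and ``ex``
but not ``nax``.  Because ``Tx = ex * lx`` determines every person-years
column, the ``nax`` values can be recovered exactly::

    nax = (nLx - n * l_{x+n}) / ndx        (closed groups, ndx > 0)
    nax = ex                               (open-ended last group)

These recovered ``nax`` pin down the mean age at death within each
interval (``x + nax``) and are reused downstream to time morbidity onsets
within intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedules import AbridgedSchedule, check_same_grid

logger = logging.getLogger(__name__)

#: Slack allowed on recovered nax before a hard consistency error
#: (published qx/ex pairs carry rounding incoherence).
NAX_TOL = 1e-6

#: In clamp mode, floor on nax as a fraction of the interval width, so the
#: downstream morbidity recursion never divides by (near) zero.
NAX_CLAMP_FLOOR = 0.01


@dataclass
class LifeTable:
    """A complete abridged life table.

    Columns follow standard demographic notation.  ``x`` are group start
    ages; ``n`` are interval widths (``nan`` for the open last group);
    ``qx`` death probabilities; ``lx`` survivors at exact age ``x`` (in
    units of ``radix``); ``ndx`` deaths in the interval; ``nax`` mean
    person-years lived in the interval by those dying in it; ``nLx``
    person-years lived in the interval; ``Tx`` person-years lived above
    ``x``; ``ex`` remaining life expectancy.
    """

    x: np.ndarray
    n: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    ndx: np.ndarray
    nax: np.ndarray
    nLx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray
    radix: float = 1.0

    @property
    def n_groups(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        """Serialize to the documented tabular layout."""
        return pd.DataFrame(
            {"x": self.x, "n": self.n, "qx": self.qx, "lx": self.lx,
             "ndx": self.ndx, "nax": self.nax, "nLx": self.nLx,
             "Tx": self.Tx, "ex": self.ex}
        )


def lx_from_qx(qx: AbridgedSchedule, radix: float = 1.0) -> AbridgedSchedule:
    """Survivorship column from death probabilities.

    ``l(first) = radix`` and ``l_{x+n} = lx * (1 - nqx)``.  The open last
    group's ``qx`` is implicitly 1 and does not enter.
    """
    if radix <= 0:
        raise ValueError("radix must be positive")
    q = qx.values
    bad = (q < 0) | (q > 1)
    if np.any(bad):
        raise ValueError(
            f"death probability outside [0, 1] at age {qx.grid[np.argmax(bad)]:g}"
        )
    lx = radix * np.concatenate([[1.0], np.cumprod(1.0 - q[:-1])])
    return AbridgedSchedule(qx.grid.copy(), lx, "survivors")


def _widths(grid: np.ndarray) -> np.ndarray:
    return np.concatenate([np.diff(grid), [np.nan]])


def build_life_table(
    grid: np.ndarray,
    qx: np.ndarray,
    nax: np.ndarray,
    e_last: float,
    radix: float = 1.0,
) -> LifeTable:
    """Forward life-table construction from (qx, nax) plus the open-group
    expectancy.

    ``nax`` entries for closed groups must lie in ``[0, n]``; the last
    entry is ignored and replaced by ``e_last`` (for the open group,
    ``nax = ex`` by definition).  This is the oracle against which the
    backward recovery is tested, and the route the synthetic generator
    uses.
    """
    grid = np.asarray(grid, float)
    qx = np.asarray(qx, float)
    nax = np.asarray(nax, float).copy()
    k = grid.size
    n = _widths(grid)
    if np.any((nax[:-1] < 0) | (nax[:-1] > n[:-1])):
        raise ValueError("closed-group nax outside [0, n]")
    lx = radix * np.concatenate([[1.0], np.cumprod(1.0 - qx[:-1])])
    ndx = np.concatenate([lx[:-1] - lx[1:], [lx[-1]]])
    nax[-1] = e_last
    nLx = np.empty(k)
    nLx[:-1] = n[:-1] * lx[1:] + nax[:-1] * ndx[:-1]
    nLx[-1] = e_last * lx[-1]
    Tx = np.cumsum(nLx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)
    q_full = np.concatenate([qx[:-1], [1.0]])
    return LifeTable(grid, n, q_full, lx, ndx, nax, nLx, Tx, ex, radix)


def recover_ax(
    qx: AbridgedSchedule,
    ex: AbridgedSchedule,
    radix: float = 1.0,
    mode: str = "strict",
    tol: float = NAX_TOL,
) -> LifeTable:
    """Recover the full life table — including ``nax`` — from published
    (qx, ex) schedules.

    ``Tx = ex * lx`` gives the person-years columns by first differences,
    from which ``nax`` follows for every closed group with deaths.  Groups
    with ``ndx = 0`` take the conventional midpoint ``nax = n / 2``.  The
    open group has ``nax = ex(last)``.

    Parameters
    ----------
    mode
        ``strict`` (default): recovered ``nax`` outside ``[-tol, n + tol]``
        raises a consistency error naming the age; small excursions are
        clipped with a logged warning.  ``clamp``: any excursion is
        projected onto ``[0.01 * n, n]`` with a logged count — used when
        propagating sampled (hence mutually incoherent) qx/ex pairs.
    """
    if mode not in ("strict", "clamp"):
        raise ValueError(f"unknown mode {mode!r}")
    grid = check_same_grid(qx, ex)
    k = grid.size
    n = _widths(grid)
    lx = lx_from_qx(qx, 1.0).values  # internal radix 1; radix is presentation
    e = ex.values
    if np.any((lx > 0) & (e <= 0) & (np.arange(k) < k - 1)):
        raise ValueError("ex must be positive where survivors remain")

    ndx = np.concatenate([lx[:-1] - lx[1:], [lx[-1]]])
    Tx = e * lx
    nLx = np.concatenate([Tx[:-1] - Tx[1:], [Tx[-1]]])

    nax = np.full(k, np.nan)
    closed = slice(0, k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cand = (nLx[closed] - n[closed] * lx[1:]) / ndx[closed]
    nax[closed] = np.where(ndx[closed] > 0, cand, n[closed] / 2.0)
    nax[-1] = e[-1]

    lo, hi = np.zeros(k - 1), n[:-1]
    out_of_range = (nax[:-1] < lo) | (nax[:-1] > hi)
    if mode == "strict":
        hard = (nax[:-1] < lo - tol) | (nax[:-1] > hi + tol)
        if np.any(hard):
            i = int(np.argmax(hard))
            raise ValueError(
                f"recovered nax = {nax[i]:.6g} outside [0, {hi[i]:g}] at age "
                f"{grid[i]:g}: qx and ex are mutually incoherent"
            )
        if np.any(out_of_range):
            logger.warning(
                "clipped %d recovered nax value(s) within tolerance",
                int(out_of_range.sum()),
            )
        nax[:-1] = np.clip(nax[:-1], lo, hi)
    else:
        if np.any(out_of_range):
            logger.info(
                "clamp mode: projected %d nax value(s) onto [%.2f*n, n]",
                int(out_of_range.sum()), NAX_CLAMP_FLOOR,
            )
        nax[:-1] = np.clip(nax[:-1], NAX_CLAMP_FLOOR * n[:-1], hi)

    # lx = 0 tail: downstream quantities are zero and carry no events.
    dead = lx <= 0
    Tx[dead] = 0.0
    nLx[dead] = 0.0
    e = np.where(dead, 0.0, e)

    q_full = np.concatenate([qx.values[:-1], [1.0]])
    lt = LifeTable(grid, n, q_full, radix * lx, radix * ndx, nax,
                   radix * nLx, radix * Tx, e, radix)
    return lt
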