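"""Age-indexed schedules on an abridged age grid.

An :class:`AbridgedSchedule` holds one age-specific quantity (a death
probability ``qx``, a remaining life expectancy ``ex``, or a remaining
health-adjusted life expectancy ``hale``) on a shared grid of age-group
start ages.  Age intervals are half-open ``[x, x + n)``; the last group is
open-ended (``[x, inf)``).  The default grid is the abridged grid used by
the Global Burden of Disease (GBD) results tool: ``<1``, ``1-4``, then
5-year groups up to the open group ``95+``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Valid measures carried by a schedule.  ``survivors`` is internal (the
#: lx column viewed as a schedule); the other three arrive from data.
MEASURES = ("death_probability", "life_expectancy", "hale", "survivors")

#: GBD abridged grid: 0, 1, 5, 10, ..., 95 (open-ended last group).
GBD_GRID = np.array([0, 1] + list(range(5, 100, 5)), dtype=float)


@dataclass
class AbridgedSchedule:
    """One age-specific quantity on an abridged age grid.

    Parameters
    ----------
    grid
        Strictly increasing age-group start ages in years.  The last group
        is open-ended.
    values
        Point estimates aligned to ``grid``.
    measure
        One of ``death_probability``, ``life_expectancy`` or ``hale``.
    lower, upper
        Optional aligned uncertainty-interval bounds, ``lower <= values <=
        upper`` elementwise.
    """

    grid: np.ndarray
    values: np.ndarray
    measure: str
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be a 1-d array with at least 2 groups")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.values.shape != self.grid.shape:
            raise ValueError("values must align with grid")
        for name in ("lower", "upper"):
            bound = getattr(self, name)
            if bound is not None:
                bound = np.asarray(bound, dtype=float)
                if bound.shape != self.grid.shape:
                    raise ValueError(f"{name} must align with grid")
                setattr(self, name, bound)
        if self.lower is not None and self.upper is not None:
            bad = (self.lower > self.values + 1e-12) | (
                self.upper < self.values - 1e-12
            )
            if np.any(bad):
                age = self.grid[np.argmax(bad)]
                raise ValueError(
                    f"interval does not bracket point estimate at age {age:g}"
                )
        if self.measure == "death_probability":
            bad = (self.values < 0) | (self.values > 1)
            if np.any(bad):
                age = self.grid[np.argmax(bad)]
                raise ValueError(f"death probability outside [0, 1] at age {age:g}")
        elif np.any(self.values < 0):
            age = self.grid[np.argmax(self.values < 0)]
            raise ValueError(f"{self.measure} negative at age {age:g}")

    @property
    def n_groups(self) -> int:
        return self.grid.size

    @property
    def closed_widths(self) -> np.ndarray:
        """Widths ``n`` of the closed groups (length ``n_groups - 1``)."""
        return np.diff(self.grid)

    @property
    def has_interval(self) -> bool:
        return self.lower is not None and self.upper is not None

    def value_at(self, age: float) -> float:
        """Point estimate at a grid start age; error if ``age`` is off-grid."""
        idx = np.flatnonzero(np.isclose(self.grid, age))
        if idx.size == 0:
            raise ValueError(f"age {age:g} is not a grid start age")
        return float(self.values[idx[0]])

    def replace_values(self, values: np.ndarray) -> "AbridgedSchedule":
        """Copy of this schedule with new point values and no intervals."""
        return AbridgedSchedule(self.grid.copy(), np.asarray(values, float),
                                self.measure)


def check_same_grid(*schedules: AbridgedSchedule) -> np.ndarray:
    """Return the shared grid, raising if the schedules' grids differ."""
    grid = schedules[0].grid
    for s in schedules[1:]:
        if s.grid.shape != grid.shape or not np.allclose(s.grid, grid):
            raise ValueError("schedules are not on a common age grid")
    return grid
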