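"""Shared fixtures: random but valid life tables and morbidity curves."""

from __future__ import annotations

import numpy as np
import pytest

import hli
from hli.lifetable import build_life_table
from hli.schedules import GBD_GRID, AbridgedSchedule


def make_random_life_table(rng: np.random.Generator,
                           grid: np.ndarray = GBD_GRID) -> hli.LifeTable:
    """A demographically shaped random life table: U-shaped death
    probabilities, deaths early in the infant interval, mid-interval
    elsewhere."""
    k = grid.size
    n = np.diff(grid)
    qx = np.empty(k - 1)
    qx[0] = rng.uniform(0.002, 0.08)                      # infant
    qx[1:] = np.clip(
        rng.uniform(0.0005, 0.01, k - 2)
        * np.exp(0.06 * grid[1:-1] * rng.uniform(0.8, 1.2)),
        0.0, 0.7,
    )
    nax = np.empty(k)
    nax[0] = rng.uniform(0.1, 0.5) * n[0]
    nax[1:-1] = rng.uniform(0.35, 0.65, k - 2) * n[1:]
    e_last = rng.uniform(1.5, 6.0)
    return build_life_table(grid, np.append(qx, 1.0), nax, e_last)


def make_random_lstar(rng: np.random.Generator, lt: hli.LifeTable) -> np.ndarray:
    """A random valid morbidity curve: non-increasing, within [0, lx]."""
    frac = np.cumprod(rng.uniform(0.75, 1.0, lt.n_groups))
    return lt.lx * frac


@pytest.fixture(scope="session")
def demo_population() -> hli.SyntheticPopulation:
    return hli.make_synthetic_population(hli.SyntheticModel())


@pytest.fixture(scope="session")
def battery_populations() -> list[hli.SyntheticPopulation]:
    """A dozen random synthetic populations for cross-cutting checks."""
    rng = np.random.default_rng(7_301)
    return [hli.make_synthetic_population(hli.random_model(rng))
            for _ in range(12)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)


def schedules_from_table(lt: hli.LifeTable, hale_values: np.ndarray
                         ) -> tuple[AbridgedSchedule, AbridgedSchedule, AbridgedSchedule]:
    """Package a life table and a hale vector as pipeline inputs."""
    grid = lt.x
    qx = AbridgedSchedule(grid, lt.qx.copy(), "death_probability")
    ex = AbridgedSchedule(grid, lt.ex.copy(), "life_expectancy")
    hale = AbridgedSchedule(grid, np.asarray(hale_values, float), "hale")
    return qx, ex, hale
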