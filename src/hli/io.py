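"""Reading GBD-results-tool-style CSV extracts and writing indicator tables.

Results-tool exports are long tables with one row per (measure, location,
sex, year, age group) and ``val``/``lower``/``upper`` columns.  Header
names vary across tool versions, so the column mapping is configuration:
a mapping from canonical names (``location``, ``sex``, ``year``, ``age``,
``val``, ``lower``, ``upper``, and optionally ``measure``) to the header
actually present, loadable from YAML/JSON.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .schedules import AbridgedSchedule

#: Candidate headers per canonical column, tried in order.
DEFAULT_COLUMN_CANDIDATES = {
    "location": ("location", "location_name"),
    "sex": ("sex", "sex_name"),
    "year": ("year", "year_id"),
    "age": ("age", "age_name", "age_group", "age_group_name"),
    "val": ("val", "value", "mean"),
    "lower": ("lower",),
    "upper": ("upper",),
    "measure": ("measure", "measure_name"),
}

#: Results-tool measure labels (lowercased) per canonical measure.
DEFAULT_MEASURE_LABELS = {
    "death_probability": {"probability of death", "death probability",
                          "death_probability", "qx"},
    "life_expectancy": {"life expectancy", "life_expectancy", "ex"},
    "hale": {"hale", "hale (healthy life expectancy)",
             "healthy life expectancy (hale)", "healthy life expectancy"},
}

_SEX_LABELS = {"female": "female", "females": "female",
               "male": "male", "males": "male",
               "both": "both", "both sexes": "both"}

_RE_UNDER = re.compile(r"^<\s*(\d+)")
_RE_RANGE = re.compile(r"^(\d+)\s*(?:to|-|–)\s*(\d+)")
_RE_OPEN = re.compile(r"^(\d+)\s*(?:plus|\+)")
_RE_SINGLE = re.compile(r"^(\d+)\s*(?:year|years)?\s*$")


def parse_age_label(label: str) -> tuple[float, bool]:
    """Start age and open-endedness of a results-tool age-group label.

    ``"<1 year" -> (0, False)``, ``"1 to 4" -> (1, False)``,
    ``"95 plus" -> (95, True)``.
    """
    text = str(label).strip().lower()
    if m := _RE_UNDER.match(text):
        return 0.0, False
    if m := _RE_RANGE.match(text):
        return float(m.group(1)), False
    if m := _RE_OPEN.match(text):
        return float(m.group(1)), True
    if m := _RE_SINGLE.match(text):
        return float(m.group(1)), False
    raise ValueError(f"unparseable age-group label {label!r}")


def load_column_map(path: str | Path) -> dict:
    """Column map from a YAML (or JSON, a YAML subset) config file."""
    with open(path, encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValueError("column map config must be a mapping")
    return mapping


def _resolve_columns(columns, column_map: dict | None) -> dict:
    resolved = {}
    for canon, candidates in DEFAULT_COLUMN_CANDIDATES.items():
        if column_map and canon in column_map:
            candidates = (column_map[canon],)
        hit = next((c for c in candidates if c in columns), None)
        if hit is None and canon not in ("measure", "lower", "upper"):
            raise ValueError(f"no column found for {canon!r} "
                             f"(tried {', '.join(candidates)})")
        if hit is not None:
            resolved[canon] = hit
    return resolved


def read_gbd_table(
    source,
    measure: str,
    column_map: dict | None = None,
    measure_labels: dict | None = None,
) -> dict[tuple[str, str, int], AbridgedSchedule]:
    """Read one measure from a results-tool-style CSV into schedules
    keyed by (location, sex, year).

    ``source`` is anything :func:`pandas.read_csv` accepts, or an
    already-loaded DataFrame.  If the table has a measure column, rows
    are filtered to ``measure``'s known labels; otherwise the whole table
    is taken to be that measure.  Every key must carry the full age grid
    (the union of ages seen in the table): a gap raises an error naming
    the key and the missing start age, as does a duplicate (key, age).
    """
    if measure not in DEFAULT_MEASURE_LABELS:
        raise ValueError(f"unknown measure {measure!r}")
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    cols = _resolve_columns(df.columns, column_map)

    if "measure" in cols:
        labels = (measure_labels or DEFAULT_MEASURE_LABELS)[measure]
        mask = df[cols["measure"]].astype(str).str.strip().str.lower().isin(labels)
        df = df.loc[mask]
        if df.empty:
            raise ValueError(f"no rows matched measure {measure!r}")

    parsed = df[cols["age"]].map(parse_age_label)
    df = df.assign(
        _start=[p[0] for p in parsed],
        _open=[p[1] for p in parsed],
        _sex=df[cols["sex"]].astype(str).str.strip().str.lower().map(_SEX_LABELS),
    )
    if df["_sex"].isna().any():
        bad = df.loc[df["_sex"].isna(), cols["sex"]].iloc[0]
        raise ValueError(f"unrecognised sex label {bad!r}")

    grid = np.array(sorted(df["_start"].unique()), dtype=float)
    out: dict[tuple[str, str, int], AbridgedSchedule] = {}
    grouped = df.groupby([cols["location"], "_sex", cols["year"]], sort=True)
    for (loc, sex, year), g in grouped:
        key = (str(loc), str(sex), int(year))
        if g["_start"].duplicated().any():
            age = g.loc[g["_start"].duplicated(), "_start"].iloc[0]
            raise ValueError(f"duplicate age group {age:g} for key {key}")
        missing = np.setdiff1d(grid, g["_start"].to_numpy())
        if missing.size:
            raise ValueError(
                f"missing age group starting at {missing[0]:g} for key {key}"
            )
        g = g.sort_values("_start")
        has_bounds = "lower" in cols and "upper" in cols
        out[key] = AbridgedSchedule(
            grid=g["_start"].to_numpy(dtype=float),
            values=g[cols["val"]].to_numpy(dtype=float),
            measure=measure,
            lower=g[cols["lower"]].to_numpy(dtype=float) if has_bounds else None,
            upper=g[cols["upper"]].to_numpy(dtype=float) if has_bounds else None,
        )
    if not out:
        raise ValueError("no data rows found")
    return out


def read_input_bundle(
    source, column_map: dict | None = None
) -> dict[tuple, tuple[AbridgedSchedule, AbridgedSchedule, AbridgedSchedule]]:
    """Read all three measures from one long table and align them by key."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    per_measure = {
        m: read_gbd_table(df, m, column_map=column_map)
        for m in ("death_probability", "life_expectancy", "hale")
    }
    keys = set(per_measure["death_probability"])
    for m, tables in per_measure.items():
        if set(tables) != keys:
            diff = keys.symmetric_difference(tables)
            raise ValueError(f"keys differ across measures near {sorted(diff)[:3]}")
    return {
        k: (per_measure["death_probability"][k],
            per_measure["life_expectancy"][k],
            per_measure["hale"][k])
        for k in sorted(keys)
    }


def write_indicators(rows, destination) -> pd.DataFrame:
    """Write indicator rows as a tidy CSV, one row per (location, sex,
    year); point, lower and upper columns per indicator.  Returns the
    frame written.  Values are written with 12 significant digits so a
    write/read round trip preserves at least 10."""
    records = [r.to_record() for r in rows]
    if records:
        frame = pd.DataFrame(records)
    else:
        frame = pd.DataFrame(
            columns=["location", "sex", "year", "inequality_measure"]
        )
    frame.to_csv(destination, index=False, float_format="%.12g")
    return frame


def read_indicators(source) -> pd.DataFrame:
    """Read a tidy indicator CSV back into a DataFrame."""
    return pd.read_csv(source)
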