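"""Tissue CSV readers/writers and result serialization.

Tissue CSV dialect: comma-separated UTF-8, one row per specimen, nutrient
columns named with a unit suffix ("N_g_kg", "Cu_mg_kg"), an optional
"yield_kg_tree" column and an optional leading "specimen" identifier
column.  All concentrations are normalized to mg kg^-1 at read time, the
single scale on which closure and the filling value are defined.  Values
printed with a typographic minus sign are accepted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .roc import ROCCurve

YIELD_COLUMN = "yield_kg_tree"
ID_COLUMN = "specimen"

#: multiplicative factors to mg kg^-1 per recognised unit suffix
UNIT_FACTORS = {
    "mg_kg": 1.0,
    "g_kg": 1e3,
    "pct": 1e4,  # percent of dry mass
}


def split_unit_suffix(column: str) -> tuple[str, str | None]:
    """Split "N_g_kg" -> ("N", "g_kg"); unknown suffixes return (column, None)."""
    for suffix in sorted(UNIT_FACTORS, key=len, reverse=True):
        if column.endswith("_" + suffix):
            return column[: -len(suffix) - 1], suffix
    return column, None


def read_tissue_csv(
    path,
    unit_map: dict[str, str] | None = None,
    yield_column: str = YIELD_COLUMN,
):
    """Read a tissue CSV into (nutrients in mg kg^-1, yields or None, ids).

    ``unit_map`` may override or supply units per raw column name.  Rows
    with non-numeric or non-positive concentrations are reported with their
    (1-based, header excluded) line numbers.
    """
    df = pd.read_csv(path, dtype=str).apply(lambda s: s.str.strip() if s.dtype == object else s)
    ids = None
    if ID_COLUMN in df.columns:
        ids = df.pop(ID_COLUMN)

    yields = None
    if yield_column in df.columns:
        yields = _numeric(df.pop(yield_column), yield_column)

    nutrients = {}
    for col in df.columns:
        name, suffix = split_unit_suffix(col)
        unit = (unit_map or {}).get(col, suffix)
        if unit is None:
            raise ValueError(
                f"column {col!r} has no recognised unit suffix and no unit_map entry"
            )
        if unit not in UNIT_FACTORS:
            raise ValueError(f"unknown unit {unit!r} for column {col!r}")
        vals = _numeric(df[col], col) * UNIT_FACTORS[unit]
        bad = np.flatnonzero(~(vals > 0))
        if bad.size:
            raise ValueError(
                f"non-positive concentration in column {col!r}, row {bad[0] + 1}"
            )
        nutrients[name] = vals
    table = pd.DataFrame(nutrients)
    if ids is not None:
        table.index = pd.Index(ids, name=ID_COLUMN)
        if yields is not None:
            yields = pd.Series(np.asarray(yields), index=table.index, name=yield_column)
    return table, yields, ids


def _numeric(series: pd.Series, col: str) -> np.ndarray:
    cleaned = series.astype(str).str.replace("−", "-", regex=False)
    vals = pd.to_numeric(cleaned, errors="coerce")
    bad = np.flatnonzero(vals.isna().to_numpy())
    if bad.size:
        raise ValueError(f"non-numeric value in column {col!r}, row {bad[0] + 1}")
    return vals.to_numpy(dtype=float)


def write_tissue_csv(path, nutrients_mg_kg: pd.DataFrame, yields=None) -> None:
    """Write the reader's dialect: mg kg^-1 suffixes plus the yield column."""
    out = nutrients_mg_kg.copy()
    out.columns = [f"{c}_mg_kg" for c in out.columns]
    if yields is not None:
        out[YIELD_COLUMN] = np.asarray(yields)
    label = out.index.name == ID_COLUMN
    out.to_csv(path, index=label)


def write_roc_csv(path, curve: ROCCurve) -> None:
    pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "sensitivity": curve.sensitivity,
            "specificity": curve.specificity,
        }
    ).to_csv(path, index=False)


def write_quadrants_csv(path, labels, distances, yields, ids=None) -> None:
    df = pd.DataFrame(
        {
            "distance": np.asarray(distances),
            YIELD_COLUMN: np.asarray(yields),
            "quadrant": np.asarray(labels),
        }
    )
    if ids is not None:
        df.insert(0, ID_COLUMN, np.asarray(ids))
    df.to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
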