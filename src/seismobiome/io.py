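"""Readers and writers for the study's tabular formats.

All formats are plain CSV/TSV. The catalog reader accepts either
Julian-day or ISO-8601 date columns and a configurable column mapping so
Utah Quarterly Seismicity Summary exports can be ingested directly. The
analyte table is wide (rows = sampling days) with below-detection cells
encoded as the string ``BD``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .community import OtuTable
from .crush import CrushExperiment
from .geochem import AnalyteTable

__all__ = [
    "read_catalog",
    "read_precip",
    "read_analyte_table",
    "write_analyte_table",
    "read_otu_table",
    "read_crush",
    "write_crush",
]

#: default column mapping: catalog-file header -> canonical name
CATALOG_COLUMNS = {
    "day": "day",
    "date": "day",
    "lat": "lat",
    "latitude": "lat",
    "lon": "lon",
    "longitude": "lon",
    "depth_km": "depth_km",
    "depth": "depth_km",
    "magnitude": "magnitude",
    "mag": "magnitude",
    "m": "magnitude",
}


def _to_julian_day(col: pd.Series) -> pd.Series:
    """Interpret a date column as fractional Julian day-of-year (one year)."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        return numeric.astype(float)
    ts = pd.to_datetime(col, utc=True, errors="raise")
    years = ts.dt.year.unique()
    if len(years) > 1:
        raise ValueError(
            f"catalog spans calendar years {sorted(years)}; day-of-year accumulation "
            "requires a single year"
        )
    frac = (ts.dt.hour * 3600 + ts.dt.minute * 60 + ts.dt.second) / 86400.0
    return ts.dt.dayofyear.astype(float) + frac


def read_catalog(path, column_map: dict | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read an earthquake catalog CSV/TSV into day/lat/lon/depth_km/magnitude.

    Rows with missing magnitude are dropped; the count is recorded in
    ``df.attrs['n_dropped']``.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    cmap = {**CATALOG_COLUMNS, **{k.lower(): v for k, v in (column_map or {}).items()}}
    df.columns = [cmap.get(str(c).strip().lower(), str(c).strip().lower()) for c in df.columns]
    required = {"day", "lat", "lon", "depth_km", "magnitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns {sorted(missing)}; found {list(df.columns)}")
    df["day"] = _to_julian_day(df["day"])
    mag = pd.to_numeric(df["magnitude"], errors="coerce")
    bad = mag.isna()
    if bad.any():
        dropped = [int(i) + 2 for i in df.index[bad]]  # 1-based file line numbers
        df = df.loc[~bad].copy()
        df.attrs["dropped_lines"] = dropped
    df["magnitude"] = pd.to_numeric(df["magnitude"])
    df.attrs["n_dropped"] = int(bad.sum())
    return df[["day", "lat", "lon", "depth_km", "magnitude"]].reset_index(drop=True)


def read_precip(path) -> pd.DataFrame:
    """Read daily precipitation CSV with ``day`` (Julian) and ``mm`` columns."""
    df = pd.read_csv(path)
    cols = {str(c).strip().lower(): c for c in df.columns}
    if "day" not in cols and "date" in cols:
        df["day"] = _to_julian_day(df[cols["date"]])
    elif "day" in cols:
        df["day"] = pd.to_numeric(df[cols["day"]])
    else:
        raise ValueError("precipitation file needs a 'day' or 'date' column")
    if "mm" not in cols:
        raise ValueError("precipitation file needs an 'mm' column")
    return pd.DataFrame({"day": df["day"], "mm": pd.to_numeric(df[cols["mm"]])})


def read_analyte_table(
    path, bd_token: str = "BD", filtered_variant_map: dict | None = None
) -> AnalyteTable:
    """Read a wide analyte CSV (rows = sampling days, first column = day).

    Cells equal to ``bd_token`` (case-insensitive) or empty are flagged
    below-detection. Filtered/unfiltered pairs are inferred from
    ``<name>_filt`` / ``<name>_unfilt`` column names unless a map is given.
    """
    raw = pd.read_csv(path, index_col=0, dtype=str)
    raw.index = pd.to_numeric(raw.index)
    bd = raw.apply(lambda s: s.str.strip().str.upper() == bd_token.upper()) | raw.isna()
    values = raw.apply(pd.to_numeric, errors="coerce").where(~bd)
    if filtered_variant_map is None:
        filtered_variant_map = {
            c: c.replace("_filt", "_unfilt")
            for c in values.columns
            if c.endswith("_filt") and c.replace("_filt", "_unfilt") in values.columns
        }
    return AnalyteTable(values=values, bd_mask=bd, filtered_variant_map=filtered_variant_map)


def write_analyte_table(table: AnalyteTable, path, bd_token: str = "BD") -> None:
    out = table.values.astype(object).where(~table.bd_mask, bd_token)
    out.to_csv(path, index_label="day")


def read_otu_table(abundance_path, annotations_path=None, sep: str = "\t") -> OtuTable:
    """Read an OTU × sample TSV plus an optional sidecar annotation TSV."""
    ab = pd.read_csv(abundance_path, sep=sep, index_col=0)
    ab.columns = [int(float(c)) if str(c).replace(".", "").isdigit() else c for c in ab.columns]
    ann = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep=sep, index_col=0)
        for col in ("autotroph", "responder"):
            if col in ann.columns:
                ann[col] = ann[col].astype(str).str.lower().isin(("true", "1", "yes"))
    return OtuTable(abundance=ab, annotations=ann)


def read_crush(path) -> dict[str, CrushExperiment]:
    """Read a long crush CSV (rock_type, replicate, hour, h2_nmol_per_g)."""
    df = pd.read_csv(path)
    out = {}
    for rock, grp in df.groupby("rock_type"):
        wide = grp.pivot(index="replicate", columns="hour", values="h2_nmol_per_g").sort_index()
        out[str(rock)] = CrushExperiment(
            rock_type=str(rock),
            times_h=np.asarray(wide.columns, dtype=float),
            h2_nmol_per_g=wide.to_numpy(dtype=float),
        )
    return out


def write_crush(experiments: dict[str, CrushExperiment], path) -> None:
    rows = []
    for rock, exp in experiments.items():
        for r, series in enumerate(exp.h2_nmol_per_g):
            for t, v in zip(exp.times_h, series):
                rows.append(
                    {"rock_type": rock, "replicate": r, "hour": t, "h2_nmol_per_g": v}
                )
    pd.DataFrame(rows).to_csv(path, index=False)
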