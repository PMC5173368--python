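"""Reading, validating and writing cave attribute tables.

The canonical on-disk format is a plain CSV with one header row; a schema
mapping absorbs third-party column dialects. Coordinates are consumed as
projected meters (an optional helper projects lon/lat through a UTM zone,
default 22S, the study region's zone).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MANDATORY_COLUMNS",
    "KNOWN_COLUMNS",
    "load_cave_table",
    "validate_cave_table",
    "save_cave_table",
    "write_geojson_points",
    "lonlat_to_utm",
]

MANDATORY_COLUMNS = ("cave_id", "x_m", "y_m")
BINARY_COLUMNS = ("guano", "detritus", "roots", "water_reservoirs",
                  "percolating_water", "troglobites", "rare_troglobites",
                  "bat_population")
NUMERIC_COLUMNS = ("x_m", "y_m", "length_m", "area_m2", "volume_m3",
                   "altitude_m", "richness", "troglobite_richness")
KNOWN_COLUMNS = MANDATORY_COLUMNS + (
    "report_id", "length_m", "area_m2", "volume_m3", "altitude_m",
) + BINARY_COLUMNS + ("richness", "troglobite_richness", "reported_relevance")

RELEVANCE_LEVELS = ("maximal", "high", "mid", "low")


class CaveTableError(ValueError):
    """Raised when a cave table fails validation."""


def validate_cave_table(table: pd.DataFrame, strict: bool = True) -> dict:
    """Validate types and invariants; return a data-quality report.

    Hard errors (missing mandatory columns, unparseable coordinates,
    non-positive areas on rows that carry an area) raise
    :class:`CaveTableError` naming the offending rows. Soft issues — per
    column missingness and rare-troglobite/troglobite inconsistencies — are
    reported, not auto-fixed.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise CaveTableError(f"missing mandatory columns: {missing}")
    report: dict = {"n_rows": int(len(table))}

    for col in ("x_m", "y_m"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna() & table[col].notna()]
        if len(bad):
            raise CaveTableError(f"unparseable numerics in {col!r}, rows {bad[:5].tolist()}")
        if vals.isna().any():
            raise CaveTableError(
                f"missing coordinates in {col!r}, rows "
                f"{table.index[vals.isna()][:5].tolist()}")

    if "area_m2" in table.columns and strict:
        area = pd.to_numeric(table["area_m2"], errors="coerce")
        bad = table.index[(area <= 0) & area.notna()]
        if len(bad):
            ids = table.loc[bad, "cave_id"].tolist()[:5]
            raise CaveTableError(
                f"non-positive cave area (log transform undefined) at rows "
                f"{bad[:5].tolist()} (cave ids {ids})")

    report["missingness"] = {
        c: int(table[c].isna().sum()) for c in table.columns
    }
    if {"troglobites", "rare_troglobites"} <= set(table.columns):
        t = pd.to_numeric(table["troglobites"], errors="coerce")
        r = pd.to_numeric(table["rare_troglobites"], errors="coerce")
        viol = table.index[(r == 1) & (t == 0)]
        report["rare_without_troglobite_rows"] = viol.tolist()
    if "reported_relevance" in table.columns:
        labels = table["reported_relevance"].dropna()
        unknown = sorted(set(labels) - set(RELEVANCE_LEVELS))
        report["unknown_relevance_labels"] = unknown
    return report


def load_cave_table(path, schema: Mapping[str, str] | None = None,
                    strict: bool = True) -> tuple[pd.DataFrame, dict]:
    """Load a cave CSV into a typed, validated table.

    ``schema`` maps source column names to canonical names (e.g.
    ``{"UTM_E": "x_m"}``) for third-party dialects. Returns the table and
    the validation report.
    """
    path = Path(path)
    table = pd.read_csv(path)
    if schema:
        table = table.rename(columns=dict(schema))
    for col in NUMERIC_COLUMNS:
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    for col in BINARY_COLUMNS:
        if col in table.columns:
            vals = pd.to_numeric(table[col], errors="coerce")
            out_of_range = vals.dropna()[~vals.dropna().isin([0, 1])]
            if len(out_of_range):
                raise CaveTableError(
                    f"column {col!r} must be binary 0/1; offending rows "
                    f"{out_of_range.index[:5].tolist()}")
            table[col] = vals.astype("Int64")
    if "troglobite_richness" in table.columns:
        table["troglobite_richness"] = pd.array(
            table["troglobite_richness"], dtype="Int64")
    report = validate_cave_table(table, strict=strict)
    return table, report


def save_cave_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_geojson_points(table: pd.DataFrame, path,
                         properties: tuple[str, ...] = ("cave_id",)) -> None:
    """Write cave locations as a GeoJSON point collection (planar meters)."""
    feats = []
    for _, row in table.iterrows():
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row["x_m"]), float(row["y_m"])]},
            "properties": {p: _jsonable(row[p]) for p in properties if p in row},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _jsonable(v):
    if pd.isna(v):
        return None
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def lonlat_to_utm(lon: np.ndarray, lat: np.ndarray, zone: int = 22,
                  south: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Project geographic lon/lat (degrees, WGS84) to UTM meters.

    Standard transverse-Mercator series (sub-meter accuracy within the
    zone), sufficient for building distance-band neighbor graphs.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    a, f = 6378137.0, 1 / 298.257223563
    k0, e2 = 0.9996, f * (2 - f)
    ep2 = e2 / (1 - e2)
    lam0 = np.radians(-183.0 + 6.0 * zone)
    phi, lam = np.radians(lat), np.radians(lon)
    N = a / np.sqrt(1 - e2 * np.sin(phi) ** 2)
    T = np.tan(phi) ** 2
    C = ep2 * np.cos(phi) ** 2
    A = (lam - lam0) * np.cos(phi)
    M = a * ((1 - e2 / 4 - 3 * e2 ** 2 / 64 - 5 * e2 ** 3 / 256) * phi
             - (3 * e2 / 8 + 3 * e2 ** 2 / 32 + 45 * e2 ** 3 / 1024) * np.sin(2 * phi)
             + (15 * e2 ** 2 / 256 + 45 * e2 ** 3 / 1024) * np.sin(4 * phi)
             - (35 * e2 ** 3 / 3072) * np.sin(6 * phi))
    x = k0 * N * (A + (1 - T + C) * A ** 3 / 6
                  + (5 - 18 * T + T ** 2 + 72 * C - 58 * ep2) * A ** 5 / 120) + 500000.0
    y = k0 * (M + N * np.tan(phi) * (A ** 2 / 2
              + (5 - T + 9 * C + 4 * C ** 2) * A ** 4 / 24
              + (61 - 58 * T + T ** 2 + 600 * C - 330 * ep2) * A ** 6 / 720))
    if south:
        y = y + 10000000.0
    return x, y
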