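"""Readers and writers for the package's plain-text interchange formats.

All tables are CSV with a ``#``-comment header noting units (projected km);
polygons travel as GeoJSON in the same projected plane; rasters as ESRI
ASCII grids. Reads validate cross-references (detector ids, occasions) and
fail hard with the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .data import CaptureData, DetectorLayouts, HabitatMask
from .raster import Raster

_KM_HEADER = "# coordinates in projected km; occasions 1-based\n"


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _write_csv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_KM_HEADER)
        df.to_csv(fh, index=False)


# ------------------------------------------------------------------ layouts
def write_layouts(layouts: DetectorLayouts, path) -> None:
    _write_csv(layouts.table, path)


def read_layouts(path) -> DetectorLayouts:
    df = _read_csv(path)
    try:
        return DetectorLayouts(df)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


# ------------------------------------------------------------------ capture
def write_capture(capture: CaptureData, path, session_label: str = "study") -> None:
    df = capture.records.copy()
    df.insert(0, "session_label", session_label)
    df["n_occasions"] = capture.n_occasions
    _write_csv(df, path)


def read_capture(path, layouts: DetectorLayouts | None = None) -> CaptureData:
    df = _read_csv(path)
    if "n_occasions" in df.columns and len(df):
        n_occ = int(df["n_occasions"].iloc[0])
    elif layouts is not None:
        n_occ = layouts.n_occasions
    else:
        n_occ = int(df["occasion"].max()) if len(df) else 1
    df = df.drop(columns=[c for c in ("session_label", "n_occasions") if c in df.columns])
    if layouts is not None:
        idx = layouts.column_index()
        for row_no, (s, d) in enumerate(zip(df["occasion"], df["detector_id"]), start=1):
            if (int(s), d) not in idx:
                raise ValueError(
                    f"{path} row {row_no}: detector {d!r} not in layout for occasion {s}"
                )
    try:
        return CaptureData(df, n_occ, layouts)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


# --------------------------------------------------------------------- mask
def write_mask(mask: HabitatMask, path) -> None:
    df = mask.points.copy()
    df.insert(0, "spacing", mask.spacing)
    _write_csv(df, path)


def read_mask(path, require_covariates: tuple[str, ...] = ()) -> HabitatMask:
    df = _read_csv(path)
    spacing = float(df["spacing"].iloc[0])
    df = df.drop(columns=["spacing"])
    for c in df.columns:
        if c.startswith("inside_") or c.endswith("_filled"):
            df[c] = df[c].astype(bool)
    mask = HabitatMask(df, spacing)
    for c in require_covariates:
        if c not in df.columns:
            raise ValueError(f"{path}: mask lacks required covariate {c!r}")
        vals = df[c].to_numpy(float)
        ing = df["inside_grid"].to_numpy(bool) if "inside_grid" in df else np.ones(len(df), bool)
        if not np.isfinite(vals[ing]).all():
            bad = int(np.flatnonzero(ing & ~np.isfinite(vals))[0]) + 1
            raise ValueError(f"{path} row {bad}: missing {c!r} inside the grid")
    return mask


# ---------------------------------------------------------------- telemetry
def write_telemetry(telemetry: pd.DataFrame, path) -> None:
    _write_csv(telemetry, path)


def read_telemetry(path) -> pd.DataFrame:
    df = _read_csv(path)
    need = {"animal_id", "sex", "x", "y"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: telemetry needs columns {sorted(need)}")
    return df


# -------------------------------------------------------------------- truth
def write_truth(truth, path) -> None:
    df = truth.centers.copy()
    df["seed"] = truth.seed
    _write_csv(df, path)


def read_truth_centers(path) -> pd.DataFrame:
    return _read_csv(path)


# ------------------------------------------------------------------ polygon
def write_polygon(polygon, path) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [{"type": "Feature", "properties": {}, "geometry": mapping(polygon)}],
    }
    Path(path).write_text(json.dumps(gj))


def read_polygon(path):
    gj = json.loads(Path(path).read_text())
    if gj.get("type") == "FeatureCollection":
        return shape(gj["features"][0]["geometry"])
    if gj.get("type") == "Feature":
        return shape(gj["geometry"])
    return shape(gj)


# -------------------------------------------------------------- ascii grid
def write_ascii_grid(raster: Raster, path, nodata: float = -9999.0) -> None:
    v = np.where(np.isfinite(raster.values), raster.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.nx}\n")
        fh.write(f"nrows {raster.ny}\n")
        fh.write(f"xllcorner {raster.x0}\n")
        fh.write(f"yllcorner {raster.y0}\n")
        fh.write(f"cellsize {raster.resolution}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in v[::-1]:  # ASCII grids run north to south
            fh.write(" ".join(f"{x:g}" for x in row) + "\n")


def read_ascii_grid(path) -> Raster:
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        k, val = line.split()
        header[k.lower()] = float(val)
    vals = np.loadtxt(lines[6:])
    vals = np.atleast_2d(vals)[::-1]
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    return Raster(vals, header["xllcorner"], header["yllcorner"], header["cellsize"])


# ------------------------------------------------------------------ outputs
def write_surface(surface: pd.DataFrame, path) -> None:
    _write_csv(surface, path)


def write_table(df: pd.DataFrame, path) -> None:
    _write_csv(df, path)
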