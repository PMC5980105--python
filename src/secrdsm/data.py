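"""Core data containers: detector layouts, capture records, habitat masks.

All coordinates are projected planar kilometres; occasions are 1-based.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep

RESERVED_LAYOUT_COLUMNS = ("occasion", "detector_id", "x", "y")


class DetectorLayouts:
    """Hair-snag detector positions and site covariates per sampling occasion.

    Parameters
    ----------
    table : DataFrame
        One row per detector per occasion with columns ``occasion`` (1-based
        int), ``detector_id``, ``x``, ``y``; any further numeric columns are
        treated as site covariates (e.g. terrain ruggedness ``TRI_site``,
        canopy closure ``CC_site``).
    """

    def __init__(self, table: pd.DataFrame):
        required = set(RESERVED_LAYOUT_COLUMNS)
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"layout table missing columns: {sorted(missing)}")
        table = table.copy()
        table["occasion"] = table["occasion"].astype(int)
        if (table["occasion"] < 1).any():
            raise ValueError("occasions are 1-based")
        dup = table.duplicated(subset=["occasion", "detector_id"])
        if dup.any():
            raise ValueError("detector ids must be unique within an occasion")
        cov = [c for c in table.columns if c not in required]
        bad = [c for c in cov if not np.isfinite(table[c].to_numpy(float)).all()]
        if bad:
            raise ValueError(f"non-finite site covariates: {bad}")
        occs = np.sort(table["occasion"].unique())
        if not np.array_equal(occs, np.arange(1, occs[-1] + 1)):
            raise ValueError("occasions must form a contiguous 1..S range")
        self.table = table.sort_values(["occasion", "detector_id"], kind="mergesort").reset_index(drop=True)
        self.n_occasions = int(occs[-1])
        self.covariate_names = cov

    def occasion(self, s: int) -> pd.DataFrame:
        return self.table[self.table["occasion"] == s]

    @property
    def n_detectors_per_occasion(self) -> int:
        return len(self.table) // self.n_occasions

    def column_index(self) -> dict[tuple[int, object], int]:
        """Map (occasion, detector_id) -> stacked column index."""
        return {
            (int(s), d): i
            for i, (s, d) in enumerate(zip(self.table["occasion"], self.table["detector_id"]))
        }

    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(float)


class CaptureData:
    """Binary detection records of identified individuals.

    One row per (animal, occasion, detector) triplet at which the animal left
    an identified hair sample; repeated deposits within one occasion at one
    site collapse to a single record.
    """

    COLUMNS = ("animal_id", "sex", "occasion", "detector_id")

    def __init__(self, records: pd.DataFrame, n_occasions: int, layouts: DetectorLayouts | None = None):
        records = records.copy()
        missing = set(self.COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"capture records missing columns: {sorted(missing)}")
        records["occasion"] = records["occasion"].astype(int)
        if len(records):
            if records["occasion"].min() < 1 or records["occasion"].max() > n_occasions:
                raise ValueError("occasion outside 1..n_occasions")
            dup = records.duplicated(subset=["animal_id", "occasion", "detector_id"])
            if dup.any():
                raise ValueError("duplicate (animal, occasion, detector) records")
            sex_per_animal = records.groupby("animal_id")["sex"].nunique()
            if (sex_per_animal > 1).any():
                raise ValueError("inconsistent sex within an animal")
        if layouts is not None:
            idx = layouts.column_index()
            for row_no, (s, d) in enumerate(zip(records["occasion"], records["detector_id"])):
                if (int(s), d) not in idx:
                    raise ValueError(
                        f"capture row {row_no}: detector {d!r} unknown in occasion {s}"
                    )
        self.records = records.reset_index(drop=True)
        self.n_occasions = int(n_occasions)

    @property
    def animals(self) -> list:
        return sorted(self.records["animal_id"].unique().tolist())

    @property
    def n_animals(self) -> int:
        return self.records["animal_id"].nunique()

    def sex_of(self) -> pd.Series:
        return self.records.groupby("animal_id")["sex"].first()

    def detections_per_animal(self) -> pd.Series:
        return self.records.groupby("animal_id").size()

    def occasions_detected(self) -> pd.Series:
        """Number of occasions in which each animal was detected at least once."""
        return self.records.groupby("animal_id")["occasion"].nunique()

    def efficiency(self) -> float:
        """Share of detected animals seen in more than one occasion."""
        if self.n_animals == 0:
            return float("nan")
        return float((self.occasions_detected() > 1).mean())

    def for_sex(self, sex) -> "CaptureData":
        return CaptureData(self.records[self.records["sex"] == sex], self.n_occasions)


class HabitatMask:
    """Regular point lattice with cell area over which SECR integrals run.

    ``points`` carries columns ``x``, ``y`` plus optional covariates (``RSF``,
    ``Risk``, ...) and boolean region flags (``inside_grid``,
    ``inside_province``).
    """

    def __init__(self, points: pd.DataFrame, spacing: float):
        if spacing <= 0:
            raise ValueError("mask spacing must be positive")
        if not {"x", "y"} <= set(points.columns):
            raise ValueError("mask points need x and y columns")
        if len(points) == 0:
            raise ValueError("empty mask")
        self.points = points.reset_index(drop=True).copy()
        self.spacing = float(spacing)

    @property
    def cell_area(self) -> float:
        """Area represented by one mask point, km^2."""
        return self.spacing**2

    @property
    def n_points(self) -> int:
        return len(self.points)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def coords(self) -> np.ndarray:
        return self.points[["x", "y"]].to_numpy(float)

    def flag(self, name: str) -> np.ndarray:
        if name not in self.points.columns:
            raise KeyError(f"mask has no flag {name!r}")
        return self.points[name].to_numpy(bool)

    def area(self, flag: str | None = None) -> float:
        n = self.n_points if flag is None else int(self.flag(flag).sum())
        return n * self.cell_area

    def subset(self, keep: np.ndarray) -> "HabitatMask":
        return HabitatMask(self.points[np.asarray(keep, bool)], self.spacing)

    @classmethod
    def from_polygon(cls, polygon, spacing: float, buffer: float = 0.0) -> "HabitatMask":
        """Lattice covering ``polygon`` buffered outward by ``buffer`` km.

        Points get an ``inside_grid`` flag marking membership in the
        unbuffered polygon.
        """
        if spacing <= 0:
            raise ValueError("mask spacing must be positive")
        region = polygon.buffer(buffer) if buffer > 0 else polygon
        xmin, ymin, xmax, ymax = region.bounds
        xs = np.arange(xmin + spacing / 2, xmax, spacing)
        ys = np.arange(ymin + spacing / 2, ymax, spacing)
        xx, yy = np.meshgrid(xs, ys)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        pregion = prep(region)
        keep = np.fromiter(
            (pregion.contains(Point(p)) for p in pts), bool, count=len(pts)
        )
        pts = pts[keep]
        if len(pts) == 0:
            raise ValueError("polygon too small for requested spacing")
        pgrid = prep(polygon)
        inside = np.fromiter((pgrid.contains(Point(p)) for p in pts), bool, count=len(pts))
        df = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "inside_grid": inside})
        return cls(df, spacing)

    def add_region_flag(self, polygon, name: str) -> None:
        pgon = prep(polygon)
        self.points[name] = [pgon.contains(Point(x, y)) for x, y in self.coords]
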