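"""Quality grading, temporal change, mean centers and zonal EI comparison.

The [0, 1] index is cut into five levels at 0.2 intervals (Poor, Fair,
Moderate, Good, Excellent; bins half-open, top bin closed).  Change between
two dates is the signed level difference, grouped into five categories with
areas in km².  Per-grade mean centers are unweighted pixel-center centroids in
the projected CRS.  Zonal means against reference EI values use
pixel-center-in-polygon membership.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

from .composite import IndexRaster
from .errors import AlignmentError, RseikitError
from .raster_io import Affine

LEVEL_LABELS = {1: "Poor", 2: "Fair", 3: "Moderate", 4: "Good", 5: "Excellent"}

#: Change code → five-category label.
CATEGORY_OF_CODE = {
    -4: "Markedly deteriorated",
    -3: "Markedly deteriorated",
    -2: "Mildly deteriorated",
    -1: "Mildly deteriorated",
    0: "Basically stable",
    1: "Slightly improved",
    2: "Slightly improved",
    3: "Markedly improved",
    4: "Markedly improved",
}

#: Change code → three-level label.
LEVEL_OF_CODE = {c: ("Deteriorated" if c < 0 else "Improved" if c > 0 else "Basically stable")
                 for c in range(-4, 5)}


@dataclass
class EQLevelRaster:
    """Integer quality grades 1..5 on the index grid."""

    levels: np.ndarray
    valid_mask: np.ndarray
    transform: Affine
    crs_id: str = "unknown"

    @property
    def pixel_area_km2(self) -> float:
        return self.transform.pixel_area / 1e6


@dataclass
class ChangeRecord:
    code: int
    level_label: str
    category_label: str
    area_km2: float


@dataclass
class ChangeResult:
    codes: np.ndarray
    valid_mask: np.ndarray
    records: list[ChangeRecord]

    def area_by_category(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for rec in self.records:
            out[rec.category_label] = out.get(rec.category_label, 0.0) + rec.area_km2
        return out

    def area_by_level(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for rec in self.records:
            out[rec.level_label] = out.get(rec.level_label, 0.0) + rec.area_km2
        return out


@dataclass
class MeanCenter:
    grade: int
    x: float
    y: float
    n_pixels: int


@dataclass
class ZonalRecord:
    region_id: str
    mean_index: float | None
    ei_value: float | None = None
    difference: float | None = None
    n_pixels: int = 0


def classify_levels(index: IndexRaster) -> EQLevelRaster:
    """Cut the [0, 1] index into grades 1..5 at 0.2 intervals.

    Bins are [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1.0]; a boundary
    value belongs to the upper bin except 1.0, which stays Excellent.
    """
    vals = index.values[index.valid_mask]
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise RseikitError("index values outside [0, 1]; cannot classify")
    levels = np.zeros(index.values.shape, dtype=np.uint8)
    with np.errstate(invalid="ignore"):
        binned = np.floor(index.values * 5.0)
    binned = np.clip(binned, 0, 4)
    levels[index.valid_mask] = (binned[index.valid_mask] + 1).astype(np.uint8)
    if index.transform is None:
        raise RseikitError("index raster has no transform; cannot derive pixel area")
    return EQLevelRaster(levels, index.valid_mask.copy(), index.transform, index.crs_id)


def change_grade(t1: EQLevelRaster, t2: EQLevelRaster) -> ChangeResult:
    """Signed level change t2 − t1 with per-code areas.

    Returns every code −4..4 (possibly zero area); the code areas sum exactly
    to the jointly valid area.
    """
    if t1.levels.shape != t2.levels.shape or tuple(t1.transform) != tuple(t2.transform):
        raise AlignmentError("level rasters are not aligned")
    joint = t1.valid_mask & t2.valid_mask
    codes = np.zeros(t1.levels.shape, dtype=np.int8)
    codes[joint] = t2.levels[joint].astype(np.int8) - t1.levels[joint].astype(np.int8)
    area = t1.pixel_area_km2
    records = [
        ChangeRecord(
            code=c,
            level_label=LEVEL_OF_CODE[c],
            category_label=CATEGORY_OF_CODE[c],
            area_km2=float((codes[joint] == c).sum()) * area,
        )
        for c in range(-4, 5)
    ]
    return ChangeResult(codes=codes, valid_mask=joint, records=records)


def mean_centers(levels: EQLevelRaster) -> list[MeanCenter]:
    """Per-grade arithmetic mean of pixel-center projected coordinates.

    Grades with no pixels are omitted.
    """
    out: list[MeanCenter] = []
    for grade in range(1, 6):
        sel = levels.valid_mask & (levels.levels == grade)
        n = int(sel.sum())
        if n == 0:
            continue
        rows, cols = np.nonzero(sel)
        xs, ys = levels.transform.xy(rows, cols)
        out.append(MeanCenter(grade=grade, x=float(xs.mean()), y=float(ys.mean()),
                              n_pixels=n))
    return out


def read_regions_geojson(path: str | Path, id_field: str = "id") -> dict[str, BaseGeometry]:
    """Load a GeoJSON FeatureCollection into {region_id: shapely geometry}."""
    with open(path) as fh:
        gj = json.load(fh)
    regions: dict[str, BaseGeometry] = {}
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        rid = str(props.get(id_field, feat.get("id")))
        regions[rid] = geom_shape(feat["geometry"])
    return regions


def zonal_mean(
    index: IndexRaster, regions: Mapping[str, BaseGeometry]
) -> list[ZonalRecord]:
    """Mean index per region over valid pixels whose centers fall inside it.

    Regions with no valid pixels yield a record with a missing mean.
    """
    if index.transform is None:
        raise RseikitError("index raster has no transform; cannot locate pixels")
    rows, cols = np.nonzero(index.valid_mask)
    xs, ys = index.transform.xy(rows, cols)
    vals = index.values[index.valid_mask]
    out: list[ZonalRecord] = []
    for rid, geom in regions.items():
        inside = shapely.contains_xy(geom, xs, ys)
        n = int(inside.sum())
        mean = float(vals[inside].mean()) if n else None
        out.append(ZonalRecord(region_id=rid, mean_index=mean, n_pixels=n))
    return out


def index_ei_difference(
    zonal: Sequence[ZonalRecord],
    ei_table: Mapping[str, float],
    index_scale: float = 100.0,
) -> list[ZonalRecord]:
    """Difference between the scaled zonal index mean and the reference EI.

    EI is conventionally on a 0–100 scale, hence the default scale of 100.
    """
    out: list[ZonalRecord] = []
    for rec in zonal:
        if rec.region_id not in ei_table:
            raise LookupError(f"region {rec.region_id!r} missing from EI table")
        ei = float(ei_table[rec.region_id])
        diff = (index_scale * rec.mean_index - ei) if rec.mean_index is not None else None
        out.append(ZonalRecord(rec.region_id, rec.mean_index, ei, diff, rec.n_pixels))
    return out


def read_ei_table(path: str | Path) -> dict[str, float]:
    """CSV (region_id, ei) → mapping."""
    table: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            table[str(row["region_id"])] = float(row["ei"])
    return table
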