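"""Georeferenced band-stack I/O and scene preprocessing.

Reads and writes multiband GeoTIFFs (via tifffile, carrying the standard
GeoTIFF ModelPixelScale / ModelTiepoint / GDAL_NODATA tags plus a JSON
ImageDescription with band names, CRS identifier and the full affine), decodes
Landsat Collection-2 QA_PIXEL cloud flags, composites repeat acquisitions by
the per-pixel median, and fills residual gaps from a secondary acquisition.

Reflectance bands are stored as physical surface reflectance: the Collection-2
scale (2.75e-05) and offset (-0.2) are applied at read time under control of
the SensorProfile, so downstream index math never sees raw digital numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import tifffile

from .errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateDataError,
    RasterFormatError,
)

REFLECTANCE_BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")

#: QA_PIXEL bits treated as contamination by default: 1 dilated cloud,
#: 3 cloud, 4 cloud shadow (Landsat Collection-2 convention).
DEFAULT_CLOUD_BITS = frozenset({1, 3, 4})

# Private TIFF tags used for georeferencing (GeoTIFF spec / GDAL convention).
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class Affine(NamedTuple):
    """Six-parameter affine map from pixel (col, row) to projected (x, y).

    ``x = a*col + b*row + c`` and ``y = d*col + e*row + f`` at the pixel's
    upper-left corner; pixel centers sit at (col+0.5, row+0.5).  The raster
    convention is row-major with the origin at the upper-left, so ``e`` is
    normally negative.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def xy(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Projected coordinates of pixel centers for (row, col) indices."""
        cc = np.asarray(cols, dtype=float) + 0.5
        rr = np.asarray(rows, dtype=float) + 0.5
        return self.a * cc + self.b * rr + self.c, self.d * cc + self.e * rr + self.f

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in squared projected units (meters^2)."""
        return abs(self.a * self.e - self.b * self.d)

    def translated(self, dx: float, dy: float) -> "Affine":
        return self._replace(c=self.c + dx, f=self.f + dy)


@dataclass(frozen=True)
class SensorProfile:
    """Sensor-specific band layout and coefficients.

    ``band_index_map`` maps semantic names to 1-based band numbers in the file
    sequence handed to :func:`read_stack`.  ``wet_coefficients`` are the six
    tasseled-cap wetness weights in (blue, green, red, nir, swir1, swir2)
    order.
    """

    sensor: str
    band_index_map: Mapping[str, int]
    wet_coefficients: tuple[float, ...]
    st_band_name: str = "st"
    reflectance_scale: float = 1.0
    reflectance_offset: float = 0.0

    def __post_init__(self) -> None:
        if len(self.wet_coefficients) != 6:
            raise ConfigurationError("wet_coefficients must have length 6")

    @classmethod
    def from_json(cls, path: str | Path) -> "SensorProfile":
        with open(path) as fh:
            cfg = json.load(fh)
        return cls(
            sensor=cfg["sensor"],
            band_index_map=dict(cfg["band_index_map"]),
            wet_coefficients=tuple(cfg["wet_coefficients"]),
            st_band_name=cfg.get("st_band_name", "st"),
            reflectance_scale=cfg.get("reflectance_scale", 1.0),
            reflectance_offset=cfg.get("reflectance_offset", 0.0),
        )


# Tasseled-cap wetness coefficients, (blue, green, red, nir, swir1, swir2).
WET_COEFFICIENTS = {
    "TM": (0.0315, 0.2021, 0.3102, 0.1594, -0.6806, -0.6109),
    "OLI": (0.1511, 0.1973, 0.3283, 0.3407, -0.7117, -0.4559),
}

_C2_SCALE = 2.75e-05
_C2_OFFSET = -0.2

#: Landsat 5 TM Collection-2 Level-2 profile (SR_B1..SR_B5, SR_B7, ST_B6).
TM_PROFILE = SensorProfile(
    sensor="TM",
    band_index_map={"blue": 1, "green": 2, "red": 3, "nir": 4, "swir1": 5,
                    "swir2": 6, "st": 7, "qa": 8},
    wet_coefficients=WET_COEFFICIENTS["TM"],
    reflectance_scale=_C2_SCALE,
    reflectance_offset=_C2_OFFSET,
)

#: Landsat 8 OLI Collection-2 Level-2 profile (SR_B2..SR_B7, ST_B10).
OLI_PROFILE = SensorProfile(
    sensor="OLI",
    band_index_map={"blue": 1, "green": 2, "red": 3, "nir": 4, "swir1": 5,
                    "swir2": 6, "st": 7, "qa": 8},
    wet_coefficients=WET_COEFFICIENTS["OLI"],
    reflectance_scale=_C2_SCALE,
    reflectance_offset=_C2_OFFSET,
)


@dataclass
class BandStack:
    """Aligned semantic bands on one grid with a shared validity mask.

    Reflectance bands are dimensionless surface reflectance (nominally
    [0, 1]); ``st`` is in Kelvin; ``qa`` holds integer bit flags.
    """

    bands: dict[str, np.ndarray]
    valid_mask: np.ndarray
    transform: Affine
    crs_id: str
    sensor: str

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def __post_init__(self) -> None:
        shp = self.shape
        for name, arr in self.bands.items():
            if arr.shape != shp:
                raise AlignmentError(f"band {name!r} shape {arr.shape} != {shp}")
        if self.valid_mask.shape != shp:
            raise AlignmentError("valid_mask shape mismatch")

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise ConfigurationError(f"band {name!r} not present in stack") from None

    def copy(self) -> "BandStack":
        return BandStack(
            bands={k: v.copy() for k, v in self.bands.items()},
            valid_mask=self.valid_mask.copy(),
            transform=self.transform,
            crs_id=self.crs_id,
            sensor=self.sensor,
        )


def _check_aligned(a: BandStack, b: BandStack) -> None:
    if a.shape != b.shape:
        raise AlignmentError(f"grid shapes differ: {a.shape} vs {b.shape}")
    if tuple(a.transform) != tuple(b.transform):
        raise AlignmentError("affine transforms differ")
    if a.crs_id != b.crs_id:
        raise AlignmentError(f"CRS differs: {a.crs_id} vs {b.crs_id}")


def _geo_extratags(transform: Affine, nodata: float | int | None) -> list:
    tags = []
    if transform.b == 0.0 and transform.d == 0.0:
        tags.append((_TAG_MODEL_PIXEL_SCALE, "d", 3,
                     (abs(transform.a), abs(transform.e), 0.0)))
        tags.append((_TAG_MODEL_TIEPOINT, "d", 6,
                     (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)))
    if nodata is not None:
        s = repr(float(nodata)) if isinstance(nodata, float) else str(nodata)
        tags.append((_TAG_GDAL_NODATA, "s", 0, s))
    return tags


def write_stack(stack: BandStack, path: str | Path) -> None:
    """Write a BandStack to one multiband GeoTIFF, including the validity mask.

    Band order and all georeferencing metadata go into a JSON ImageDescription
    so that :func:`read_bandstack` round-trips bit-exactly.
    """
    names = list(stack.bands)
    data = np.stack([stack.bands[n] for n in names] + [stack.valid_mask.astype(np.float64)])
    meta = {
        "bands": names + ["__valid__"],
        "transform": list(stack.transform),
        "crs_id": stack.crs_id,
        "sensor": stack.sensor,
        "kind": "bandstack",
    }
    tifffile.imwrite(
        path, data, photometric="minisblack",
        description=json.dumps(meta), extratags=_geo_extratags(stack.transform, None),
    )


def read_bandstack(path: str | Path) -> BandStack:
    """Read a multiband GeoTIFF written by :func:`write_stack`."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise RasterFormatError(f"{path}: missing stack metadata") from exc
    if data.ndim == 2:
        data = data[None]
    names = meta["bands"]
    if len(names) != data.shape[0]:
        raise RasterFormatError(f"{path}: band count mismatch with metadata")
    arrays = {n: data[i] for i, n in enumerate(names)}
    valid = arrays.pop("__valid__").astype(bool)
    return BandStack(
        bands=arrays,
        valid_mask=valid,
        transform=Affine(*meta["transform"]),
        crs_id=meta["crs_id"],
        sensor=meta["sensor"],
    )


def write_raster(
    values: np.ndarray,
    valid_mask: np.ndarray,
    transform: Affine,
    crs_id: str,
    path: str | Path,
    nodata: float | int | None = None,
    name: str = "values",
) -> None:
    """Write one single-band GeoTIFF; invalid pixels are set to ``nodata``."""
    out = np.array(values, copy=True)
    if nodata is None:
        nodata = 255 if out.dtype.kind in "ui" else float("nan")
    out[~valid_mask] = nodata
    meta = {
        "bands": [name],
        "transform": list(transform),
        "crs_id": crs_id,
        "nodata": None if isinstance(nodata, float) and np.isnan(nodata) else nodata,
        "kind": "raster",
    }
    tifffile.imwrite(
        path, out, photometric="minisblack",
        description=json.dumps(meta), extratags=_geo_extratags(transform, nodata),
    )


def read_raster(path: str | Path) -> tuple[np.ndarray, np.ndarray, Affine, str]:
    """Read a single-band GeoTIFF; returns (values, valid_mask, transform, crs)."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise RasterFormatError(f"{path}: missing raster metadata") from exc
    nodata = meta.get("nodata")
    if nodata is None and data.dtype.kind == "f":
        valid = np.isfinite(data)
    elif nodata is None:
        valid = np.ones(data.shape, dtype=bool)
    else:
        valid = data != nodata
    return data, valid, Affine(*meta["transform"]), meta["crs_id"]


def read_stack(paths: Sequence[str | Path], profile: SensorProfile) -> BandStack:
    """Assemble a BandStack from georeferenced raster files.

    Bands are numbered 1..N across the concatenated band sequence of ``paths``
    and selected through ``profile.band_index_map``.  The Collection-2
    reflectance scale/offset from the profile is applied to the six
    reflectance bands; ``st`` (Kelvin) and ``qa`` (bit flags) pass through
    untouched.  Pixels where any mapped band is nodata/non-finite are marked
    invalid.
    """
    if not paths:
        raise RasterFormatError("no input rasters given")
    planes: list[np.ndarray] = []
    transform = crs = None
    nodatas: list[float | None] = []
    for p in paths:
        with tifffile.TiffFile(p) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        meta = None
        try:
            meta = json.loads(desc) if desc else None
        except json.JSONDecodeError:
            meta = None
        if data.ndim == 2:
            data = data[None]
        file_nodata = meta.get("nodata") if isinstance(meta, dict) else None
        t = Affine(*meta["transform"]) if isinstance(meta, dict) and "transform" in meta else None
        c = meta.get("crs_id") if isinstance(meta, dict) else None
        if transform is None:
            transform, crs = t, c
        else:
            if t is not None and tuple(t) != tuple(transform):
                raise AlignmentError(f"{p}: transform differs from first raster")
            if c is not None and crs is not None and c != crs:
                raise AlignmentError(f"{p}: CRS differs from first raster")
        names = meta.get("bands") if isinstance(meta, dict) else None
        for i in range(data.shape[0]):
            nm = names[i] if names else None
            if nm == "__valid__":
                continue
            planes.append(data[i])
            nodatas.append(file_nodata)
    n_avail = len(planes)
    shp = planes[0].shape
    for pl in planes:
        if pl.shape != shp:
            raise AlignmentError("input rasters have mismatched grid shapes")
    bands: dict[str, np.ndarray] = {}
    valid = np.ones(shp, dtype=bool)
    for name, idx in profile.band_index_map.items():
        if not 1 <= idx <= n_avail:
            raise AlignmentError(
                f"profile maps {name!r} to band {idx} but only {n_avail} bands supplied")
        arr = planes[idx - 1]
        nd = nodatas[idx - 1]
        ok = np.ones(shp, dtype=bool) if nd is None else arr != nd
        if name in REFLECTANCE_BANDS:
            arr = arr.astype(np.float64) * profile.reflectance_scale + profile.reflectance_offset
            ok &= np.isfinite(arr)
        elif name == "qa":
            arr = arr.astype(np.int64)
        else:
            arr = arr.astype(np.float64)
            ok &= np.isfinite(arr)
        bands[name] = arr
        valid &= ok
    return BandStack(
        bands=bands,
        valid_mask=valid,
        transform=transform if transform is not None else Affine(1, 0, 0, 0, -1, 0),
        crs_id=crs if crs is not None else "unknown",
        sensor=profile.sensor,
    )


def decode_cloud_mask(qa: np.ndarray, flag_bits: Iterable[int] = DEFAULT_CLOUD_BITS) -> np.ndarray:
    """True wherever any of ``flag_bits`` is set in the QA bit-flag grid."""
    qa = np.asarray(qa)
    if qa.dtype.kind not in "iu":
        if not np.all(np.equal(np.mod(qa[np.isfinite(qa)], 1), 0)):
            raise RasterFormatError("QA grid must be integer-valued")
        qa = qa.astype(np.int64)
    if np.any(qa < 0):
        raise RasterFormatError("QA grid contains negative flag values")
    bits = list(flag_bits)
    if any(b < 0 for b in bits):
        raise RasterFormatError("flag bits must be non-negative")
    mask = 0
    for b in bits:
        mask |= 1 << int(b)
    return (qa.astype(np.int64) & mask) != 0


def cloud_coverage(mask: np.ndarray, valid: np.ndarray) -> float:
    """Fraction of valid pixels flagged as cloudy, in [0, 1]."""
    mask = np.asarray(mask, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if mask.shape != valid.shape:
        raise AlignmentError("mask and valid grids have different shapes")
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise DegenerateDataError("no valid pixels; cloud coverage undefined")
    return float((mask & valid).sum()) / n_valid


def mask_clouds(stack: BandStack, flag_bits: Iterable[int] = DEFAULT_CLOUD_BITS) -> BandStack:
    """Return a copy with cloud-flagged pixels removed from the validity mask."""
    out = stack.copy()
    if "qa" in out.bands:
        out.valid_mask &= ~decode_cloud_mask(out.bands["qa"], flag_bits)
    return out


def median_composite(stacks: Sequence[BandStack]) -> BandStack:
    """Per-pixel, per-band median across acquisitions.

    Each stack's validity mask defines which pixels contribute (mask clouds
    first with :func:`mask_clouds`).  An even number of contributors yields
    the arithmetic mean of the two middle values.  A pixel is invalid in the
    output only if it is invalid in every input.
    """
    if len(stacks) == 0:
        raise DegenerateDataError("median_composite needs at least one stack")
    first = stacks[0]
    for s in stacks[1:]:
        _check_aligned(first, s)
        if s.sensor != first.sensor:
            raise AlignmentError("cannot composite stacks from different sensors")
    band_names = [n for n in first.bands if n != "qa"]
    for s in stacks[1:]:
        if set(n for n in s.bands if n != "qa") != set(band_names):
            raise AlignmentError("stacks carry different band sets")
    out_bands: dict[str, np.ndarray] = {}
    valid_any = np.zeros(first.shape, dtype=bool)
    for s in stacks:
        valid_any |= s.valid_mask
    for name in band_names:
        cube = np.empty((len(stacks),) + first.shape, dtype=np.float64)
        for i, s in enumerate(stacks):
            layer = s.bands[name].astype(np.float64).copy()
            layer[~s.valid_mask] = np.nan
            cube[i] = layer
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
            med = np.nanmedian(cube, axis=0)
        out_bands[name] = med
    return BandStack(
        bands=out_bands,
        valid_mask=valid_any,
        transform=first.transform,
        crs_id=first.crs_id,
        sensor=first.sensor,
    )


def fill_gaps(primary: BandStack, secondary: BandStack) -> tuple[BandStack, int]:
    """Fill invalid primary pixels from a same-month secondary acquisition.

    Valid primary pixels are never modified.  Returns the filled stack and the
    number of pixels filled.
    """
    _check_aligned(primary, secondary)
    if primary.sensor != secondary.sensor:
        raise AlignmentError("cannot fill gaps across sensors")
    out = primary.copy()
    fill = ~primary.valid_mask & secondary.valid_mask
    for name, arr in out.bands.items():
        if name in secondary.bands:
            arr[fill] = secondary.bands[name][fill]
    out.valid_mask |= fill
    return out, int(fill.sum())
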