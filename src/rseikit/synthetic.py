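"""Seed-controlled synthetic scenes for end-to-end testing.

Generates multispectral band stacks with the statistical structure the
composite-index method assumes: a latent ecological-quality field rising from
an urban core to the rural edge, bands linear in that field (so greenness and
wetness rise with quality while dryness, particulate load and surface
temperature fall), an open-water body satisfying green > swir1, cloud pixels
flagged in a QA band, rectangular district polygons, and a reference EI table
derived from the latent truth.  Everything is deterministic given the seed.

The particulate signal enters the red (+) and NIR (−) bands through a single
contrast knob (``di_variability``): shrinking it lowers the spatial variance
of the DI band against the fixed band noise, which is the band-level lever
behind the spatial-variability→PCA-loading mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, mapping
from shapely.geometry.base import BaseGeometry

from .errors import ConfigurationError
from .raster_io import Affine, BandStack

ZONE_RURAL, ZONE_URBAN, ZONE_WATER, ZONE_CLOUD = 0, 1, 2, 3
ZONE_NAMES = {ZONE_RURAL: "rural", ZONE_URBAN: "urban",
              ZONE_WATER: "water", ZONE_CLOUD: "cloud"}

#: Band model: reflectance = base + slope_q * q + slope_p * pol (+ noise),
#: with pol = di_variability * (1 - q).  Slopes are chosen so NDVI and WET
#: rise with quality while NDSI, DI and surface temperature fall.
_BAND_MODEL = {
    #        base   slope_q  slope_pol
    "blue": (0.10, -0.03, 0.02),
    "green": (0.14, -0.02, 0.02),
    "red": (0.25, -0.10, 0.10),
    "nir": (0.30, -0.10, -0.10),
    "swir1": (0.30, -0.15, 0.03),
    "swir2": (0.25, -0.13, 0.03),
}
_ST_MODEL = (305.0, -12.0, 3.0)  # Kelvin

_WATER_BANDS = {"blue": 0.08, "green": 0.15, "red": 0.06, "nir": 0.04,
                "swir1": 0.01, "swir2": 0.01}
_WATER_ST = 300.0
_CLOUD_REFLECTANCE = 0.55
_CLOUD_ST = 275.0
_CLOUD_QA_BIT = 3

_SMOOTH_SIGMA = 3.0  # pixels; spatial correlation length of the noise


@dataclass(frozen=True)
class SceneParams:
    """Generator settings; the defaults define the standard test conditions."""

    width: int = 96
    height: int = 96
    urban_fraction: float = 0.25
    water_fraction: float = 0.05
    cloud_fraction: float = 0.05
    noise_sd: float = 0.015
    sensor: str = "OLI"
    seed: int = 0
    pixel_size_m: float = 30.0
    di_variability: float = 1.0
    hotspot_fraction: float = 0.005

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ConfigurationError("scene dimensions must be at least 8 pixels")
        fracs = (self.urban_fraction, self.water_fraction, self.cloud_fraction)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ConfigurationError("zone fractions must lie in [0,1] and sum to <= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Latent quality in [0, 1] and zone labels aligned with the stack."""

    quality: np.ndarray
    zone_labels: np.ndarray
    transform: Affine

    def zone_mask(self, zone: int) -> np.ndarray:
        return self.zone_labels == zone


def _smooth_unit_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to unit standard deviation."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=_SMOOTH_SIGMA)
    sd = z.std()
    return z / sd if sd > 0 else z


def generate_scene(params: SceneParams) -> tuple[BandStack, GroundTruth]:
    """Generate one synthetic acquisition and its ground truth."""
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    rows, cols = np.mgrid[0:h, 0:w]

    # Latent quality: radial urban–rural gradient plus correlated noise.
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot((rows - cy) / h, (cols - cx) / w)
    r = r / r.max()
    q = np.clip(0.12 + 0.75 * r + 0.15 * _smooth_unit_noise(rng, (h, w)), 0.0, 1.0)

    labels = np.full((h, w), ZONE_RURAL, dtype=np.uint8)
    if params.urban_fraction > 0:
        labels[r <= np.quantile(r, params.urban_fraction)] = ZONE_URBAN
    if params.water_fraction > 0:
        wy, wx = 0.28 * h, 0.70 * w
        rw = np.hypot(rows - wy, cols - wx)
        labels[rw <= np.quantile(rw, params.water_fraction)] = ZONE_WATER
    cloud = np.zeros((h, w), dtype=bool)
    if params.cloud_fraction > 0:
        cfield = _smooth_unit_noise(rng, (h, w))
        cloud = cfield >= np.quantile(cfield, 1.0 - params.cloud_fraction)
        labels[cloud] = ZONE_CLOUD

    pol = params.di_variability * (1.0 - q)
    water = labels == ZONE_WATER
    # Persistent point sources (industrial hotspots): strong particulate
    # contrast that does not scale with the diffuse-pollution knob, anchoring
    # the DI band's extremes.
    hotspots = (rng.random((h, w)) < params.hotspot_fraction) & ~water & ~cloud
    bands: dict[str, np.ndarray] = {}
    for name, (base, sq, sp) in _BAND_MODEL.items():
        vals = base + sq * q + sp * pol
        if name == "red":
            vals = np.where(hotspots, vals + 0.15, vals)
        elif name == "nir":
            vals = np.where(hotspots, vals - 0.12, vals)
        vals = np.where(water, _WATER_BANDS[name], vals)
        vals = np.where(cloud, _CLOUD_REFLECTANCE, vals)
        vals = vals + params.noise_sd * _smooth_unit_noise(rng, (h, w))
        bands[name] = np.clip(vals, 5e-4, 1.0)
    st_base, st_q, st_p = _ST_MODEL
    st = st_base + st_q * q + st_p * pol
    st = np.where(water, _WATER_ST, st)
    st = np.where(cloud, _CLOUD_ST, st)
    bands["st"] = st + 40.0 * params.noise_sd * _smooth_unit_noise(rng, (h, w))

    qa = np.zeros((h, w), dtype=np.int64)
    qa[cloud] |= 1 << _CLOUD_QA_BIT
    bands["qa"] = qa

    px = params.pixel_size_m
    transform = Affine(px, 0.0, 500000.0, 0.0, -px, 4000000.0)
    stack = BandStack(
        bands=bands,
        valid_mask=np.ones((h, w), dtype=bool),
        transform=transform,
        crs_id="EPSG:32648",
        sensor=params.sensor,
    )
    return stack, GroundTruth(quality=q, zone_labels=labels, transform=transform)


def generate_regions(params: SceneParams, n_regions: int) -> dict[str, Polygon]:
    """Tile the scene extent into ``n_regions`` rectangular districts.

    The tiling is an exact partition with edges on pixel boundaries (a
    rows×cols grid with rows the largest divisor of n_regions not exceeding
    its square root, so a prime count degrades to column strips).
    """
    if n_regions < 1:
        raise ConfigurationError("n_regions must be >= 1")
    if n_regions > params.width * params.height:
        raise ConfigurationError("more regions than pixels")
    n_rows = 1
    for cand in range(int(np.sqrt(n_regions)), 0, -1):
        if n_regions % cand == 0:
            n_rows = cand
            break
    n_cols = n_regions // n_rows
    row_edges = np.linspace(0, params.height, n_rows + 1).round().astype(int)
    col_edges = np.linspace(0, params.width, n_cols + 1).round().astype(int)
    px = params.pixel_size_m
    x0, y0 = 500000.0, 4000000.0
    regions: dict[str, Polygon] = {}
    k = 0
    for i in range(n_rows):
        for j in range(n_cols):
            k += 1
            left, right = x0 + col_edges[j] * px, x0 + col_edges[j + 1] * px
            top, bottom = y0 - row_edges[i] * px, y0 - row_edges[i + 1] * px
            regions[f"R{k:02d}"] = Polygon(
                [(left, bottom), (right, bottom), (right, top), (left, top)]
            )
    return regions


def generate_ei_table(
    truth: GroundTruth,
    regions: Mapping[str, BaseGeometry],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, float]:
    """Reference EI per region: 100 × regional mean latent quality + noise,
    clipped to [0, 100]."""
    import shapely

    rng = np.random.default_rng(seed)
    h, w = truth.quality.shape
    rows, cols = np.mgrid[0:h, 0:w]
    xs, ys = truth.transform.xy(rows.ravel(), cols.ravel())
    qflat = truth.quality.ravel()
    table: dict[str, float] = {}
    for rid, geom in regions.items():
        inside = shapely.contains_xy(geom, xs, ys)
        mean_q = float(qflat[inside].mean()) if inside.any() else float("nan")
        ei = 100.0 * mean_q + rng.normal(0.0, noise_sd)
        table[rid] = float(np.clip(ei, 0.0, 100.0))
    return table


def regions_to_geojson(regions: Mapping[str, BaseGeometry]) -> dict:
    """Serializable GeoJSON FeatureCollection with an ``id`` property."""
    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"id": rid}, "geometry": mapping(geom)}
            for rid, geom in regions.items()
        ],
    }
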