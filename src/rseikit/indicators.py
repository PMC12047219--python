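"""Spectral indicators feeding the composite index.

Greenness (NDVI), moisture (tasseled-cap WET), dryness (NDSI, the mean of the
soil index SI and the index-based built-up index IBI), heat (LST in Celsius)
and particulate load (DI = red − NIR, a PM2.5 proxy), plus the MNDWI open-water
mask and frequency histograms of indicator distributions.

All ratio indices invalidate (rather than clamp) pixels whose denominator is
exactly zero; masks propagate from the source stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError
from .raster_io import REFLECTANCE_BANDS, BandStack, WET_COEFFICIENTS


@dataclass
class IndicatorRaster:
    """One indicator on the source grid with its own validity mask."""

    name: str
    values: np.ndarray
    valid_mask: np.ndarray
    units: str = "dimensionless"
    components: dict[str, "IndicatorRaster"] = field(default_factory=dict)

    def masked_values(self) -> np.ndarray:
        """Values of valid pixels as a flat array."""
        return self.values[self.valid_mask]

    def mask_where(self, exclude: np.ndarray) -> "IndicatorRaster":
        """Copy with additional pixels (e.g. open water) removed from the mask."""
        return IndicatorRaster(
            name=self.name,
            values=self.values.copy(),
            valid_mask=self.valid_mask & ~np.asarray(exclude, dtype=bool),
            units=self.units,
            components=self.components,
        )


def _ratio(num: np.ndarray, den: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = valid & (den != 0)
    out = np.full(num.shape, np.nan)
    np.divide(num, den, out=out, where=ok)
    return out, ok


def ndvi(stack: BandStack) -> IndicatorRaster:
    """Normalized difference vegetation index (NIR − red)/(NIR + red)."""
    nir, red = stack.band("nir"), stack.band("red")
    vals, ok = _ratio(nir - red, nir + red, stack.valid_mask)
    return IndicatorRaster("NDVI", vals, ok)


def wet(stack: BandStack) -> IndicatorRaster:
    """Tasseled-cap wetness: fixed six-band linear combination.

    Coefficients are sensor-specific (TM vs OLI); an unknown sensor is a
    configuration error.
    """
    try:
        coeffs = WET_COEFFICIENTS[stack.sensor]
    except KeyError:
        raise ConfigurationError(
            f"no wetness coefficients for sensor {stack.sensor!r}") from None
    vals = np.zeros(stack.shape, dtype=np.float64)
    for c, name in zip(coeffs, REFLECTANCE_BANDS):
        vals = vals + c * stack.band(name)
    out = np.where(stack.valid_mask, vals, np.nan)
    return IndicatorRaster("WET", out, stack.valid_mask.copy())


def mndwi_water_mask(
    stack: BandStack, threshold: float = 0.0
) -> tuple[IndicatorRaster, np.ndarray]:
    """MNDWI = (green − swir1)/(green + swir1); water where MNDWI > threshold."""
    green, swir1 = stack.band("green"), stack.band("swir1")
    vals, ok = _ratio(green - swir1, green + swir1, stack.valid_mask)
    water = ok & (vals > threshold)
    return IndicatorRaster("MNDWI", vals, ok), water


def lst(stack: BandStack) -> IndicatorRaster:
    """Land surface temperature in Celsius: ST band (Kelvin) − 273.15."""
    st = stack.band("st")
    vals = np.where(stack.valid_mask, st - 273.15, np.nan)
    return IndicatorRaster("LST", vals, stack.valid_mask.copy(), units="degC")


def ndsi(stack: BandStack) -> IndicatorRaster:
    """Dryness index NDSI = (SI + IBI)/2.

    SI contrasts (swir1 + red) against (blue + nir); IBI contrasts the
    built-up response 2·swir1/(swir1+nir) against the vegetation and water
    responses nir/(red+nir) and green/(swir1+green).  SI and IBI are
    retrievable from ``components``.
    """
    blue, green, red = stack.band("blue"), stack.band("green"), stack.band("red")
    nir, swir1 = stack.band("nir"), stack.band("swir1")

    si_vals, si_ok = _ratio(
        (swir1 + red) - (blue + nir), (swir1 + red) + (blue + nir), stack.valid_mask
    )

    inner_ok = stack.valid_mask & (swir1 + nir != 0) & (red + nir != 0) & (swir1 + green != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        built = 2.0 * swir1 / (swir1 + nir)
        veg = nir / (red + nir)
        wat = green / (swir1 + green)
        ibi_num = built - (veg + wat)
        ibi_den = built + (veg + wat)
    ibi_vals, ibi_ok = _ratio(ibi_num, ibi_den, inner_ok)

    ok = si_ok & ibi_ok
    vals = np.where(ok, 0.5 * (si_vals + ibi_vals), np.nan)
    return IndicatorRaster(
        "NDSI", vals, ok,
        components={
            "SI": IndicatorRaster("SI", si_vals, si_ok),
            "IBI": IndicatorRaster("IBI", ibi_vals, ibi_ok),
        },
    )


def di(stack: BandStack) -> IndicatorRaster:
    """Difference index DI = red − NIR, a particulate (PM2.5) proxy."""
    red, nir = stack.band("red"), stack.band("nir")
    vals = np.where(stack.valid_mask, red - nir, np.nan)
    return IndicatorRaster("DI", vals, stack.valid_mask.copy())


def frequency_histogram(
    indicator: IndicatorRaster,
    n_bins: int,
    value_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Percentage-of-frequency histogram over valid pixels.

    Returns a DataFrame with columns (bin_left, bin_right, percent); the
    percentages sum to 100 over the binned pixels.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    vals = indicator.masked_values()
    if vals.size == 0:
        raise DegenerateDataError("no valid pixels to histogram")
    counts, edges = np.histogram(vals, bins=n_bins, range=value_range)
    total = counts.sum()
    if total == 0:
        raise DegenerateDataError("no valid pixels fall inside the given range")
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "percent": 100.0 * counts / total,
        }
    )
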