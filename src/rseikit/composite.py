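"""PCA fusion of the four indicators into RSEI or DRSEI.

Pipeline: min–max normalize each indicator to [0, 1] over the jointly valid
pixels, eigendecompose the population (1/N) covariance of the pixel vectors,
orient the first principal component so greenness loads positively, and
min–max normalize the PC1 score field to the final [0, 1] index.

RSEI fuses {NDVI, WET, NDSI, LST}; DRSEI replaces the heat axis with the
particulate DI, fusing {NDVI, WET, NDSI, DI}.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError
from .indicators import (
    IndicatorRaster,
    di as _di,
    lst as _lst,
    mndwi_water_mask,
    ndsi as _ndsi,
    ndvi as _ndvi,
    wet as _wet,
)
from .raster_io import Affine, BandStack

INDICATOR_SETS = {
    "RSEI": ("NDVI", "WET", "NDSI", "LST"),
    "DRSEI": ("NDVI", "WET", "NDSI", "DI"),
}


@dataclass
class IndicatorStack:
    """Co-registered indicators sharing one joint validity mask."""

    indicators: list[IndicatorRaster]
    joint_valid_mask: np.ndarray
    normalized: bool
    transform: Affine | None = None
    crs_id: str = "unknown"

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(ind.name for ind in self.indicators)

    def matrix(self) -> np.ndarray:
        """(n_valid_pixels, n_indicators) data matrix over the joint mask."""
        return np.column_stack(
            [ind.values[self.joint_valid_mask] for ind in self.indicators]
        )


@dataclass
class PCAResult:
    """Loadings, eigenvalues, contribution rates and the PC1 score grid.

    ``loadings[:, j]`` is the unit-norm eigenvector of component j (descending
    eigenvalue order); ``contribution_rates`` are eigenvalue shares in
    percent.
    """

    names: tuple[str, ...]
    loadings: np.ndarray
    eigenvalues: np.ndarray
    contribution_rates: np.ndarray
    pc1_raster: np.ndarray
    valid_mask: np.ndarray
    oriented: bool = False

    def loading(self, name: str, component: int = 0) -> float:
        return float(self.loadings[self.names.index(name), component])


@dataclass
class IndexRaster:
    """Final [0, 1] ecological-quality index with its PCA provenance."""

    name: str
    values: np.ndarray
    valid_mask: np.ndarray
    provenance: PCAResult
    transform: Affine | None = None
    crs_id: str = "unknown"


def normalize01(indicator: IndicatorRaster) -> IndicatorRaster:
    """Min–max rescale to [0, 1] over valid pixels.

    A constant raster has zero range and no meaningful normalization.
    """
    vals = indicator.masked_values()
    if vals.size < 2:
        raise DegenerateDataError("need at least two valid pixels to normalize")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise DegenerateDataError(
            f"indicator {indicator.name!r} is constant; cannot normalize")
    out = np.full(indicator.values.shape, np.nan)
    out[indicator.valid_mask] = (indicator.values[indicator.valid_mask] - lo) / (hi - lo)
    return IndicatorRaster(indicator.name, out, indicator.valid_mask.copy(),
                           units="dimensionless")


def make_indicator_stack(
    indicators: list[IndicatorRaster],
    transform: Affine | None = None,
    crs_id: str = "unknown",
) -> IndicatorStack:
    shp = indicators[0].values.shape
    joint = np.ones(shp, dtype=bool)
    for ind in indicators:
        if ind.values.shape != shp:
            raise ConfigurationError("indicator grids are not aligned")
        joint &= ind.valid_mask
    return IndicatorStack(indicators, joint, normalized=False,
                          transform=transform, crs_id=crs_id)


def normalize_stack(stack: IndicatorStack) -> IndicatorStack:
    """Normalize every indicator to [0, 1] over the joint-valid pixels."""
    normed = []
    for ind in stack.indicators:
        restricted = IndicatorRaster(ind.name, ind.values, stack.joint_valid_mask)
        normed.append(normalize01(restricted))
    return IndicatorStack(normed, stack.joint_valid_mask.copy(), normalized=True,
                          transform=stack.transform, crs_id=stack.crs_id)


def pca(
    stack: IndicatorStack,
    max_samples: int | None = None,
    seed: int = 0,
) -> PCAResult:
    """Eigendecomposition of the covariance of the normalized pixel vectors.

    Components are sorted by descending eigenvalue; each eigenvector's sign is
    fixed by making its largest-magnitude entry positive (deterministic
    tie-break; the ecological orientation is applied by :func:`orient_pc1`).
    PC1 scores are the mean-centered projections, mapped back onto the grid.
    ``max_samples`` optionally subsamples the pixels entering the covariance
    estimate (seeded); scores are always computed for every valid pixel.
    """
    if not stack.normalized:
        raise ConfigurationError("pca expects a normalized IndicatorStack")
    X = stack.matrix()
    n, k = X.shape
    if n < 5:
        raise DegenerateDataError("need at least 5 jointly valid pixels for PCA")
    Xc_full = X - X.mean(axis=0)
    if max_samples is not None and n > max_samples:
        rng = np.random.default_rng(seed)
        sel = rng.choice(n, size=max_samples, replace=False)
        Xs = X[sel]
        Xs = Xs - Xs.mean(axis=0)
    else:
        Xs = Xc_full
    cov = (Xs.T @ Xs) / Xs.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    if eigvals[0] <= 0:
        raise DegenerateDataError("covariance has no positive eigenvalue")
    for j in range(k):
        i_max = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i_max, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    contrib = 100.0 * eigvals / eigvals.sum()
    scores = Xc_full @ eigvecs[:, 0]
    pc1 = np.full(stack.joint_valid_mask.shape, np.nan)
    pc1[stack.joint_valid_mask] = scores
    return PCAResult(
        names=stack.names,
        loadings=eigvecs,
        eigenvalues=eigvals,
        contribution_rates=contrib,
        pc1_raster=pc1,
        valid_mask=stack.joint_valid_mask.copy(),
        oriented=False,
    )


def orient_pc1(result: PCAResult) -> PCAResult:
    """Fix the ecological polarity of PC1: greenness must load positively.

    If the NDVI loading on PC1 is negative, PC1's loadings and score grid are
    negated; an exactly-zero NDVI loading falls back to the WET loading sign.
    """
    idx = result.names.index("NDVI")
    lead = result.loadings[idx, 0]
    if lead == 0.0 and "WET" in result.names:
        lead = result.loadings[result.names.index("WET"), 0]
    loadings = result.loadings.copy()
    pc1 = result.pc1_raster
    if lead < 0:
        loadings[:, 0] = -loadings[:, 0]
        pc1 = -pc1
    return replace(result, loadings=loadings, pc1_raster=pc1, oriented=True)


def build_index(
    stack: IndicatorStack,
    which: str = "DRSEI",
    max_samples: int | None = None,
    seed: int = 0,
) -> tuple[IndexRaster, PCAResult]:
    """Raw indicators → normalized stack → oriented PC1 → [0, 1] index."""
    which = which.upper()
    if which not in INDICATOR_SETS:
        raise ConfigurationError(f"unknown index {which!r}")
    expected = INDICATOR_SETS[which]
    if stack.names != expected:
        raise ConfigurationError(
            f"{which} requires indicators {expected}, got {stack.names}")
    normed = stack if stack.normalized else normalize_stack(stack)
    result = orient_pc1(pca(normed, max_samples=max_samples, seed=seed))
    pc1_ind = IndicatorRaster("PC1", result.pc1_raster, result.valid_mask)
    final = normalize01(pc1_ind)
    index = IndexRaster(
        name=which,
        values=final.values,
        valid_mask=final.valid_mask,
        provenance=result,
        transform=stack.transform,
        crs_id=stack.crs_id,
    )
    return index, result


def compute_indicators(
    stack: BandStack,
    which: str = "DRSEI",
    water_threshold: float = 0.0,
    mask_water: bool = True,
) -> IndicatorStack:
    """Compute the four raw component indicators from a band stack.

    Open water (MNDWI > ``water_threshold``) is removed from every
    indicator's validity mask so the PCA sample is consistent across
    components.
    """
    which = which.upper()
    if which not in INDICATOR_SETS:
        raise ConfigurationError(f"unknown index {which!r}")
    _, water = mndwi_water_mask(stack, water_threshold)
    fourth = _lst(stack) if which == "RSEI" else _di(stack)
    inds = [_ndvi(stack), _wet(stack), _ndsi(stack), fourth]
    if mask_water:
        inds = [ind.mask_where(water) for ind in inds]
    return make_indicator_stack(inds, transform=stack.transform, crs_id=stack.crs_id)


def pca_report(result: PCAResult, which: str, scene: str = "") -> dict:
    """One row of the loading/contribution report (Table-3 style layout)."""
    row = {
        "scene": scene,
        "model": which,
        "contribution_pc1": float(result.contribution_rates[0]),
    }
    for name in result.names:
        row[f"loading_{name}"] = result.loading(name)
    return row


def report_to_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)
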