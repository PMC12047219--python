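"""Taylor-diagram verification statistics.

Correlation, standard deviation and centered RMS difference between a model
series (RSEI/DRSEI zonal means) and a reference series (EI), using population
(1/N) moments throughout.  The statistics satisfy the Taylor law of cosines
E'^2 = sd_f^2 + sd_p^2 - 2*sd_f*sd_p*r, which is what places each model as a
single point on a Taylor diagram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError


@dataclass
class PairedSample:
    """Reference series f (EI role) paired with model series p."""

    f: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.f.shape != self.p.shape or self.f.ndim != 1:
            raise ValueError("f and p must be 1-D arrays of equal length")
        if self.f.size < 2:
            raise ValueError("need at least two paired observations")
        if not (np.all(np.isfinite(self.f)) and np.all(np.isfinite(self.p))):
            raise ValueError("paired sample contains non-finite values")

    @property
    def n(self) -> int:
        return self.f.size


@dataclass
class TaylorStats:
    r: float
    sd_f: float
    sd_p: float
    rms_centered: float
    bias: float


def std_dev(x: Sequence[float] | np.ndarray) -> float:
    """Population standard deviation sqrt((1/N) * sum((x - mean)^2))."""
    x = np.asarray(x, dtype=np.float64)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def pearson_r(s: PairedSample) -> float:
    """Pearson correlation with population moments; constant series are
    degenerate."""
    sf, sp = std_dev(s.f), std_dev(s.p)
    if sf == 0.0 or sp == 0.0:
        raise DegenerateDataError("zero variance; correlation undefined")
    cov = float(np.mean((s.f - s.f.mean()) * (s.p - s.p.mean())))
    return cov / (sf * sp)


def average_correlation(correlations: Sequence[float], n: int) -> float:
    """Mean absolute pairwise correlation of one indicator against the other
    n−1 indicators."""
    correlations = list(correlations)
    if len(correlations) == 0:
        raise ValueError("need at least one correlation")
    if len(correlations) != n - 1:
        raise ValueError(f"expected n-1={n - 1} correlations, got {len(correlations)}")
    return float(np.mean(np.abs(correlations)))


def centered_rms(s: PairedSample) -> float:
    """Centered pattern RMS difference between anomalies of f and p.

    sqrt((1/N) * sum(((f - fbar) - (p - pbar))^2)); the overall bias is
    removed by the centering, so it is the Taylor-diagram distance to the
    reference point.
    """
    d = (s.f - s.f.mean()) - (s.p - s.p.mean())
    return float(np.sqrt(np.mean(d**2)))


def taylor_stats(s: PairedSample) -> TaylorStats:
    """Bundle (r, sd_f, sd_p, E', bias) for one model-vs-reference pair."""
    return TaylorStats(
        r=pearson_r(s),
        sd_f=std_dev(s.f),
        sd_p=std_dev(s.p),
        rms_centered=centered_rms(s),
        bias=float(s.f.mean() - s.p.mean()),
    )
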