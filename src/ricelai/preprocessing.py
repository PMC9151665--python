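"""NDVI composite preprocessing: QA masking, spline gap-filling, LAI conversion.

The pipeline ingests 8-day NDVI composites (MOD09A1-style, with 16-bit QA
flags).  Cloud- and aerosol-contaminated composites are masked by a QA rule,
the gaps are filled with a cubic interpolating spline through the good
values, and NDVI is converted to LAI by an empirical exponential relation

    LAI = alpha * exp(beta * NDVI),

with configurable coefficients (defaults alpha = 0.1 m^2 m^-2, beta = 4.0,
which map NDVI ~ 0.9 to LAI ~ 3.7, typical for paddy rice at peak canopy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .exceptions import ConfigError, InsufficientDataError, InvalidInputError

__all__ = [
    "CompositeSeries",
    "NdviLaiCoefficients",
    "DEFAULT_NDVI_LAI",
    "qa_filter",
    "spline_fill",
    "ndvi_to_lai",
    "lai_to_ndvi",
]

logger = logging.getLogger(__name__)

COMPOSITE_STEP_DAYS = 8


@dataclass(frozen=True)
class CompositeSeries:
    """An 8-day NDVI composite series for one pixel with a quality mask."""

    dates: pd.DatetimeIndex       # composite start dates, strictly increasing, 8-day step
    ndvi: np.ndarray              # values in [-1, 1]; may be anything where not qa_good
    qa_good: np.ndarray           # boolean, True where the composite is usable

    def __post_init__(self):
        dates = pd.DatetimeIndex(self.dates)
        if not (len(dates) == len(self.ndvi) == len(self.qa_good)):
            raise InvalidInputError("composite series fields must have equal length")
        steps = np.diff(dates.to_numpy()).astype("timedelta64[D]").astype(int)
        if len(steps) and not (steps == COMPOSITE_STEP_DAYS).all():
            raise InvalidInputError("composite dates must step by exactly 8 days")
        good = np.asarray(self.qa_good, dtype=bool)
        ndvi = np.asarray(self.ndvi, dtype=float)
        if good.any() and not np.isfinite(ndvi[good]).all():
            raise InvalidInputError("non-finite NDVI at a good-quality date")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "ndvi", ndvi)
        object.__setattr__(self, "qa_good", good)

    def __len__(self):
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "ndvi": self.ndvi, "qa": self.qa_good.astype(int)}
        )


@dataclass(frozen=True)
class NdviLaiCoefficients:
    """Coefficients of the exponential NDVI-LAI relation LAI = alpha*exp(beta*NDVI)."""

    alpha: float = 0.1  # m^2 m^-2, LAI at NDVI = 0
    beta: float = 4.0   # dimensionless rate

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise InvalidInputError("alpha and beta must be strictly positive")


DEFAULT_NDVI_LAI = NdviLaiCoefficients()


def qa_filter(series: CompositeSeries, qa_values, qa_rule: dict[int, int]) -> CompositeSeries:
    """Update the quality mask from 16-bit QA words and a bit rule.

    ``qa_rule`` maps bit position (0-15) to the required bit value (0 or 1);
    a composite is good only if every listed bit matches.  An empty rule
    leaves the mask unchanged.  NDVI values are never modified.
    """
    for bit, want in qa_rule.items():
        if not (0 <= int(bit) <= 15):
            raise ConfigError(f"QA bit position {bit} outside 0-15")
        if int(want) not in (0, 1):
            raise ConfigError(f"QA bit value must be 0 or 1, got {want}")
    if not qa_rule:
        return series
    qa_values = np.asarray(qa_values, dtype=np.uint16)
    if qa_values.shape != (len(series),):
        raise InvalidInputError("QA word array must match series length")
    good = series.qa_good.copy()
    for bit, want in qa_rule.items():
        good &= ((qa_values >> int(bit)) & 1) == int(want)
    return replace(series, qa_good=good)


def spline_fill(series: CompositeSeries) -> CompositeSeries:
    """Replace masked NDVI values with a cubic interpolating spline.

    A not-a-knot cubic spline is fit through the good-quality points (so it
    reproduces cubic polynomials exactly) and evaluated at masked dates.
    Good values pass through bit-identically.  Gaps before the first or
    after the last good point are held at the nearest good value, since the
    spline would extrapolate wildly there.
    """
    good = series.qa_good
    if good.sum() < 4:
        raise InsufficientDataError(
            f"spline gap-filling needs >= 4 good composites, have {int(good.sum())}"
        )
    if good.all():
        return replace(series, qa_good=np.ones(len(series), dtype=bool))
    # day offsets from the first composite as the spline abscissa
    x = (series.dates - series.dates[0]).days.to_numpy(dtype=float)
    spline = CubicSpline(x[good], series.ndvi[good], bc_type="not-a-knot")
    ndvi = series.ndvi.copy()
    masked = ~good
    ndvi[masked] = spline(x[masked])
    good_idx = np.flatnonzero(good)
    lead = masked & (np.arange(len(series)) < good_idx[0])
    trail = masked & (np.arange(len(series)) > good_idx[-1])
    if lead.any():
        ndvi[lead] = series.ndvi[good_idx[0]]
        logger.info("leading gap of %d composites held at first good value", lead.sum())
    if trail.any():
        ndvi[trail] = series.ndvi[good_idx[-1]]
        logger.info("trailing gap of %d composites held at last good value", trail.sum())
    return CompositeSeries(
        dates=series.dates, ndvi=ndvi, qa_good=np.ones(len(series), dtype=bool)
    )


def ndvi_to_lai(ndvi, coeffs: NdviLaiCoefficients = DEFAULT_NDVI_LAI):
    """Convert NDVI in [-1, 1] to LAI via LAI = alpha*exp(beta*NDVI)."""
    ndvi = np.asarray(ndvi, dtype=float)
    if np.any(ndvi < -1) or np.any(ndvi > 1) or not np.isfinite(ndvi).all():
        raise InvalidInputError("NDVI outside [-1, 1]")
    out = coeffs.alpha * np.exp(coeffs.beta * ndvi)
    return float(out) if out.ndim == 0 else out


def lai_to_ndvi(lai, coeffs: NdviLaiCoefficients = DEFAULT_NDVI_LAI):
    """Exact inverse of :func:`ndvi_to_lai`: NDVI = ln(LAI/alpha)/beta."""
    lai = np.asarray(lai, dtype=float)
    lo = coeffs.alpha * np.exp(-coeffs.beta)
    hi = coeffs.alpha * np.exp(coeffs.beta)
    if np.any(lai < lo * (1 - 1e-12)) or np.any(lai > hi * (1 + 1e-12)):
        raise InvalidInputError(
            f"LAI outside attainable range [{lo:.4g}, {hi:.4g}] of the NDVI relation"
        )
    out = np.log(lai / coeffs.alpha) / coeffs.beta
    out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out
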