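"""Agreement statistics for observed versus simulated LAI series.

Two indices are used throughout the package: the root mean square error
(RMSE, in the units of the series, here m^2 m^-2) and the Nash-Sutcliffe
model efficiency (ME),

    ME = 1 - SSE / SST,

where SSE is the sum of squared residuals between simulation and
observation and SST the total sum of squares of the observations about
their own mean.  ME lies in (-inf, 1]; 1 is a perfect fit and 0 means the
simulation is no better than predicting the observed mean.

For reporting, ME is mapped onto (0, 1] by the normalization

    nME = 1 / (2 - ME),

the smallest smooth rational map through the three anchor points
ME = 1, 0, -inf -> nME = 1, 0.5, 0.  A model is considered reliable when
the normalized value is near 1 and undependable near 0.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError, UndefinedStatisticError

__all__ = ["rmse", "nse", "normalized_me", "r2_score"]


def _paired(obs, sim) -> tuple[np.ndarray, np.ndarray]:
    """Validate and coerce an (obs, sim) pair of equal-length finite series."""
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.ndim != 1 or sim.ndim != 1:
        raise InvalidInputError("obs and sim must be one-dimensional series")
    if obs.shape != sim.shape:
        raise InvalidInputError(
            f"length mismatch: obs has {obs.size} values, sim has {sim.size}"
        )
    if obs.size < 2:
        raise InvalidInputError("paired series need at least 2 points")
    if not (np.isfinite(obs).all() and np.isfinite(sim).all()):
        # NaNs are a preprocessing failure, not something to drop silently.
        raise InvalidInputError("non-finite value in paired series")
    return obs, sim


def rmse(obs, sim) -> float:
    """Root mean square error between observed and simulated values."""
    obs, sim = _paired(obs, sim)
    return float(np.sqrt(np.mean((sim - obs) ** 2)))


def nse(obs, sim) -> float:
    """Raw Nash-Sutcliffe model efficiency, 1 - SSE/SST, in (-inf, 1].

    Raises
    ------
    UndefinedStatisticError
        If the observations have zero variance (SST = 0).
    """
    obs, sim = _paired(obs, sim)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedStatisticError(
            "Nash-Sutcliffe efficiency undefined: observations have zero variance"
        )
    sse = float(np.sum((sim - obs) ** 2))
    return 1.0 - sse / sst


def normalized_me(raw_nse: float) -> float:
    """Map a raw Nash-Sutcliffe efficiency onto (0, 1].

    Uses nME = 1 / (2 - ME), the monotone rational map with fixed points
    1 -> 1 and 0 -> 0.5 and limit -inf -> 0.
    """
    raw_nse = float(raw_nse)
    if np.isnan(raw_nse) or raw_nse > 1.0:
        raise InvalidInputError(f"raw efficiency must be <= 1, got {raw_nse}")
    if raw_nse == -np.inf:
        return 0.0
    return 1.0 / (2.0 - raw_nse)


def r2_score(obs, sim) -> float:
    """Coefficient of determination on the given pairs.

    Identical to :func:`nse`; exposed under the name used when scoring
    regressors on train/test subsets.
    """
    return nse(obs, sim)
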