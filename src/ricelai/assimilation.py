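"""Within-season calibration of the crop model to observed or estimated LAI.

This is the assimilation step of the hybrid regime: the four growth
parameters (L0, a, b, c) are fitted to a season's LAI observations by
minimizing the sum of squared differences between the simulated trajectory
and the observations at their dates, using Powell's derivative-free
direction-set method.  The search runs over unit-scaled parameters with
bound-constrained line searches, so the returned parameters are inside
their bounds by construction.  (A logit reparameterization was tried and
rejected: warping the coordinates flattens the objective near the bounds
and strands the direction set in spurious valleys.)

The module follows the model/results idiom: build a
:class:`LAIAssimilation` from the observations and weather, call
:meth:`~LAIAssimilation.fit`, and read estimates, diagnostics and the
fitted trajectory off the returned :class:`CalibrationResult`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import metrics
from .crop_model import (
    DEFAULT_BOUNDS,
    CropParameters,
    LAITrajectory,
    ParameterBounds,
    SeasonConfig,
    lai_at_dates,
    simulate_lai,
)
from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    OptimizerFailureError,
)
from .ml import FitResult, build_features, predict_lai

__all__ = [
    "ObservationSet",
    "LAIAssimilation",
    "CalibrationResult",
    "powell_calibrate",
    "run_hybrid",
    "cross_region_evaluate",
]

logger = logging.getLogger(__name__)

SOURCES = ("ndvi_baseline", "ml_estimated", "dnn_estimated")


@dataclass(frozen=True)
class ObservationSet:
    """LAI observations for one season: dates, values, and their provenance."""

    dates: pd.DatetimeIndex
    lai_obs: np.ndarray
    source: str = "ndvi_baseline"

    def __post_init__(self):
        dates = pd.DatetimeIndex(pd.to_datetime(self.dates))
        lai = np.asarray(self.lai_obs, dtype=float)
        if len(dates) != len(lai):
            raise InvalidInputError("dates and lai_obs must have equal length")
        if len(dates) < 4:
            raise InsufficientDataError(
                f"within-season calibration needs >= 4 observations, have {len(dates)}"
            )
        if not np.isfinite(lai).all() or (lai < 0).any():
            raise InvalidInputError("LAI observations must be finite and non-negative")
        if self.source not in SOURCES:
            raise InvalidInputError(f"source must be one of {SOURCES}")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "lai_obs", lai)

    def __len__(self):
        return len(self.dates)


# ---------------------------------------------------------------------------
# unit scaling: x in [lo, hi]  <->  u in [0, 1]


def _to_unit(x, lo, hi):
    return (x - lo) / (hi - lo)


def _from_unit(u, lo, hi):
    return np.clip(lo + (hi - lo) * np.asarray(u, dtype=float), lo, hi)


class LAIAssimilation:
    """Model object binding a season's observations, weather and bounds.

    Parameters
    ----------
    obs : ObservationSet
        LAI observations (satellite-derived or regressor-estimated).
    weather : DataFrame
        Daily weather covering the season (date, tmax, tmin, srad).
    season : SeasonConfig
        Fixed season constants (transplant date, thermal-time settings).
    bounds : ParameterBounds
        Box bounds for the four calibratable parameters.
    """

    def __init__(
        self,
        obs: ObservationSet,
        weather: pd.DataFrame,
        season: SeasonConfig,
        bounds: ParameterBounds = DEFAULT_BOUNDS,
    ):
        self.obs = obs
        self.weather = weather
        self.season = season
        self.bounds = bounds
        span = season.dates
        outside = obs.dates.difference(span)
        if len(outside):
            raise InvalidInputError(
                f"observation date outside simulated span: {outside[0].date()}"
            )

    @classmethod
    def from_dataframe(
        cls,
        obs_frame: pd.DataFrame,
        weather: pd.DataFrame,
        season: SeasonConfig,
        bounds: ParameterBounds = DEFAULT_BOUNDS,
        source: str = "ndvi_baseline",
    ) -> "LAIAssimilation":
        """Build from an observation table with columns date and lai."""
        obs = ObservationSet(
            dates=pd.to_datetime(obs_frame["date"]),
            lai_obs=obs_frame["lai"].to_numpy(dtype=float),
            source=source,
        )
        return cls(obs, weather, season, bounds)

    def simulate(self, params: CropParameters) -> LAITrajectory:
        return simulate_lai(params, self.weather, self.season)

    def objective(self, params: CropParameters) -> float:
        """Sum of squared LAI residuals at the observation dates (m^4 m^-4)."""
        traj = self.simulate(params)
        sim = lai_at_dates(traj, self.obs.dates)
        resid = sim - self.obs.lai_obs
        return float(resid @ resid)

    def fit(
        self,
        start: CropParameters | None = None,
        *,
        ftol: float = 1e-8,
        maxiter: int = 200,
        fixed: dict[str, float] | None = None,
    ) -> "CalibrationResult":
        """Calibrate by Powell's method; returns a :class:`CalibrationResult`.

        Starts from the bound-interval midpoints unless ``start`` is given.
        Parameters named in ``fixed`` are pinned at the given values and
        excluded from the search (slice calibrations).  Convergence:
        successive objective improvement below ``ftol`` or ``maxiter``
        direction-set iterations.
        """
        lo, hi = self.bounds.as_arrays()
        if start is None:
            start = self.bounds.midpoint()
        fixed = dict(fixed or {})
        unknown = set(fixed) - set(CropParameters.names)
        if unknown:
            raise InvalidInputError(f"unknown fixed parameter(s): {sorted(unknown)}")
        if fixed:
            merged = {n: fixed.get(n, getattr(start, n)) for n in CropParameters.names}
            start = CropParameters(**merged)
        if not self.bounds.contains(start):
            raise InvalidInputError("start parameters outside bounds")
        free = [i for i, n in enumerate(CropParameters.names) if n not in fixed]
        if not free:
            raise InvalidInputError("all four parameters fixed: nothing to calibrate")
        x_full = start.as_array()

        best = [None, np.inf]  # salvage state for optimizer failures

        def fun(u):
            x = x_full.copy()
            x[free] = _from_unit(u, lo[free], hi[free])
            try:
                params = CropParameters.from_array(x)
            except InvalidInputError:
                # infeasible corner (l0 > b) inside the box: steer away
                return 1e12 * (1.0 + float(x[0] - x[2]))
            val = self.objective(params)
            if not np.isfinite(val):
                raise OptimizerFailureError(
                    "non-finite objective during Powell search",
                    last_good=tuple(best),
                )
            if val < best[1]:
                best[0], best[1] = params, val
            return val

        u0 = _to_unit(x_full[free], lo[free], hi[free])
        res = minimize(
            fun,
            u0,
            method="Powell",
            bounds=[(0.0, 1.0)] * len(free),
            options={"ftol": ftol, "xtol": 1e-8, "maxiter": maxiter, "maxfev": 100000},
        )
        x = x_full.copy()
        x[free] = _from_unit(res.x, lo[free], hi[free])
        params = CropParameters.from_array(x)
        objective = self.objective(params)
        f0 = self.objective(start)
        if objective > f0:  # Powell should never worsen; keep the start if it did
            params, objective = start, f0
        traj = self.simulate(params)
        return CalibrationResult(
            model=self,
            params=params,
            objective=objective,
            start=start,
            start_objective=f0,
            n_iter=int(res.nit),
            converged=bool(res.success),
            trajectory=traj,
        )


@dataclass
class CalibrationResult:
    """Fitted parameters, fit diagnostics and the calibrated trajectory."""

    model: LAIAssimilation
    params: CropParameters
    objective: float          # SSE at observation dates, m^4 m^-4
    start: CropParameters
    start_objective: float
    n_iter: int
    converged: bool
    trajectory: LAITrajectory

    @property
    def sim_at_obs(self) -> np.ndarray:
        return lai_at_dates(self.trajectory, self.model.obs.dates)

    @property
    def rmse(self) -> float:
        return metrics.rmse(self.model.obs.lai_obs, self.sim_at_obs)

    @property
    def me(self) -> float:
        """Normalized Nash-Sutcliffe efficiency against the observations."""
        return metrics.normalized_me(metrics.nse(self.model.obs.lai_obs, self.sim_at_obs))

    def predict(self, dates=None) -> np.ndarray:
        """Calibrated LAI at the given dates (defaults to observation dates)."""
        if dates is None:
            return self.sim_at_obs
        return lai_at_dates(self.trajectory, dates)

    def summary(self) -> str:
        """Plain-text summary table of the calibration."""
        b = self.model.bounds
        lines = [
            "Within-season LAI calibration (Powell)",
            "=" * 54,
            f"observations: {len(self.model.obs)} ({self.model.obs.source})",
            f"season start: {self.model.season.transplant_date}  "
            f"length: {self.model.season.season_length} d",
            f"converged: {self.converged}  iterations: {self.n_iter}",
            f"objective (SSE): {self.objective:.6g}  (start {self.start_objective:.6g})",
            f"RMSE: {self.rmse:.4f} m2 m-2   ME: {self.me:.4f}",
            "-" * 54,
            f"{'param':>6} {'estimate':>12} {'start':>12} {'bounds':>18}",
        ]
        for name in CropParameters.names:
            lo, hi = getattr(b, name)
            lines.append(
                f"{name:>6} {getattr(self.params, name):>12.6g} "
                f"{getattr(self.start, name):>12.6g} "
                f"{'[' + format(lo, 'g') + ', ' + format(hi, 'g') + ']':>18}"
            )
        lines.append("=" * 54)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": {n: getattr(self.params, n) for n in CropParameters.names},
            "objective": self.objective,
            "start_objective": self.start_objective,
            "iterations": self.n_iter,
            "converged": self.converged,
            "rmse": self.rmse,
            "me": self.me,
            "source": self.model.obs.source,
        }

    def plot(self, ax=None):
        """Observed vs calibrated LAI over the season."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trajectory.dates, self.trajectory.lai, label="simulated")
        ax.plot(self.model.obs.dates, self.model.obs.lai_obs, "o", label="observed")
        ax.set_xlabel("date")
        ax.set_ylabel("LAI (m$^2$ m$^{-2}$)")
        ax.legend()
        return ax


def powell_calibrate(
    obs: ObservationSet,
    weather: pd.DataFrame,
    season: SeasonConfig,
    init: CropParameters | None = None,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    **fit_kwargs,
) -> CalibrationResult:
    """Functional front door for :meth:`LAIAssimilation.fit`."""
    return LAIAssimilation(obs, weather, season, bounds).fit(start=init, **fit_kwargs)


def run_hybrid(
    weather: pd.DataFrame,
    fit: FitResult,
    season: SeasonConfig,
    init: CropParameters | None = None,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    *,
    composite_dates=None,
    pixel_id: str = "px",
    **fit_kwargs,
) -> CalibrationResult:
    """The hybrid regime: regressor-estimated LAI assimilated into the crop model.

    Builds cumulative climate features at the composite dates (every 8th
    day from transplanting unless ``composite_dates`` is given), predicts
    LAI with the trained regressor, and calibrates the crop model to those
    estimates by Powell's method.
    """
    if composite_dates is None:
        composite_dates = season.dates[8::8]
    composite_dates = pd.DatetimeIndex(pd.to_datetime(composite_dates))
    if len(composite_dates) < 4:
        raise InsufficientDataError(
            f"hybrid calibration needs >= 4 composite dates, have {len(composite_dates)}"
        )
    obs_frame = pd.DataFrame({"pixel_id": pixel_id, "date": composite_dates})
    features = build_features({pixel_id: weather}, obs_frame, season)
    pred = predict_lai(fit, features)
    source = "dnn_estimated" if fit.spec.family == "dnn" else "ml_estimated"
    obs = ObservationSet(
        dates=pd.DatetimeIndex(features["date"]), lai_obs=pred, source=source
    )
    return powell_calibrate(obs, weather, season, init, bounds, **fit_kwargs)


def cross_region_evaluate(
    models: dict[str, FitResult],
    datasets: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Score every trained region model on every region's labelled features.

    ``datasets`` maps region name to a feature table with target column
    ``lai`` and metadata column ``year``.  Each (model region -> data
    region, year) pair is scored with RMSE and normalized ME; missing
    region data produces a warning and a partial table.
    """
    if len(models) < 1 or len(datasets) < 1:
        raise InvalidInputError("need at least one model and one dataset")
    rows = []
    for model_region in sorted(models):
        fit = models[model_region]
        for data_region in sorted(datasets):
            table = datasets[data_region]
            if table is None or len(table) == 0:
                logger.warning("no data for region %s; skipping", data_region)
                continue
            years = sorted(table["year"].unique()) if "year" in table.columns else [None]
            for year in years:
                sub = table if year is None else table[table["year"] == year]
                pred = predict_lai(fit, sub)
                obs = sub["lai"].to_numpy(dtype=float)
                rows.append(
                    {
                        "model_region": model_region,
                        "region": data_region,
                        "year": year,
                        "source": (
                            "dnn_estimated" if fit.spec.family == "dnn" else "ml_estimated"
                        ),
                        "n": len(sub),
                        "rmse": metrics.rmse(obs, pred),
                        "me": metrics.normalized_me(metrics.nse(obs, pred)),
                    }
                )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["region", "year", "model_region"]).reset_index(drop=True)
    return out
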