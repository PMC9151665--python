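"""Process-based daily LAI growth simulator for paddy rice.

The canopy model is a remote-sensing-integrated crop model in the GRAMI
tradition: a small number of parameters re-fitted each season to remotely
sensed canopy observations.  Leaf area index L (m^2 m^-2) evolves on a
thermal-time clock.  Daily thermal time is

    dGDD_t = max(0, (tmax_t + tmin_t)/2 - t_base)            [degC day]

and while the cumulative GDD since transplanting is at or below a
senescence-onset threshold the canopy grows logistically, modulated by
incoming solar radiation:

    dL_t = a * dGDD_t * rho_t * L_t * (1 - L_t / b),
    rho_t = min(1, srad_t / r_ref),

after which it senesces exponentially in thermal time:

    dL_t = -c * dGDD_t * L_t.

Four parameters are calibrated within each season:

    L0  initial LAI at transplanting            (m^2 m^-2)
    a   relative leaf growth rate               (per degC day)
    b   asymptotic maximum LAI                  (m^2 m^-2)
    c   relative senescence rate                (per degC day)

The remaining constants (t_base, r_ref, the senescence GDD threshold and
the season length) are fixed season configuration, not calibrated.
Integration is daily explicit Euler, matching the daily weather inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "CropParameters",
    "ParameterBounds",
    "DEFAULT_BOUNDS",
    "SeasonConfig",
    "LAITrajectory",
    "thermal_time",
    "simulate_lai",
    "lai_at_dates",
    "validate_weather",
]


@dataclass(frozen=True)
class CropParameters:
    """The four within-season calibratable growth parameters."""

    l0: float  # initial LAI at transplanting, m^2 m^-2
    a: float   # relative leaf growth rate, per degC day
    b: float   # asymptotic maximum LAI, m^2 m^-2
    c: float   # relative senescence rate, per degC day

    def __post_init__(self):
        # l0 and b are canopy states and must be strictly positive; the rates
        # a and c may be zero (no growth / no senescence are meaningful limits)
        for name, strict in (("l0", True), ("a", False), ("b", True), ("c", False)):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0 or (strict and v == 0):
                raise InvalidInputError(f"parameter {name} must be positive, got {v}")
        if self.l0 > self.b:
            raise InvalidInputError(f"l0={self.l0} exceeds asymptotic maximum b={self.b}")

    def as_array(self) -> np.ndarray:
        return np.array([self.l0, self.a, self.b, self.c], dtype=float)

    @classmethod
    def from_array(cls, x) -> "CropParameters":
        l0, a, b, c = (float(v) for v in x)
        return cls(l0=l0, a=a, b=b, c=c)

    names = ("l0", "a", "b", "c")


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds for the four parameters, as (low, high) pairs."""

    l0: tuple[float, float] = (0.01, 0.5)
    a: tuple[float, float] = (1e-4, 5e-2)
    b: tuple[float, float] = (2.0, 8.0)
    c: tuple[float, float] = (1e-5, 1e-2)

    def __post_init__(self):
        for name in CropParameters.names:
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise InvalidInputError(f"invalid bound for {name}: ({lo}, {hi})")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([getattr(self, n)[0] for n in CropParameters.names])
        hi = np.array([getattr(self, n)[1] for n in CropParameters.names])
        return lo, hi

    def midpoint(self) -> CropParameters:
        lo, hi = self.as_arrays()
        return CropParameters.from_array((lo + hi) / 2.0)

    def contains(self, params: CropParameters, rtol: float = 1e-9) -> bool:
        lo, hi = self.as_arrays()
        x = params.as_array()
        return bool(np.all(x >= lo * (1 - rtol)) and np.all(x <= hi * (1 + rtol)))


DEFAULT_BOUNDS = ParameterBounds()


@dataclass(frozen=True)
class SeasonConfig:
    """Fixed (non-calibrated) constants describing one rice season.

    Rice in the central Korean peninsula is transplanted in mid/late May
    (day of year ~135-140); defaults reflect a typical paddy season.
    """

    transplant_date: _date
    t_base: float = 10.0            # degC, base temperature for GDD
    gdd_senescence: float = 1200.0  # degC day, growth -> senescence switch
    r_ref: float = 20.0             # MJ m^-2 d^-1, reference insolation
    season_length: int = 128        # days simulated from transplanting

    def __post_init__(self):
        if self.t_base >= 45:
            raise InvalidInputError(f"t_base must be < 45 degC, got {self.t_base}")
        if self.gdd_senescence <= 0:
            raise InvalidInputError("gdd_senescence must be positive")
        if not (60 <= self.season_length <= 200):
            raise InvalidInputError(
                f"season_length must lie in [60, 200] days, got {self.season_length}"
            )

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.transplant_date, periods=self.season_length, freq="D")


def validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Check the daily-weather contract and return a normalized copy.

    Expects columns date, tmax, tmin, srad; dates strictly increasing with a
    one-day step, tmax >= tmin, srad >= 0.
    """
    required = ["date", "tmax", "tmin", "srad"]
    missing = [c for c in required if c not in weather.columns]
    if missing:
        raise InvalidInputError(f"weather table missing columns: {missing}")
    if len(weather) == 0:
        raise InvalidInputError("weather table is empty")
    out = weather.loc[:, required].copy()
    out["date"] = pd.to_datetime(out["date"])
    steps = out["date"].diff().dropna()
    if len(steps) and not (steps == pd.Timedelta(days=1)).all():
        raise InvalidInputError("weather dates must be strictly increasing with a daily step")
    for col in ("tmax", "tmin", "srad"):
        if not np.isfinite(out[col].to_numpy()).all():
            raise InvalidInputError(f"non-finite value in weather column {col!r}")
    if (out["tmax"] < out["tmin"]).any():
        raise InvalidInputError("tmax < tmin in weather table")
    if (out["srad"] < 0).any():
        raise InvalidInputError("negative solar radiation in weather table")
    return out.reset_index(drop=True)


def thermal_time(weather: pd.DataFrame, t_base: float = 10.0) -> np.ndarray:
    """Daily growing-degree-day increments, max(0, (tmax+tmin)/2 - t_base)."""
    w = validate_weather(weather)
    tmean = (w["tmax"].to_numpy() + w["tmin"].to_numpy()) / 2.0
    return np.maximum(0.0, tmean - t_base)


@dataclass(frozen=True)
class LAITrajectory:
    """A simulated daily LAI trajectory with its thermal-time clock."""

    dates: pd.DatetimeIndex
    lai: np.ndarray   # m^2 m^-2, one value per day
    gdd: np.ndarray   # cumulative degC day, same length

    def __post_init__(self):
        if not (len(self.dates) == len(self.lai) == len(self.gdd)):
            raise InvalidInputError("trajectory fields must have equal length")
        if (np.asarray(self.lai) < 0).any():
            raise InvalidInputError("negative LAI in trajectory")

    def at(self, dates) -> np.ndarray:
        """Exact daily lookup of LAI at the requested dates (no interpolation)."""
        return lai_at_dates(self, dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "lai": self.lai, "gdd": self.gdd})

    @property
    def peak(self) -> float:
        return float(np.max(self.lai))


def _simulate_core(
    params: CropParameters,
    dgdd: np.ndarray,
    rho: np.ndarray,
    gdd_senescence: float,
    lai0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-step the growth/senescence recurrence. Returns (lai, cum_gdd)."""
    n = len(dgdd)
    lai = np.empty(n)
    gdd = np.cumsum(dgdd)
    lai[0] = params.l0 if lai0 is None else lai0
    a, b, c = params.a, params.b, params.c
    for t in range(1, n):
        l_prev = lai[t - 1]
        if gdd[t] <= gdd_senescence:
            dl = a * dgdd[t] * rho[t] * l_prev * (1.0 - l_prev / b)
        else:
            dl = -c * dgdd[t] * l_prev
        lai[t] = max(0.0, l_prev + dl)
    return lai, gdd


def simulate_lai(
    params: CropParameters,
    weather: pd.DataFrame,
    season: SeasonConfig,
    *,
    initial_lai: float | None = None,
) -> LAITrajectory:
    """Simulate the daily LAI trajectory over one season.

    The weather table must cover every day from the transplant date through
    the end of the season.  Day 0 carries the initial LAI (L0 unless
    ``initial_lai`` resumes a saved state); each subsequent day applies that
    day's thermal time and radiation.
    """
    w = validate_weather(weather)
    dates = season.dates
    w = w.set_index("date")
    missing = dates.difference(w.index)
    if len(missing):
        raise InvalidInputError(
            f"weather does not cover the season: first missing day {missing[0].date()}"
        )
    w = w.loc[dates]
    tmean = (w["tmax"].to_numpy() + w["tmin"].to_numpy()) / 2.0
    dgdd = np.maximum(0.0, tmean - season.t_base)
    rho = np.minimum(1.0, w["srad"].to_numpy() / season.r_ref)
    lai, gdd = _simulate_core(params, dgdd, rho, season.gdd_senescence, lai0=initial_lai)
    return LAITrajectory(dates=dates, lai=lai, gdd=gdd)


def lai_at_dates(traj: LAITrajectory, dates) -> np.ndarray:
    """LAI values at the requested dates by exact daily lookup."""
    req = pd.DatetimeIndex(pd.to_datetime(dates))
    ser = pd.Series(traj.lai, index=traj.dates)
    missing = req.difference(ser.index)
    if len(missing):
        raise InvalidInputError(f"date outside simulated span: {missing[0].date()}")
    return ser.loc[req].to_numpy()


def resume(
    params: CropParameters,
    traj: LAITrajectory,
    weather: pd.DataFrame,
    season: SeasonConfig,
) -> LAITrajectory:
    """Extend a partial trajectory to the full season (restart equivalence).

    Re-simulates from the last saved day using its LAI as the initial state;
    the result over the overlap is identical to an uninterrupted run because
    the recurrence depends only on the current state and the day's weather.
    """
    done = len(traj.lai)
    w = validate_weather(weather).set_index("date")
    dates = season.dates
    missing = dates.difference(w.index)
    if len(missing):
        raise InvalidInputError(
            f"weather does not cover the season: first missing day {missing[0].date()}"
        )
    w = w.loc[dates]
    tmean = (w["tmax"].to_numpy() + w["tmin"].to_numpy()) / 2.0
    dgdd = np.maximum(0.0, tmean - season.t_base)
    rho = np.minimum(1.0, w["srad"].to_numpy() / season.r_ref)
    gdd = np.cumsum(dgdd)
    # resume from the saved state; the senescence switch still reads the
    # season-cumulative GDD, so shift the tail's threshold accordingly
    tail_dgdd = np.concatenate([[0.0], dgdd[done:]])
    tail_rho = np.concatenate([[1.0], rho[done:]])
    offset = gdd[done - 1]
    tail_lai, _ = _simulate_core(
        params, tail_dgdd, tail_rho, season.gdd_senescence - offset,
        lai0=float(traj.lai[-1]),
    )
    lai = np.concatenate([traj.lai, tail_lai[1:]])
    return LAITrajectory(dates=dates, lai=lai, gdd=gdd)
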