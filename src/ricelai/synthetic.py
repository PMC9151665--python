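"""Synthetic multi-pixel rice-season datasets for end-to-end testing.

The generator emulates the statistical structure of the pipeline's real
inputs without any downloads:

* daily weather per pixel-season — sinusoidal temperature climatology with
  AR(1) noise (RDAPS-style model temperatures) and insolation that dips on
  cloudy days (COMS-style satellite insolation);
* a two-state clear/cloudy Markov chain on days, so cloudy spells cluster
  the way monsoon cloud cover does; an 8-day composite is flagged poor
  quality when more than half of its days are cloudy (MOD09A1-style QA
  gaps);
* true LAI trajectories simulated by the process model from per-pixel
  parameter draws, converted to NDVI through the inverse of the empirical
  NDVI-LAI relation, with additive observation noise.

Everything is driven by one seeded generator, so a dataset is reproducible
byte-for-byte from its configuration.

The region presets named after Korean rice-growing districts are synthetic
climatologies shaped to exercise cross-region transfer (warmer south,
cooler north); they are fixtures, not measured descriptions of the places.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as _date

import numpy as np
import pandas as pd

from .crop_model import (
    CropParameters,
    LAITrajectory,
    SeasonConfig,
    lai_at_dates,
    simulate_lai,
)
from .exceptions import ConfigError
from .preprocessing import (
    DEFAULT_NDVI_LAI,
    CompositeSeries,
    NdviLaiCoefficients,
    lai_to_ndvi,
)

__all__ = [
    "RegionGeneratorConfig",
    "PixelSeason",
    "SyntheticRegionDataset",
    "REGION_PRESETS",
    "gen_weather",
    "gen_region",
    "dataset_to_feature_table",
    "gen_benchmark_table",
]


@dataclass(frozen=True)
class RegionGeneratorConfig:
    """Everything needed to generate one synthetic region."""

    name: str = "region"
    n_pixels: int = 93
    years: tuple[int, ...] = (2011, 2012, 2013, 2014, 2015, 2016, 2017)
    transplant_doy: tuple[int, int] = (135, 140)   # mid/late May window
    # temperature climatology: Tmean(doy) = mean + amplitude*sin(2pi(doy-phase)/365)
    temp_mean: float = 12.0          # degC annual mean
    temp_amplitude: float = 13.0     # degC seasonal amplitude
    temp_phase_doy: float = 110.0    # day of year where the sinusoid crosses its mean
    diurnal_range: float = 9.0       # degC tmax - tmin
    rad_clear: float = 22.0          # MJ m^-2 d^-1 clear-sky insolation
    rad_cloud_factor: float = 0.35   # cloudy-day insolation fraction
    ar1_rho: float = 0.7             # day-to-day temperature noise persistence
    ar1_sigma: float = 1.5           # degC innovation s.d.
    # true-parameter draws: uniform on these intervals
    l0_range: tuple[float, float] = (0.05, 0.25)
    a_range: tuple[float, float] = (0.006, 0.016)
    b_range: tuple[float, float] = (2.6, 4.2)
    c_range: tuple[float, float] = (8e-4, 4e-3)
    obs_noise_sigma: float = 0.1     # m^2 m^-2 additive LAI observation noise
    # clear/cloudy Markov chain (monsoon clustering)
    p_clear_to_cloud: float = 0.15
    p_cloud_stay: float = 0.6
    # if set, overrides the Markov QA rule with iid composite-level gaps
    gap_probability: float | None = None
    season: SeasonConfig = field(
        default_factory=lambda: SeasonConfig(transplant_date=_date(2014, 5, 17))
    )
    ndvi_lai: NdviLaiCoefficients = DEFAULT_NDVI_LAI
    seed: int = 0

    def __post_init__(self):
        if self.n_pixels < 1:
            raise ConfigError("n_pixels must be >= 1")
        probs = [self.p_clear_to_cloud, self.p_cloud_stay]
        if self.gap_probability is not None:
            probs.append(self.gap_probability)
        for p in probs:
            if not 0 <= p <= 1:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.seed is None:
            raise ConfigError("seed is mandatory for reproducibility")


# Synthetic climatology presets loosely shaped like the four study districts:
# two central-peninsula regions, one warmer southern, one cooler northern.
REGION_PRESETS: dict[str, RegionGeneratorConfig] = {
    "cheorwon": RegionGeneratorConfig(name="cheorwon", n_pixels=93, temp_mean=11.0),
    "paju": RegionGeneratorConfig(name="paju", n_pixels=59, temp_mean=12.0, seed=1),
    "gimje": RegionGeneratorConfig(name="gimje", n_pixels=60, temp_mean=14.5, seed=2),
    "pyeongyang": RegionGeneratorConfig(
        name="pyeongyang", n_pixels=60, temp_mean=10.0, temp_amplitude=14.5, seed=3
    ),
}


@dataclass(frozen=True)
class PixelSeason:
    """One pixel-season: weather, truth, and the degraded observations."""

    pixel_id: str
    year: int
    weather: pd.DataFrame
    true_params: CropParameters
    true_lai: LAITrajectory
    composites: CompositeSeries   # noisy NDVI with QA gaps
    season: SeasonConfig


@dataclass(frozen=True)
class SyntheticRegionDataset:
    """All pixel-seasons of one synthetic region plus its configuration."""

    config: RegionGeneratorConfig
    pixel_seasons: tuple[PixelSeason, ...]

    def __len__(self):
        return len(self.pixel_seasons)


def _cloud_chain(rng: np.random.Generator, n: int, cfg: RegionGeneratorConfig) -> np.ndarray:
    """Two-state clear(0)/cloudy(1) Markov chain over days."""
    state = np.empty(n, dtype=bool)
    state[0] = rng.random() < cfg.p_clear_to_cloud
    u = rng.random(n)
    for t in range(1, n):
        p = cfg.p_cloud_stay if state[t - 1] else cfg.p_clear_to_cloud
        state[t] = u[t] < p
    return state


def _weather_from_rng(
    cfg: RegionGeneratorConfig, year: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Daily weather for one pixel-season plus the cloudy-day indicator."""
    transplant_doy = int(rng.integers(cfg.transplant_doy[0], cfg.transplant_doy[1] + 1))
    start = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=transplant_doy - 1)
    n = cfg.season.season_length + 8  # cover the season with margin
    dates = pd.date_range(start, periods=n, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    clim = cfg.temp_mean + cfg.temp_amplitude * np.sin(
        2 * np.pi * (doy - cfg.temp_phase_doy) / 365.0
    )
    noise = np.empty(n)
    innov = rng.normal(0.0, cfg.ar1_sigma, size=n)
    noise[0] = innov[0]
    for t in range(1, n):
        noise[t] = cfg.ar1_rho * noise[t - 1] + innov[t]
    tmean = clim + noise
    tmax = tmean + cfg.diurnal_range / 2.0
    tmin = tmean - cfg.diurnal_range / 2.0
    cloudy = _cloud_chain(rng, n, cfg)
    srad = np.where(cloudy, cfg.rad_clear * cfg.rad_cloud_factor, cfg.rad_clear)
    srad = np.maximum(0.0, srad + rng.normal(0.0, 0.5, size=n))
    weather = pd.DataFrame({"date": dates, "tmax": tmax, "tmin": tmin, "srad": srad})
    return weather, cloudy


def gen_weather(config: RegionGeneratorConfig, pixel: int, year: int) -> pd.DataFrame:
    """Daily weather for one pixel-season (independently reproducible)."""
    rng = np.random.default_rng([config.seed, pixel, year])
    weather, _ = _weather_from_rng(config, year, rng)
    return weather


def _draw_params(cfg: RegionGeneratorConfig, rng: np.random.Generator) -> tuple[CropParameters, int]:
    """Draw true parameters; redraw (counted) on an infeasible l0 > b."""
    redraws = 0
    while True:
        l0 = rng.uniform(*cfg.l0_range)
        a = rng.uniform(*cfg.a_range)
        b = rng.uniform(*cfg.b_range)
        c = rng.uniform(*cfg.c_range)
        if l0 <= b:
            return CropParameters(l0=l0, a=a, b=b, c=c), redraws
        redraws += 1


def gen_region(config: RegionGeneratorConfig) -> SyntheticRegionDataset:
    """Generate every pixel-season of one region.

    For each pixel-season: draw true parameters, simulate the true LAI,
    convert to NDVI via the inverse empirical relation, add observation
    noise, and apply clustered QA gaps on 8-day composites.
    """
    pixel_seasons = []
    for pixel in range(config.n_pixels):
        for year in config.years:
            rng = np.random.default_rng([config.seed, pixel, year])
            weather, cloudy = _weather_from_rng(config, year, rng)
            params, _ = _draw_params(config, rng)
            season = replace(config.season, transplant_date=weather["date"].iloc[0].date())
            traj = simulate_lai(params, weather, season)
            comp_dates = season.dates[8::8]
            true_lai = lai_at_dates(traj, comp_dates)
            # clamp to the invertible range of the NDVI relation
            lo = config.ndvi_lai.alpha * np.exp(-config.ndvi_lai.beta)
            ndvi_true = lai_to_ndvi(np.maximum(true_lai, lo), config.ndvi_lai)
            noisy_lai = np.maximum(
                true_lai + rng.normal(0.0, config.obs_noise_sigma, size=len(true_lai)), lo
            )
            ndvi = lai_to_ndvi(noisy_lai, config.ndvi_lai) if config.obs_noise_sigma > 0 else ndvi_true
            if config.gap_probability is not None:
                qa_good = rng.random(len(comp_dates)) >= config.gap_probability
            else:
                # a composite is poor quality if >half of its 8 days were cloudy
                day_offsets = (comp_dates - season.dates[0]).days.to_numpy()
                qa_good = np.array(
                    [cloudy[max(0, off - 7): off + 1].sum() <= 4 for off in day_offsets]
                )
            composites = CompositeSeries(dates=comp_dates, ndvi=ndvi, qa_good=qa_good)
            pixel_seasons.append(
                PixelSeason(
                    pixel_id=f"{config.name}_{pixel:04d}",
                    year=year,
                    weather=weather,
                    true_params=params,
                    true_lai=traj,
                    composites=composites,
                    season=season,
                )
            )
    return SyntheticRegionDataset(config=config, pixel_seasons=tuple(pixel_seasons))


def dataset_to_feature_table(
    dataset: SyntheticRegionDataset,
    *,
    fill_gaps: bool = True,
    use_true_lai: bool = False,
) -> pd.DataFrame:
    """Flatten a region into the regressor-ready feature table.

    Targets come from the (gap-filled) NDVI composites through the
    empirical relation, or from the noise-free truth when
    ``use_true_lai`` is set (closed-loop experiments).
    """
    from .ml import build_features
    from .preprocessing import ndvi_to_lai, spline_fill

    frames = []
    for ps in dataset.pixel_seasons:
        comp = ps.composites
        if fill_gaps and not comp.qa_good.all():
            comp = spline_fill(comp)
        if use_true_lai:
            lai = lai_at_dates(ps.true_lai, comp.dates)
        else:
            lai = ndvi_to_lai(np.clip(comp.ndvi, -1.0, 1.0), dataset.config.ndvi_lai)
        obs = pd.DataFrame(
            {
                "pixel_id": f"{ps.pixel_id}_{ps.year}",
                "region": dataset.config.name,
                "year": ps.year,
                "date": comp.dates,
                "lai": lai,
            }
        )
        feats = build_features({f"{ps.pixel_id}_{ps.year}": ps.weather}, obs, ps.season)
        frames.append(feats)
    return pd.concat(frames, ignore_index=True)


def gen_benchmark_table(
    n: int = 8000, seed: int = 42, noise_frac: float = 0.1
) -> pd.DataFrame:
    """Regressor benchmark: a deterministic nonlinear LAI target plus noise.

    Each row emulates one pixel-composite sample: a day-since-transplanting
    and per-day accumulation rates give correlated cumulative climate
    features, and the target is a canopy curve (logistic rise, exponential
    senescence) evaluated on the implied thermal time — a smooth but
    strongly nonlinear, non-monotone function of the three features.
    Gaussian noise with standard deviation ``noise_frac`` times the target
    spread is added, so no family can reach R^2 = 1 on held-out rows.
    """
    rng = np.random.default_rng(seed)
    d = rng.uniform(8, 128, n)                 # days since transplanting
    srad_rate = rng.uniform(14, 22, n)         # MJ m^-2 d^-1
    tmax_rate = rng.uniform(24, 32, n)         # degC
    tmin_rate = rng.uniform(15, 23, n)         # degC
    gdd = d * ((tmax_rate + tmin_rate) / 2.0 - 10.0)
    rho = np.minimum(1.0, srad_rate / 20.0)
    l0, a, b, c = 0.12, 0.012, 3.5, 2e-3
    ratio = (b - l0) / l0
    grow = b / (1.0 + ratio * np.exp(-a * rho * gdd))
    peak = b / (1.0 + ratio * np.exp(-a * rho * 1200.0))
    target = np.where(gdd <= 1200.0, grow, peak * np.exp(-c * (gdd - 1200.0)))
    target = np.maximum(0.0, target + rng.normal(0.0, noise_frac * target.std(), n))
    return pd.DataFrame(
        {
            "cum_srad": d * srad_rate,
            "cum_tmax": d * tmax_rate,
            "cum_tmin": d * tmin_rate,
            "lai": target,
        }
    )
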