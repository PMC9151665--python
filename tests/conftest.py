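"""Shared fixtures: small deterministic weather series and synthetic regions."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from ricelai import CropParameters, RegionGeneratorConfig, SeasonConfig, gen_region


@pytest.fixture
def season():
    return SeasonConfig(transplant_date=date(2014, 5, 17))


@pytest.fixture
def constant_weather(season):
    """140 days of constant warm weather: tmax 30, tmin 20, srad 22 (rho=1)."""
    return pd.DataFrame(
        {
            "date": pd.date_range(season.transplant_date, periods=140, freq="D"),
            "tmax": 30.0,
            "tmin": 20.0,
            "srad": 22.0,
        }
    )


@pytest.fixture
def params():
    return CropParameters(l0=0.1, a=0.01, b=3.5, c=2e-3)


@pytest.fixture(scope="session")
def small_region():
    """A 4-pixel single-year synthetic region shared across tests."""
    return gen_region(RegionGeneratorConfig(n_pixels=4, years=(2014,), seed=7))


@pytest.fixture(scope="session")
def clean_region():
    """Noise-free, gap-free region for closed-loop checks."""
    return gen_region(
        RegionGeneratorConfig(
            n_pixels=6,
            years=(2014,),
            seed=9,
            obs_noise_sigma=0.0,
            p_clear_to_cloud=0.0,
            p_cloud_stay=0.0,
        )
    )
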