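"""Seeded synthetic daily weather.

Generates the climate inputs a crop-water model consumes — daily minimum
and maximum air temperature, reference evapotranspiration (ETo) and
rainfall — as a multi-decade series with a sinusoidal seasonal cycle, a
linear warming trend and seeded Gaussian noise. Years are idealized
365-day years (no leap days) so trend arithmetic is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._calendar import DAYS_PER_YEAR, doy_to_month_day
from ..errors import ValidationError

#: Day-of-year of the seasonal temperature peak (mid-July in the
#: northern hemisphere).
PEAK_DOY = 196

#: Relative amplitude of the ETo seasonal cycle and its floor (mm/day).
ETO_SEASONALITY = 0.6
ETO_FLOOR = 0.1

#: Wet-day probability for the rainfall occurrence process.
WET_DAY_PROB = 0.35


@dataclass(frozen=True)
class WeatherParams:
    """Parameters of the synthetic weather process.

    base_tmin / base_tmax are annual-mean daily extremes (degC);
    seasonal_amplitude (degC) is added to both with a cosine peaking at
    mid-July; warming_trend is degC per decade applied linearly in time;
    eto_base is the annual-mean reference evapotranspiration (mm/day);
    rain_mean is mean rainfall per day (mm) across wet and dry days.
    """

    start_year: int = 2010
    n_years: int = 90
    base_tmin: float = 4.0
    base_tmax: float = 16.0
    seasonal_amplitude: float = 12.0
    warming_trend: float = 0.1
    eto_base: float = 3.0
    rain_mean: float = 1.5
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 1:
            raise ValidationError(f"n_years must be >= 1, got {self.n_years}")
        if not self.base_tmax > self.base_tmin:
            raise ValidationError(
                f"base_tmax ({self.base_tmax}) must exceed base_tmin ({self.base_tmin})")
        if not self.eto_base > 0:
            raise ValidationError(f"eto_base must be > 0, got {self.eto_base}")
        if self.rain_mean < 0:
            raise ValidationError(f"rain_mean must be >= 0, got {self.rain_mean}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def replace(self, **kwargs) -> "WeatherParams":
        from dataclasses import replace
        return replace(self, **kwargs)


def generate_weather(params: WeatherParams) -> pd.DataFrame:
    """Generate a daily weather series.

    Returns a DataFrame with one row per day and columns
    ``year, doy, month, day, tmin, tmax, eto, rain``; length is
    ``n_years * 365``. Deterministic for a fixed seed. The same noise
    draw is added to tmin and tmax, so the diurnal gap is preserved and
    ``tmax >= tmin`` holds on every day.
    """
    n_days = params.n_years * DAYS_PER_YEAR
    t = np.arange(n_days)
    year = params.start_year + t // DAYS_PER_YEAR
    doy = t % DAYS_PER_YEAR + 1
    month, day = doy_to_month_day(doy)

    season = np.cos(2 * np.pi * (doy - PEAK_DOY) / DAYS_PER_YEAR)
    trend = params.warming_trend / 10.0 * (t / DAYS_PER_YEAR)

    rng = np.random.default_rng(params.seed)
    noise = rng.normal(0.0, params.noise_sd, n_days) if params.noise_sd > 0 else 0.0

    tmin = params.base_tmin + params.seasonal_amplitude * season + trend + noise
    tmax = params.base_tmax + params.seasonal_amplitude * season + trend + noise

    eto = np.maximum(ETO_FLOOR, params.eto_base * (1.0 + ETO_SEASONALITY * season))

    if params.rain_mean > 0:
        wet = rng.random(n_days) < WET_DAY_PROB
        amounts = rng.exponential(params.rain_mean / WET_DAY_PROB, n_days)
        rain = np.where(wet, amounts, 0.0)
    else:
        rain = np.zeros(n_days)

    return pd.DataFrame({
        "year": year.astype(int), "doy": doy.astype(int),
        "month": month.astype(int), "day": day.astype(int),
        "tmin": tmin, "tmax": tmax, "eto": eto, "rain": rain,
    })
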