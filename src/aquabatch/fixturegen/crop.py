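"""Toy crop-water season simulator.

A deliberately simple daily model with the structure of a crop-water
productivity simulation: thermal time (growing degree days, GDD) drives
the cycle length, canopy cover (CC) ramps linearly to a plateau, crop
transpiration is ``Tr = Ks * Kc * CC * ETo`` with a binary temperature
stress coefficient Ks, biomass follows the water-driven production
relation ``B = sum(Tr) * WP*`` and yield is ``Y = HI * B``. A closed
daily root-zone water balance (rain = E + Tr + runoff + drainage +
change in storage, exactly) provides the soil-water bookkeeping. The
model is a fixture: it has the statistical shape of real simulations
(warming shortens cycles, heat stress days, plausible magnitudes), not
their physics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._calendar import DAYS_PER_YEAR, doy_to_month_day
from ..errors import ValidationError

#: Root-zone storage capacity and initial fill (mm), and the maximum
#: daily infiltration before surface runoff is generated (mm/day).
STORAGE_CAPACITY = 150.0
STORAGE_INITIAL = 75.0
INFILTRATION_MAX = 40.0

#: Reference CO2 concentration written to seasonal summaries (ppm).
CO2_REFERENCE = 369.41


@dataclass(frozen=True)
class ToyCropParams:
    """Crop parameters of the toy simulator.

    sowing_doy is the sowing day-of-year in the 365-day calendar;
    t_base (degC) is the GDD base temperature; gdd_maturity (degC day)
    ends the season once accumulated; kc scales ETo to potential
    transpiration; cc_max and cc_ramp_days shape the linear canopy ramp;
    wp_star is the water productivity coefficient in t/ha per mm of
    transpired water; hi is the harvest index; [t_opt_low, t_opt_high]
    is the optimal daily-mean temperature range outside of which
    stomatal (temperature) stress sets Ks to zero.
    """

    name: str = "Maize"
    sowing_doy: int = 131  # 11 May
    t_base: float = 10.0
    gdd_maturity: float = 1150.0
    max_cycle_days: int = 180
    kc: float = 1.05
    cc_max: float = 0.9
    cc_ramp_days: int = 40
    wp_star: float = 0.04
    hi: float = 0.48
    t_opt_low: float = 9.0
    t_opt_high: float = 30.0

    def __post_init__(self):
        if not 0 < self.hi <= 1:
            raise ValidationError(f"hi must be in (0, 1], got {self.hi}")
        if not 0 < self.cc_max <= 1:
            raise ValidationError(f"cc_max must be in (0, 1], got {self.cc_max}")
        if not self.wp_star > 0:
            raise ValidationError(f"wp_star must be > 0, got {self.wp_star}")
        if not self.t_opt_low < self.t_opt_high:
            raise ValidationError(
                f"t_opt_low ({self.t_opt_low}) must be below t_opt_high ({self.t_opt_high})")
        if not self.gdd_maturity > 0:
            raise ValidationError(f"gdd_maturity must be > 0, got {self.gdd_maturity}")
        if not 1 <= self.sowing_doy <= DAYS_PER_YEAR:
            raise ValidationError(f"sowing_doy must be in 1..365, got {self.sowing_doy}")
        if self.max_cycle_days < 1:
            raise ValidationError(f"max_cycle_days must be >= 1, got {self.max_cycle_days}")
        if self.cc_ramp_days < 1:
            raise ValidationError(f"cc_ramp_days must be >= 1, got {self.cc_ramp_days}")

    def replace(self, **kwargs) -> "ToyCropParams":
        from dataclasses import replace
        return replace(self, **kwargs)


@dataclass
class SimulatedSeason:
    """One simulated growing season: daily trace plus seasonal summary."""

    season_year: int
    cycle_length: int
    sowing_doy: int
    harvest_doy: int
    sum_tr: float          # mm transpired over the season
    sum_trx: float         # mm potential (unstressed) transpiration
    sum_evap: float        # mm soil evaporation
    sum_ex: float          # mm potential soil evaporation
    sum_et: float          # mm evapotranspiration (E + Tr)
    biomass: float         # t/ha, = wp_star * sum_tr
    yield_: float          # t/ha, = hi * biomass
    wp_et: float           # kg yield per m3 of evapotranspired water
    stress_pct: float      # % of cycle days with temperature stress
    gdd_total: float       # degC day accumulated over the cycle
    crop: ToyCropParams
    daily: pd.DataFrame    # per-day trace


def simulate_season(weather: pd.DataFrame, crop: ToyCropParams, year: int) -> SimulatedSeason:
    """Simulate one growing season of ``year`` from a weather series.

    The daily loop accumulates GDD with the average method
    (``max(0, (tmax+tmin)/2 - t_base)``); the season ends on the first
    day accumulated GDD reaches ``gdd_maturity``, or after
    ``max_cycle_days`` days. Transpiration and evaporation demand may be
    reduced when the root zone and the day's infiltration cannot supply
    it; the water balance closes exactly every day.
    """
    start_year = int(weather["year"].iloc[0])
    sow_index = (year - start_year) * DAYS_PER_YEAR + crop.sowing_doy - 1
    if sow_index < 0:
        raise ValidationError(f"weather series starts after sowing of year {year}")
    if sow_index + crop.max_cycle_days > len(weather):
        raise ValidationError(
            f"weather window shorter than max_cycle_days ({crop.max_cycle_days}) "
            f"for season {year}")

    win = weather.iloc[sow_index: sow_index + crop.max_cycle_days]
    tmin = win["tmin"].to_numpy()
    tmax = win["tmax"].to_numpy()
    eto = win["eto"].to_numpy()
    rain = win["rain"].to_numpy()

    tmean = 0.5 * (tmin + tmax)
    gdd_day = np.maximum(0.0, tmean - crop.t_base)
    gdd_cum = np.cumsum(gdd_day)

    mature = np.nonzero(gdd_cum >= crop.gdd_maturity)[0]
    length = int(mature[0]) + 1 if mature.size else crop.max_cycle_days

    dap = np.arange(1, length + 1)
    cc = crop.cc_max * np.minimum(1.0, dap / crop.cc_ramp_days)
    stage = np.where(dap <= crop.cc_ramp_days, 1, 2)
    ks = np.where((tmean[:length] < crop.t_opt_low) | (tmean[:length] > crop.t_opt_high),
                  0.0, 1.0)
    trx = crop.kc * cc * eto[:length]
    tr_demand = ks * trx
    ex = 0.5 * eto[:length]
    evap_demand = (1.0 - cc) * ex

    # sequential water-balance bookkeeping (storage carries over days)
    tr = np.empty(length)
    evap = np.empty(length)
    runoff = np.empty(length)
    drainage = np.empty(length)
    storage = np.empty(length)
    s = STORAGE_INITIAL
    for i in range(length):
        ro = max(0.0, rain[i] - INFILTRATION_MAX)
        inflow = rain[i] - ro
        demand = tr_demand[i] + evap_demand[i]
        available = s + inflow
        f = 1.0 if demand <= available or demand == 0.0 else max(0.0, available / demand)
        tr[i] = tr_demand[i] * f
        evap[i] = evap_demand[i] * f
        s_new = s + inflow - tr[i] - evap[i]
        dr = max(0.0, s_new - STORAGE_CAPACITY)
        s_new -= dr
        runoff[i], drainage[i], storage[i] = ro, dr, s_new
        s = s_new

    et = evap + tr
    inet = np.maximum(0.0, et - rain[:length])
    stress = ks < 1.0

    month, day = doy_to_month_day(win["doy"].to_numpy()[:length])
    daily = pd.DataFrame({
        "year": win["year"].to_numpy()[:length], "doy": win["doy"].to_numpy()[:length],
        "month": month, "day": day, "dap": dap, "stage": stage,
        "tmin": tmin[:length], "tmax": tmax[:length], "tavg": tmean[:length],
        "eto": eto[:length], "rain": rain[:length],
        "gdd": gdd_day[:length], "gdd_cum": gdd_cum[:length],
        "cc": cc, "ks": ks, "tr": tr, "evap": evap, "et": et,
        "runoff": runoff, "drainage": drainage, "infilt": rain[:length] - runoff,
        "storage": storage, "inet": inet, "stress_day": stress.astype(float),
    })

    sum_tr = float(tr.sum())
    sum_et = float(et.sum())
    biomass = crop.wp_star * sum_tr
    yield_ = crop.hi * biomass
    # Y [t/ha] -> 0.1 kg/m2; ET [mm] -> 1e-3 m; ratio in kg/m3
    wp_et = 100.0 * yield_ / sum_et if sum_et > 0 else float("nan")
    harvest_doy = int(win["doy"].iloc[length - 1])

    return SimulatedSeason(
        season_year=year, cycle_length=length, sowing_doy=crop.sowing_doy,
        harvest_doy=harvest_doy, sum_tr=sum_tr, sum_trx=float(trx.sum()),
        sum_evap=float(evap.sum()), sum_ex=float(evap_demand.sum()),
        sum_et=sum_et, biomass=biomass, yield_=yield_, wp_et=wp_et,
        stress_pct=100.0 * float(stress.sum()) / length,
        gdd_total=float(gdd_cum[length - 1]), crop=crop, daily=daily,
    )


def simulate_run(weather: pd.DataFrame, crop: ToyCropParams) -> list[SimulatedSeason]:
    """Simulate every season whose full window fits inside ``weather``."""
    start_year = int(weather["year"].iloc[0])
    n_years = len(weather) // DAYS_PER_YEAR
    seasons = []
    for year in range(start_year, start_year + n_years):
        sow_index = (year - start_year) * DAYS_PER_YEAR + crop.sowing_doy - 1
        if sow_index + crop.max_cycle_days <= len(weather):
            seasons.append(simulate_season(weather, crop, year))
    if not seasons:
        raise ValidationError("weather series too short for any full season")
    return seasons
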