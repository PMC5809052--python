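"""Agro-meteorological branch: reference ET, Kc curves, crop ET, salinity leaching.

Implements the field-scale water arithmetic of crop water-footprint accounting:
FAO Penman-Monteith reference evapotranspiration (ETo) from daily weather
forcing, effective rainfall, staged crop-coefficient (Kc) curves, crop
evapotranspiration (ETc = Kc * ETo) and its seasonal sum (the crop water
requirement, CWR), the salinity leaching requirement from soil and
irrigation-water electrical conductivity, and gross irrigation demand.

Units follow field convention throughout: depths in mm, areas in ha,
temperatures in deg C, wind speed in m/s at 2 m, radiation in MJ/m^2/day,
electrical conductivity in dS/m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd

__all__ = [
    "MeteoRecord",
    "KcProfile",
    "FieldRecord",
    "ETSeries",
    "penman_monteith_eto",
    "effective_rainfall",
    "build_kc_curve",
    "crop_et_series",
    "leaching_fraction",
    "leaching_depth",
    "water_requirement_q",
    "gross_irrigation",
    "saturation_vapour_pressure",
    "svp_slope",
    "psychrometric_constant",
]


@dataclass(frozen=True)
class MeteoRecord:
    """One day of weather forcing.

    ``eto_mm`` may carry a pre-computed reference ET (e.g. from a weather
    station product); when present, downstream code uses it instead of
    re-deriving ETo from the radiative/aerodynamic terms, which may then
    be omitted (None).
    """

    date: Date
    tmean_c: float
    tmin_c: float | None = None
    tmax_c: float | None = None
    u2_ms: float | None = None
    rn_mj: float | None = None          # net radiation at the canopy
    g_mj: float = 0.0                   # soil heat flux (daily ~ 0)
    es_kpa: float | None = None
    ea_kpa: float | None = None
    rain_mm: float = 0.0
    eto_mm: float | None = None

    def __post_init__(self) -> None:
        if self.tmin_c is not None and self.tmax_c is not None:
            if not (self.tmin_c <= self.tmean_c <= self.tmax_c):
                raise ValueError(
                    f"{self.date}: require tmin <= tmean <= tmax, got "
                    f"{self.tmin_c}/{self.tmean_c}/{self.tmax_c}"
                )
        if self.u2_ms is not None and self.u2_ms < 0:
            raise ValueError("wind speed u2 must be >= 0")
        if self.rain_mm < 0:
            raise ValueError("rainfall must be >= 0")
        if self.es_kpa is not None and self.ea_kpa is not None and self.ea_kpa > self.es_kpa:
            raise ValueError("actual vapour pressure ea cannot exceed saturation es")


@dataclass(frozen=True)
class KcProfile:
    """Staged crop coefficients with FAO-style stage lengths (days).

    ``kc_dev`` is the single representative development-stage value used in
    look-up tables; the daily curve itself ramps linearly from ``kc_ini`` to
    ``kc_mid`` across the development stage (the ramp midpoint reproduces
    ``kc_dev`` for the standard tabulations).
    """

    crop: str
    season: str
    len_ini: int
    len_dev: int
    len_mid: int
    len_late: int
    kc_ini: float
    kc_dev: float
    kc_mid: float
    kc_late: float

    def __post_init__(self) -> None:
        for n in (self.len_ini, self.len_dev, self.len_mid, self.len_late):
            if n <= 0:
                raise ValueError("stage lengths must be positive")
        for k in (self.kc_ini, self.kc_dev, self.kc_mid, self.kc_late):
            if not (0.0 < k <= 1.5):
                raise ValueError("Kc values must lie in (0, 1.5]")

    @property
    def total_days(self) -> int:
        return self.len_ini + self.len_dev + self.len_mid + self.len_late


@dataclass
class FieldRecord:
    """Per-field agronomy: geometry, calendar, salinity, water and yield."""

    field_id: str
    crop: str
    area_ha: float
    sowing: Date
    harvest: Date
    ece_ds_m: float                     # soil saturation-extract EC (shallow sample)
    ecw_ds_m: float                     # irrigation water EC
    applied_water_mm: float | None = None
    yield_t_ha: float | None = None
    n_rate_kg_ha: float | None = None   # nitrogen application rate
    irrigation_efficiency: float = 0.70
    season: str = ""

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError("field area must be positive")
        if self.ece_ds_m <= 0 or self.ecw_ds_m < 0:
            raise ValueError("require ECe > 0 and ECw >= 0")
        if self.yield_t_ha is not None and self.yield_t_ha <= 0:
            raise ValueError("yield must be positive when given")
        if self.harvest <= self.sowing:
            raise ValueError("harvest must postdate sowing")

    @property
    def lgp_days(self) -> int:
        """Length of the growth period, sowing to harvest, in days."""
        return (self.harvest - self.sowing).days + 1


@dataclass
class ETSeries:
    """Daily ET bookkeeping over one growing season (all depths in mm/day)."""

    dates: list[Date]
    eto: np.ndarray
    kc: np.ndarray
    etc: np.ndarray
    p_eff: np.ndarray
    et_green: np.ndarray
    et_blue: np.ndarray

    @property
    def cwr_mm(self) -> float:
        """Seasonal crop water requirement: sum of daily ETc."""
        return float(self.etc.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "eto_mm": self.eto,
                "kc": self.kc,
                "etc_mm": self.etc,
                "p_eff_mm": self.p_eff,
                "et_green_mm": self.et_green,
                "et_blue_mm": self.et_blue,
            }
        )


# --- thermodynamic helpers (FAO-56 standard forms) -------------------------

def saturation_vapour_pressure(t_c: float) -> float:
    """Saturation vapour pressure e_s(T) in kPa at air temperature T (deg C)."""
    return 0.6108 * math.exp(17.27 * t_c / (t_c + 237.3))


def svp_slope(t_c: float) -> float:
    """Slope Delta of the saturation vapour-pressure curve (kPa/degC)."""
    return 4098.0 * saturation_vapour_pressure(t_c) / (t_c + 237.3) ** 2


def psychrometric_constant(elevation_m: float = 400.0) -> float:
    """Psychrometric constant gamma (kPa/degC) from station elevation.

    Atmospheric pressure follows the standard barometric profile
    P = 101.3 * ((293 - 0.0065 z)/293)^5.26; gamma = 6.65e-4 * P.
    """
    p_kpa = 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26
    return 0.000665 * p_kpa


def penman_monteith_eto(record: MeteoRecord, elevation_m: float = 400.0) -> float:
    """Daily grass-reference evapotranspiration ETo (mm/day).

    Combination equation with the daily grass-reference aerodynamic
    coefficient 900 and surface coefficient 0.34:

        ETo = [0.408 Delta (Rn - G) + gamma 900/(T+273) u2 (es - ea)]
              / [Delta + gamma (1 + 0.34 u2)]

    Negative results (strongly advective/condensing conditions) are
    clipped to zero.

    Raises
    ------
    ValueError
        If any of Rn, u2, es, ea is missing ("insufficient forcing").
    """
    missing = [
        name
        for name, v in (
            ("rn_mj", record.rn_mj),
            ("u2_ms", record.u2_ms),
            ("es_kpa", record.es_kpa),
            ("ea_kpa", record.ea_kpa),
        )
        if v is None
    ]
    if missing:
        raise ValueError(f"insufficient forcing for Penman-Monteith: missing {missing}")

    t = record.tmean_c
    delta = svp_slope(t)
    gamma = psychrometric_constant(elevation_m)
    denom = delta + gamma * (1.0 + 0.34 * record.u2_ms)
    if denom <= 0:
        raise ValueError("degenerate Penman-Monteith denominator")
    radiative = 0.408 * delta * (record.rn_mj - record.g_mj)
    aerodynamic = gamma * (900.0 / (t + 273.0)) * record.u2_ms * (record.es_kpa - record.ea_kpa)
    return max(0.0, (radiative + aerodynamic) / denom)


def effective_rainfall(p_tot_mm: float) -> float:
    """Effective rainfall P_eff = P_tot (125 - 0.2 P_tot)/125, clipped to [0, P_tot].

    The quadratic loss model peaks at P_tot = 312.5 mm; the clip guards the
    (physically irrelevant) descending branch and negative values.
    """
    if p_tot_mm < 0:
        raise ValueError("rainfall must be >= 0")
    p_eff = p_tot_mm * (125.0 - 0.2 * p_tot_mm) / 125.0
    return float(min(max(p_eff, 0.0), p_tot_mm))


def _rescale_stage_lengths(profile: KcProfile, lgp_days: int) -> list[int]:
    """Proportionally rescale the four stage lengths to sum to lgp_days.

    Largest-remainder rounding keeps the sum exact while each stage stays
    at least one day long.
    """
    raw = np.array(
        [profile.len_ini, profile.len_dev, profile.len_mid, profile.len_late], dtype=float
    )
    scaled = raw * lgp_days / raw.sum()
    floors = np.maximum(np.floor(scaled).astype(int), 1)
    remainder = lgp_days - int(floors.sum())
    if remainder < 0:  # floors forced above target by the 1-day minimum
        order = np.argsort(scaled - floors)  # shrink the most over-allocated first
        for i in order:
            while remainder < 0 and floors[i] > 1:
                floors[i] -= 1
                remainder += 1
    else:
        order = np.argsort(-(scaled - floors))
        for i in order[:remainder]:
            floors[i] += 1
    return [int(n) for n in floors]


def build_kc_curve(profile: KcProfile, lgp_days: int | None = None) -> np.ndarray:
    """Daily Kc sequence over the growth period.

    Stage lengths are rescaled proportionally to ``lgp_days`` (field calendars
    are often shorter than the tabulated stage totals). The curve is constant
    at ``kc_ini`` through the initial stage, ramps linearly to ``kc_mid``
    across development (day j of nd takes kc_ini + (kc_mid-kc_ini)*j/nd, so
    the ramp lands exactly on kc_mid at the stage boundary and the midpoint
    of an even-length stage equals the tabulated development value), holds
    ``kc_mid`` through mid-season, then ramps linearly to ``kc_late``.
    """
    if lgp_days is None:
        lgp_days = profile.total_days
    if lgp_days < 4:
        raise ValueError("growth period must be at least 4 days (one per stage)")
    n_ini, n_dev, n_mid, n_late = _rescale_stage_lengths(profile, lgp_days)
    j_dev = np.arange(1, n_dev + 1)
    j_late = np.arange(1, n_late + 1)
    curve = np.concatenate(
        [
            np.full(n_ini, profile.kc_ini),
            profile.kc_ini + (profile.kc_mid - profile.kc_ini) * j_dev / n_dev,
            np.full(n_mid, profile.kc_mid),
            profile.kc_mid + (profile.kc_late - profile.kc_mid) * j_late / n_late,
        ]
    )
    assert curve.size == lgp_days
    return curve


def crop_et_series(
    dates: list[Date],
    eto_mm: np.ndarray,
    kc: np.ndarray,
    rain_mm: np.ndarray | None = None,
    rain_is_effective: bool = False,
) -> ETSeries:
    """Daily crop ET and its green/blue partition over one season.

    ETc(day) = ETo(day) * Kc(day); the seasonal sum is the crop water
    requirement. Daily effective rainfall defaults to the quadratic loss
    model applied to each day's total; pass ``rain_is_effective=True`` to
    treat the rain series as already-effective depths.
    """
    eto_mm = np.asarray(eto_mm, dtype=float)
    kc = np.asarray(kc, dtype=float)
    if not (len(dates) == eto_mm.size == kc.size):
        raise ValueError("dates, ETo and Kc series must align")
    if rain_mm is None:
        rain_mm = np.zeros_like(eto_mm)
    rain_mm = np.asarray(rain_mm, dtype=float)
    if rain_mm.size != eto_mm.size:
        raise ValueError("rain series must align with ETo series")

    etc = eto_mm * kc
    if rain_is_effective:
        p_eff = rain_mm.copy()
    else:
        p_eff = np.array([effective_rainfall(p) for p in rain_mm])
    et_green = np.minimum(etc, p_eff)
    et_blue = np.maximum(0.0, etc - p_eff)
    return ETSeries(
        dates=list(dates), eto=eto_mm, kc=kc, etc=etc,
        p_eff=p_eff, et_green=et_green, et_blue=et_blue,
    )


def leaching_fraction(ecw_ds_m: float, ece_ds_m: float) -> float:
    """Leaching requirement fraction f = ECw / (5 ECe - ECw).

    ECw is the irrigation-water salinity and ECe the soil saturation-extract
    salinity (dS/m). The denominator 5*ECe - ECw must be positive, i.e. the
    irrigation water must be fresher than five times the soil tolerance.
    """
    if ecw_ds_m < 0 or ece_ds_m <= 0:
        raise ValueError("require ECw >= 0 and ECe > 0")
    denom = 5.0 * ece_ds_m - ecw_ds_m
    if denom <= 0:
        raise ValueError("salinity out of range: 5*ECe must exceed ECw")
    return ecw_ds_m / denom


def leaching_depth(cwr_mm: float, f: float) -> float:
    """Extra irrigation depth (mm) that flushes salts at leaching fraction f.

    Under the gross-application identity the leaching water is the fraction f
    of the *gross* depth CWR + LR, so LR = CWR * f / (1 - f). Report-level
    rounding to integer mm is left to callers.
    """
    if not (0.0 <= f < 1.0):
        raise ValueError("leaching fraction must lie in [0, 1)")
    if cwr_mm < 0:
        raise ValueError("CWR must be >= 0")
    return cwr_mm * f / (1.0 - f)


def water_requirement_q(
    areas_ha: np.ndarray, etc_mm_d: np.ndarray, p_eff_mm_d: np.ndarray
) -> float:
    """Daily agricultural water requirement Q (m^3/day) over several fields.

    Q = sum_i A_i * max(ETc_i - P_eff_i, 0) * 10; the factor 10 converts a
    depth in mm over an area in ha to m^3. Fields whose effective rain
    exceeds demand contribute zero rather than a negative volume.
    """
    areas_ha = np.asarray(areas_ha, dtype=float)
    deficit = np.maximum(np.asarray(etc_mm_d, float) - np.asarray(p_eff_mm_d, float), 0.0)
    return float(np.sum(areas_ha * deficit * 10.0))


def gross_irrigation(net_mm: float, efficiency: float = 0.70) -> float:
    """Gross application depth for a net requirement under system efficiency.

    Center-pivot sprinkler systems deliver a fixed fraction of the applied
    water to the crop; the study farms run at 70%.
    """
    if not (0.0 < efficiency <= 1.0):
        raise ValueError("efficiency must lie in (0, 1]")
    if net_mm < 0:
        raise ValueError("net requirement must be >= 0")
    return net_mm / efficiency
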