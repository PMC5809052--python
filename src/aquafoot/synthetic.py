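"""Synthetic weather, field and satellite-scene generator with known truth.

Emulates the study conditions of an arid center-pivot farm so every stage of
the water-footprint pipeline can be exercised and verified without external
data: a hyper-arid monthly climatology (reference ET 155-530 mm/month,
~13.6 mm of rain per year falling in one or two discrete events), six
circular fields (four silage-maize, two carrot) with crop calendars and
salinity drawn from the bundled reference ranges, and a 16-day cadence of
"satellite" scenes whose vegetation index follows the crop-coefficient
trajectory (peaking at the published per-crop SAVI) and whose land-surface
temperature encodes a known ET fraction between fixed hot/cold anchors:

    LST = T_h - ETf_true * (T_h - T_c) + noise,
    ETf_true = Kc(day) / Kc_mid.

With all noise levels at zero, the SSEB inversion recovers ETf_true exactly
and monthly ETo totals equal the configured climatology, so the generator
doubles as a machine-checkable oracle (the TruthBundle).

Reflectance is phenomenological: the red band is held at a constant soil/
canopy value and the NIR band is solved from the target SAVI, with optional
Gaussian noise on both. No radiative transfer or atmosphere is simulated.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field as dc_field
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd

from . import fixtures
from .agromet import FieldRecord, MeteoRecord, build_kc_curve, crop_et_series
from .raster import GridTransform, SceneRaster
from .wf import GreyParams, WFResult, accumulate_cwu, awu_grey, grey_load, wf_components

__all__ = [
    "FieldSpec",
    "SyntheticConfig",
    "TruthBundle",
    "generate_weather",
    "generate_fields",
    "generate_scene_series",
]

_SAVI_L = 0.5          # soil-brightness factor used when synthesising reflectance
_RED_REFLECTANCE = 0.10


@dataclass(frozen=True)
class FieldSpec:
    """Placement and identity of one circular (center-pivot) field."""

    field_id: str
    crop: str
    season: str
    center_row: int
    center_col: int
    radius_px: int
    sowing: Date
    harvest: Date


def _default_layout() -> list[FieldSpec]:
    """Six 50 ha pivots on a 120x120 grid: four maize, two carrot.

    Calendars follow the bundled seasonal records; the two carrot entries
    take one summer and one winter season so both regimes are exercised.
    """
    seasons = fixtures.load_table("crop_seasons").set_index("field_id")
    placements = [
        ("TE-11", 30, 20), ("PAL", 30, 60), ("TE-2", 30, 100),
        ("TE-9", 90, 20), ("3-5N", 90, 60), ("5-5S", 90, 100),
    ]
    specs = []
    for fid, row, col in placements:
        rec = seasons.loc[fid]
        specs.append(
            FieldSpec(
                field_id=fid, crop=rec["crop"], season=rec["season"],
                center_row=row, center_col=col, radius_px=15,
                sowing=rec["sowing"], harvest=rec["harvest"],
            )
        )
    return specs


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults reproduce the study conditions."""

    seed: int = 0
    monthly_climatology: pd.DataFrame | None = None   # defaults to bundled table
    rain_events: list[tuple[Date, float]] = dc_field(
        default_factory=lambda: [(Date(2016, 4, 15), 8.9), (Date(2016, 11, 15), 4.7)]
    )
    field_layout: list[FieldSpec] = dc_field(default_factory=_default_layout)
    grid_shape: tuple[int, int] = (120, 120)
    pixel_size_m: float = 30.0
    scene_interval_days: int = 16
    noise_lst_k: float = 0.0
    noise_reflectance: float = 0.0
    peak_savi: dict = dc_field(default_factory=lambda: {"maize": 0.456, "carrot": 0.416})
    savi_min: float = 0.10           # canopy SAVI at emergence
    background_savi: float = 0.05
    t_hot_k: float = 320.0
    t_cold_k: float = 295.0
    ece_range: tuple[float, float] = (1.4, 5.3)
    ecw_range: tuple[float, float] = (1.4, 2.1)
    n_rate_kg_ha: float = 125.0      # synthetic-run nitrogen rate (not a study value)
    area_ha: float = 50.0
    grey_params: GreyParams = dc_field(default_factory=GreyParams)

    def __post_init__(self) -> None:
        if self.monthly_climatology is None:
            self.monthly_climatology = fixtures.load_table("climatology")
        if self.noise_lst_k < 0 or self.noise_reflectance < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not self.field_layout:
            raise ValueError("field layout must be non-empty")
        nrow, ncol = self.grid_shape
        for spec in self.field_layout:
            if not (
                spec.radius_px <= spec.center_row <= nrow - 1 - spec.radius_px
                and spec.radius_px <= spec.center_col <= ncol - 1 - spec.radius_px
            ):
                raise ValueError(f"field {spec.field_id} circle exceeds the grid")
        start, end = self.weather_span()
        for spec in self.field_layout:
            if spec.sowing < start or spec.harvest > end:
                raise ValueError(
                    f"field {spec.field_id} season {spec.sowing}..{spec.harvest} "
                    f"outside weather span {start}..{end}"
                )
        if not self.t_hot_k > self.t_cold_k:
            raise ValueError("hot anchor must exceed cold anchor")

    def weather_span(self) -> tuple[Date, Date]:
        clim = self.monthly_climatology
        first = Date(int(clim.iloc[0]["year"]), int(clim.iloc[0]["month"]), 1)
        ly, lm = int(clim.iloc[-1]["year"]), int(clim.iloc[-1]["month"])
        last = Date(ly, lm, calendar.monthrange(ly, lm)[1])
        return first, last


@dataclass
class TruthBundle:
    """Ground truth paired with a generated scene series.

    etc_daily: per-field daily crop ET (mm/day) over its season;
    etf_by_scene: per-field true ET fraction at each scene date (0 outside
    the season); yield_t_ha: true yield implied by the peak SAVI through the
    reference yield model; wf: true per-field water-footprint components
    (equation convention).
    """

    etc_daily: dict[str, pd.Series]
    etf_by_scene: dict[str, dict[str, float]]
    yield_t_ha: dict[str, float]
    et_lgp_mm: dict[str, float]
    wf: dict[str, WFResult]


def generate_weather(config: SyntheticConfig) -> list[MeteoRecord]:
    """Daily weather records realising the configured monthly climatology.

    Each month's reference ET total is spread uniformly over its days, so
    monthly sums equal the climatology exactly; temperatures and wind are
    held at the monthly values. Rain falls only on the configured event
    dates. Two events on the same date are rejected.
    """
    event_dates = [d for d, _ in config.rain_events]
    if len(event_dates) != len(set(event_dates)):
        raise ValueError("overlapping rain events on the same date")
    start, end = config.weather_span()
    rain = dict(config.rain_events)
    for d, mm in config.rain_events:
        if not (start <= d <= end):
            raise ValueError(f"rain event {d} outside weather span")
        if mm < 0:
            raise ValueError("rain depth must be >= 0")

    records: list[MeteoRecord] = []
    for _, row in config.monthly_climatology.iterrows():
        year, month = int(row["year"]), int(row["month"])
        ndays = calendar.monthrange(year, month)[1]
        eto_day = float(row["eto_mm_month"]) / ndays
        for dom in range(1, ndays + 1):
            d = Date(year, month, dom)
            records.append(
                MeteoRecord(
                    date=d,
                    tmean_c=float(row["tmean_c"]),
                    tmin_c=float(row["tmin_c"]),
                    tmax_c=float(row["tmax_c"]),
                    u2_ms=float(row["u2_ms"]),
                    rain_mm=float(rain.get(d, 0.0)),
                    eto_mm=eto_day,
                )
            )
    return records


def generate_fields(config: SyntheticConfig) -> list[FieldRecord]:
    """Field records with salinity drawn from the configured arid ranges."""
    rng = np.random.default_rng(config.seed)
    wf_table = fixtures.load_table("water_footprint").set_index("field_id")
    out = []
    for spec in config.field_layout:
        ece = float(rng.uniform(*config.ece_range))
        ecw = float(rng.uniform(*config.ecw_range))
        measured_yield = (
            float(wf_table.loc[spec.field_id, "yield_t_ha"])
            if spec.field_id in wf_table.index
            else None
        )
        out.append(
            FieldRecord(
                field_id=spec.field_id,
                crop=spec.crop,
                season=spec.season,
                area_ha=config.area_ha,
                sowing=spec.sowing,
                harvest=spec.harvest,
                ece_ds_m=ece,
                ecw_ds_m=ecw,
                yield_t_ha=measured_yield,
                n_rate_kg_ha=config.n_rate_kg_ha,
            )
        )
    return out


def _field_curves(config: SyntheticConfig, spec: FieldSpec):
    """Daily Kc, true ET fraction and SAVI trajectories for one field.

    The SAVI trajectory is the Kc curve affinely rescaled so that the
    initial-stage value maps to ``savi_min`` and the mid-season plateau to
    the per-crop peak: both then share the piecewise-linear stage shape.
    """
    profile = fixtures.kc_profile_for(spec.crop, spec.season)
    lgp = (spec.harvest - spec.sowing).days + 1
    kc = build_kc_curve(profile, lgp)
    etf_true = kc / profile.kc_mid
    peak = config.peak_savi[spec.crop]
    savi = config.savi_min + (peak - config.savi_min) * (kc - profile.kc_ini) / (
        profile.kc_mid - profile.kc_ini
    )
    return kc, etf_true, savi


def _nir_for_savi(savi: np.ndarray, red: float = _RED_REFLECTANCE) -> np.ndarray:
    """Invert the SAVI definition for NIR at fixed red reflectance."""
    return (savi * (red + _SAVI_L) + red * (1.0 + _SAVI_L)) / (1.0 + _SAVI_L - savi)


def field_masks(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Boolean pixel mask of each circular field."""
    nrow, ncol = config.grid_shape
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    masks = {}
    for spec in config.field_layout:
        masks[spec.field_id] = (rr - spec.center_row) ** 2 + (
            cc - spec.center_col
        ) ** 2 <= spec.radius_px**2
    return masks


def generate_scene_series(
    config: SyntheticConfig,
    weather: list[MeteoRecord],
    fields: list[FieldRecord] | None = None,
) -> tuple[list[SceneRaster], TruthBundle]:
    """Scene stack at the configured revisit cadence, plus its ground truth.

    Scene dates run from the first weather day at ``scene_interval_days``
    steps. Inside an in-season field pixel, SAVI follows the field's
    trajectory and LST encodes the true ET fraction between the configured
    anchors; everywhere else SAVI sits at the background value and LST at
    the hot anchor. Gaussian noise (if configured) is added per pixel.
    """
    if fields is None:
        fields = generate_fields(config)
    weather_by_date = {r.date: r for r in weather}
    dates = sorted(weather_by_date)
    start, end = dates[0], dates[-1]
    scene_dates = []
    d = start
    while d <= end:
        scene_dates.append(d)
        d += timedelta(days=config.scene_interval_days)
    for d in scene_dates:
        if d not in weather_by_date:
            raise ValueError(f"scene date {d} not covered by the weather series")

    rng = np.random.default_rng(config.seed + 1)
    masks = field_masks(config)
    specs = {s.field_id: s for s in config.field_layout}
    curves = {fid: _field_curves(config, specs[fid]) for fid in specs}

    transform = GridTransform(pixel_size=config.pixel_size_m)
    scenes: list[SceneRaster] = []
    etf_by_scene: dict[str, dict[str, float]] = {fid: {} for fid in specs}
    for idx, sdate in enumerate(scene_dates):
        scene_id = f"S{idx:03d}"
        savi_grid = np.full(config.grid_shape, config.background_savi, dtype=float)
        etf_grid = np.zeros(config.grid_shape, dtype=float)
        for fid, spec in specs.items():
            _, etf_true, savi_curve = curves[fid]
            etf_by_scene[fid][scene_id] = 0.0
            if spec.sowing <= sdate <= spec.harvest:
                day_idx = (sdate - spec.sowing).days
                savi_grid[masks[fid]] = savi_curve[day_idx]
                etf_grid[masks[fid]] = etf_true[day_idx]
                etf_by_scene[fid][scene_id] = float(etf_true[day_idx])
        lst = config.t_hot_k - etf_grid * (config.t_hot_k - config.t_cold_k)
        red = np.full(config.grid_shape, _RED_REFLECTANCE, dtype=float)
        nir = _nir_for_savi(savi_grid)
        if config.noise_lst_k > 0:
            lst = lst + rng.normal(0.0, config.noise_lst_k, size=lst.shape)
        if config.noise_reflectance > 0:
            red = red + rng.normal(0.0, config.noise_reflectance, size=red.shape)
            nir = nir + rng.normal(0.0, config.noise_reflectance, size=nir.shape)
        scenes.append(
            SceneRaster(
                scene_id=scene_id,
                date=sdate,
                lst_k=np.clip(lst, 250.0, 350.0),
                red=np.clip(red, 0.0, 1.0),
                nir=np.clip(nir, 0.0, 1.0),
                transform=transform,
            )
        )

    truth = _build_truth(
        config, weather_by_date, fields, specs, curves, etf_by_scene, scene_dates
    )
    return scenes, truth


def _build_truth(config, weather_by_date, fields, specs, curves, etf_by_scene, scene_dates):
    fields_by_id = {f.field_id: f for f in fields}
    etc_daily: dict[str, pd.Series] = {}
    yields: dict[str, float] = {}
    et_lgp: dict[str, float] = {}
    wf_true: dict[str, WFResult] = {}
    from .sseb import REFERENCE_YIELD_MODELS

    for fid, spec in specs.items():
        kc, _, _ = curves[fid]
        season_dates = [
            spec.sowing + timedelta(days=i)
            for i in range((spec.harvest - spec.sowing).days + 1)
        ]
        eto = np.array([weather_by_date[d].eto_mm for d in season_dates])
        rain = np.array([weather_by_date[d].rain_mm for d in season_dates])
        series = crop_et_series(season_dates, eto, kc, rain)
        etc_daily[fid] = pd.Series(series.etc, index=pd.Index(season_dates, name="date"))

        # Seasonal ET as the scene branch defines it: season days owned by the
        # nearest in-season scene, period ETo total times that scene's true
        # ET fraction. Plain per-day loop, independent of the raster path.
        in_season = [
            (i, d) for i, d in enumerate(scene_dates) if spec.sowing <= d <= spec.harvest
        ]
        total = 0.0
        for day, eto_day in zip(season_dates, eto):
            nearest = min(in_season, key=lambda t: abs((day - t[1]).days))
            total += eto_day * etf_by_scene[fid][f"S{nearest[0]:03d}"]
        et_lgp[fid] = total

        model = REFERENCE_YIELD_MODELS[spec.crop]
        peak = config.peak_savi[spec.crop]
        yields[fid] = model.slope * peak + model.intercept

        cwu = accumulate_cwu(series.et_green, series.et_blue, convention="equation")
        grey_volume = awu_grey(grey_load(config.grey_params), config.grey_params)
        rec = fields_by_id.get(fid)
        y = yields[fid] if rec is None or rec.yield_t_ha is None else rec.yield_t_ha
        wf_true[fid] = wf_components(
            field_id=fid,
            crop=spec.crop,
            yield_t_ha=y,
            cwu_green_m3_ha=cwu["cwu_green_m3_ha"],
            cwu_blue_m3_ha=cwu["cwu_blue_m3_ha"],
            awu_grey_m3_ha=grey_volume,
            convention="equation",
        )
    return TruthBundle(
        etc_daily=etc_daily,
        etf_by_scene=etf_by_scene,
        yield_t_ha=yields,
        et_lgp_mm=et_lgp,
        wf=wf_true,
    )
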