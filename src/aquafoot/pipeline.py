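"""End-to-end orchestration: staged runs writing CSV/TIFF artifacts.

Stages (in dependency order):

    synth     -> weather.csv, fields.csv, scenes/*.tif + scene_index.csv, truth.json
    eto       -> eto.csv (daily reference ET; Penman-Monteith when not precomputed)
    cwr       -> season_report.csv (per-field CWR, leaching requirement, gross)
    wf-agro   -> wf_agro.csv (per-field green/blue/grey WF)
    sseb      -> scenes/etf_*.tif + anchors.csv
    wf-rs     -> rasters/et_lgp_*.tif, yp_*.tif, wf_b_*.tif + wf_rs.csv (zonal)
    evaluate  -> paired.csv + evaluation.csv

Each stage reads only the files of its upstream stages, so stages can be
re-run individually; a missing upstream artifact raises with the absent
path named. Runs are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .agromet import (
    MeteoRecord,
    build_kc_curve,
    crop_et_series,
    gross_irrigation,
    leaching_depth,
    leaching_fraction,
    penman_monteith_eto,
)
from .raster import NODATA, SceneRaster, read_band, write_band
from .sseb import (
    AnchorPair,
    REFERENCE_YIELD_MODELS,
    compute_savi,
    et_fraction,
    predict_yield,
    select_anchors,
    upscale_et_lgp,
    wf_rs_blue,
)
from .synthetic import SyntheticConfig, generate_fields, generate_scene_series, generate_weather
from .wf import GreyParams, accumulate_cwu, aggregate_report, awu_grey, grey_load, wf_components
from .evaluation import paired_report_table

log = logging.getLogger("aquafoot")

STAGES = ("synth", "eto", "cwr", "wf-agro", "sseb", "wf-rs", "evaluate")


@dataclass
class RunConfig:
    """Run-level settings; everything defaults to the synthetic study setup."""

    outdir: Path = Path("aquafoot_run")
    seed: int = 0
    convention: str = "equation"
    elevation_m: float = 400.0
    anchors: str | tuple[float, float] = "scene"   # "scene" (select per scene) or fixed pair
    yield_floor_t_ha: float = 1.0
    grey: GreyParams = dc_field(default_factory=GreyParams)
    synthetic: SyntheticConfig = dc_field(default_factory=SyntheticConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "outdir" in raw:
            kwargs["outdir"] = Path(raw["outdir"])
        for key in ("seed", "convention", "elevation_m", "yield_floor_t_ha"):
            if key in raw:
                kwargs[key] = raw[key]
        if "anchors" in raw:
            a = raw["anchors"]
            kwargs["anchors"] = tuple(a) if isinstance(a, (list, tuple)) else a
        if "grey" in raw:
            kwargs["grey"] = GreyParams(**raw["grey"])
        if "synthetic" in raw:
            syn = dict(raw["synthetic"])
            kwargs["synthetic"] = SyntheticConfig(**syn)
        cfg = cls(**kwargs)
        if isinstance(cfg.seed, bool) or not isinstance(cfg.seed, int):
            raise ValueError("seed must be an integer")
        return cfg


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the '{producer}' stage first"
        )
    return path


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all) into ``config.outdir``."""
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; expected subset of {STAGES}")
    config.outdir.mkdir(parents=True, exist_ok=True)
    runners = {
        "synth": stage_synth,
        "eto": stage_eto,
        "cwr": stage_cwr,
        "wf-agro": stage_wf_agro,
        "sseb": stage_sseb,
        "wf-rs": stage_wf_rs,
        "evaluate": stage_evaluate,
    }
    for name in STAGES:  # canonical order regardless of request order
        if name in stages:
            log.info("stage %s -> %s (seed=%d)", name, config.outdir, config.seed)
            runners[name](config)
    return config.outdir


# --- stage implementations --------------------------------------------------

def stage_synth(config: RunConfig) -> None:
    syn = config.synthetic
    if syn.seed != config.seed:
        # single source of truth for randomness: the run seed
        syn = SyntheticConfig(**{**syn.__dict__, "seed": config.seed})
    weather = generate_weather(syn)
    fields = generate_fields(syn)
    scenes, truth = generate_scene_series(syn, weather, fields)
    out = config.outdir

    pd.DataFrame(
        {
            "date": [r.date for r in weather],
            "tmin_c": [r.tmin_c for r in weather],
            "tmax_c": [r.tmax_c for r in weather],
            "tmean_c": [r.tmean_c for r in weather],
            "rain_mm": [r.rain_mm for r in weather],
            "u2_ms": [r.u2_ms for r in weather],
            "eto_mm": [r.eto_mm for r in weather],
        }
    ).to_csv(out / "weather.csv", index=False)

    layout = {s.field_id: s for s in syn.field_layout}
    pd.DataFrame(
        {
            "field_id": [f.field_id for f in fields],
            "crop": [f.crop for f in fields],
            "season": [f.season for f in fields],
            "area_ha": [f.area_ha for f in fields],
            "sowing": [f.sowing for f in fields],
            "harvest": [f.harvest for f in fields],
            "ece_ds_m": [f.ece_ds_m for f in fields],
            "ecw_ds_m": [f.ecw_ds_m for f in fields],
            "yield_t_ha": [f.yield_t_ha for f in fields],
            "n_rate_kg_ha": [f.n_rate_kg_ha for f in fields],
            "center_row": [layout[f.field_id].center_row for f in fields],
            "center_col": [layout[f.field_id].center_col for f in fields],
            "radius_px": [layout[f.field_id].radius_px for f in fields],
        }
    ).to_csv(out / "fields.csv", index=False)

    scene_dir = out / "scenes"
    scene_dir.mkdir(exist_ok=True)
    index_rows = []
    for sc in scenes:
        paths = {}
        for band, grid in (("lst_k", sc.lst_k), ("red", sc.red), ("nir", sc.nir)):
            p = scene_dir / f"{band}_{sc.scene_id}.tif"
            write_band(p, grid)
            paths[band] = p.name
        index_rows.append(
            {
                "scene_id": sc.scene_id,
                "date": sc.date,
                "lst_path": paths["lst_k"],
                "red_path": paths["red"],
                "nir_path": paths["nir"],
                "pixel_size_m": sc.transform.pixel_size,
            }
        )
    pd.DataFrame(index_rows).to_csv(out / "scene_index.csv", index=False)

    (out / "truth.json").write_text(
        json.dumps(
            {
                "et_lgp_mm": truth.et_lgp_mm,
                "yield_t_ha": truth.yield_t_ha,
                "etf_by_scene": truth.etf_by_scene,
                "wf_blue_m3_t": {fid: r.wf_blue for fid, r in truth.wf.items()},
                "anchors_k": [syn.t_hot_k, syn.t_cold_k],
            },
            indent=1,
            default=str,
        )
    )


def _load_weather(config: RunConfig) -> pd.DataFrame:
    path = _require(config.outdir / "weather.csv", "synth")
    frame = pd.read_csv(path, parse_dates=["date"])
    frame["date"] = frame["date"].dt.date
    return frame


def _load_fields(config: RunConfig) -> pd.DataFrame:
    path = _require(config.outdir / "fields.csv", "synth")
    frame = pd.read_csv(path, parse_dates=["sowing", "harvest"])
    for col in ("sowing", "harvest"):
        frame[col] = frame[col].dt.date
    return frame


def stage_eto(config: RunConfig) -> None:
    weather = _load_weather(config)
    if "eto_mm" not in weather.columns or weather["eto_mm"].isna().any():
        eto = []
        for _, row in weather.iterrows():
            rec = MeteoRecord(
                date=row["date"], tmean_c=row["tmean_c"], tmin_c=row.get("tmin_c"),
                tmax_c=row.get("tmax_c"), u2_ms=row["u2_ms"], rn_mj=row["rn_mj"],
                g_mj=row.get("g_mj", 0.0), es_kpa=row["es_kpa"], ea_kpa=row["ea_kpa"],
                rain_mm=row["rain_mm"],
            )
            eto.append(penman_monteith_eto(rec, config.elevation_m))
        weather["eto_mm"] = eto
    weather[["date", "eto_mm", "rain_mm"]].to_csv(config.outdir / "eto.csv", index=False)


def _season_series(field_row, weather: pd.DataFrame):
    season_dates = [
        field_row["sowing"] + timedelta(days=i)
        for i in range((field_row["harvest"] - field_row["sowing"]).days + 1)
    ]
    by_date = weather.set_index("date")
    eto = np.array([by_date.loc[d, "eto_mm"] for d in season_dates])
    rain = np.array([by_date.loc[d, "rain_mm"] for d in season_dates])
    profile = fixtures.kc_profile_for(field_row["crop"], field_row["season"])
    kc = build_kc_curve(profile, len(season_dates))
    return crop_et_series(season_dates, eto, kc, rain)


def stage_cwr(config: RunConfig) -> None:
    _require(config.outdir / "eto.csv", "eto")
    weather = _load_weather(config)
    weather["eto_mm"] = pd.read_csv(config.outdir / "eto.csv")["eto_mm"].to_numpy()
    fields = _load_fields(config)
    rows = []
    for _, frow in fields.iterrows():
        series = _season_series(frow, weather)
        f = leaching_fraction(frow["ecw_ds_m"], frow["ece_ds_m"])
        lr = leaching_depth(series.cwr_mm, f)
        rows.append(
            {
                "field_id": frow["field_id"],
                "crop": frow["crop"],
                "season": frow["season"],
                "lgp_days": len(series.dates),
                "cwr_mm": series.cwr_mm,
                "lr_mm": round(lr),
                "cwr_plus_lr_mm": round(series.cwr_mm + lr),
                "gross_irrigation_mm": gross_irrigation(series.cwr_mm + lr),
            }
        )
    pd.DataFrame(rows).to_csv(config.outdir / "season_report.csv", index=False)


def stage_wf_agro(config: RunConfig) -> None:
    eto_path = _require(config.outdir / "eto.csv", "eto")
    weather = _load_weather(config)
    weather["eto_mm"] = pd.read_csv(eto_path)["eto_mm"].to_numpy()
    fields = _load_fields(config)
    results = []
    for _, frow in fields.iterrows():
        series = _season_series(frow, weather)
        cwu = accumulate_cwu(series.et_green, series.et_blue, config.convention)
        grey = GreyParams(
            alpha=config.grey.alpha,
            c_max_mg_l=config.grey.c_max_mg_l,
            c_nat_mg_l=config.grey.c_nat_mg_l,
            ar_kg_ha=float(frow["n_rate_kg_ha"]),
        )
        grey_volume_eq = awu_grey(grey_load(grey), grey)  # m^3/ha, physical (x10) scale
        factor_ratio = 10.0 if config.convention == "table" else 1.0
        results.append(
            wf_components(
                field_id=frow["field_id"],
                crop=frow["crop"],
                yield_t_ha=float(frow["yield_t_ha"]),
                cwu_green_m3_ha=cwu["cwu_green_m3_ha"],
                cwu_blue_m3_ha=cwu["cwu_blue_m3_ha"],
                awu_grey_m3_ha=grey_volume_eq * factor_ratio,
                convention=config.convention,
            )
        )
    frame = pd.DataFrame(
        {
            "field_id": [r.field_id for r in results],
            "crop": [r.crop for r in results],
            "yield_t_ha": [r.yield_t_ha for r in results],
            "wf_green": [r.wf_green for r in results],
            "wf_blue": [r.wf_blue for r in results],
            "wf_grey": [r.wf_grey for r in results],
            "wf_total": [r.wf_total for r in results],
            "convention": [r.convention for r in results],
        }
    )
    frame.to_csv(config.outdir / "wf_agro.csv", index=False)
    aggregate_report(results).to_csv(config.outdir / "wf_agro_summary.csv", index=False)


def _load_scenes(config: RunConfig) -> list[SceneRaster]:
    index_path = _require(config.outdir / "scene_index.csv", "synth")
    index = pd.read_csv(index_path, parse_dates=["date"])
    scene_dir = config.outdir / "scenes"
    scenes = []
    for _, row in index.iterrows():
        scenes.append(
            SceneRaster(
                scene_id=row["scene_id"],
                date=row["date"].date(),
                lst_k=read_band(_require(scene_dir / row["lst_path"], "synth")),
                red=read_band(_require(scene_dir / row["red_path"], "synth")),
                nir=read_band(_require(scene_dir / row["nir_path"], "synth")),
            )
        )
    return scenes


def _crop_mask(config: RunConfig, fields: pd.DataFrame) -> np.ndarray:
    masks = _field_mask_dict(config, fields)
    combined = np.zeros(next(iter(masks.values())).shape, dtype=bool)
    for m in masks.values():
        combined |= m
    return combined


def _field_mask_dict(config: RunConfig, fields: pd.DataFrame) -> dict[str, np.ndarray]:
    shape = config.synthetic.grid_shape
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    masks = {}
    for _, frow in fields.iterrows():
        masks[frow["field_id"]] = (rr - frow["center_row"]) ** 2 + (
            cc - frow["center_col"]
        ) ** 2 <= frow["radius_px"] ** 2
    return masks


def _anchors_for(config: RunConfig, scene: SceneRaster, crop_mask: np.ndarray) -> AnchorPair:
    if isinstance(config.anchors, tuple):
        t_hot, t_cold = config.anchors
        return AnchorPair(t_hot_k=float(t_hot), t_cold_k=float(t_cold))
    return select_anchors(scene, crop_mask)


def stage_sseb(config: RunConfig) -> None:
    scenes = _load_scenes(config)
    fields = _load_fields(config)
    crop_mask = _crop_mask(config, fields)
    scene_dir = config.outdir / "scenes"
    rows = []
    for sc in scenes:
        anchors = _anchors_for(config, sc, crop_mask)
        etf = et_fraction(sc.lst_k, anchors)
        write_band(scene_dir / f"etf_{sc.scene_id}.tif", etf)
        rows.append(
            {
                "scene_id": sc.scene_id,
                "date": sc.date,
                "t_hot_k": anchors.t_hot_k,
                "t_cold_k": anchors.t_cold_k,
                "n_hot_px": anchors.n_hot_px,
                "n_cold_px": anchors.n_cold_px,
            }
        )
    pd.DataFrame(rows).to_csv(config.outdir / "anchors.csv", index=False)


def stage_wf_rs(config: RunConfig) -> None:
    _require(config.outdir / "anchors.csv", "sseb")
    eto_path = _require(config.outdir / "eto.csv", "eto")
    weather = _load_weather(config)
    weather["eto_mm"] = pd.read_csv(eto_path)["eto_mm"].to_numpy()
    fields = _load_fields(config)
    scenes = _load_scenes(config)
    scene_dir = config.outdir / "scenes"
    etf_grids = {
        sc.scene_id: read_band(_require(scene_dir / f"etf_{sc.scene_id}.tif", "sseb"))
        for sc in scenes
    }
    masks = _field_mask_dict(config, fields)
    raster_dir = config.outdir / "rasters"
    raster_dir.mkdir(exist_ok=True)

    weather_by_date = weather.set_index("date")
    rows = []
    for _, frow in fields.iterrows():
        fid = frow["field_id"]
        in_season = [sc for sc in scenes if frow["sowing"] <= sc.date <= frow["harvest"]]
        if not in_season:
            raise ValueError(f"no scene within the season of field {fid}")
        season_dates = [
            frow["sowing"] + timedelta(days=i)
            for i in range((frow["harvest"] - frow["sowing"]).days + 1)
        ]
        eto = np.array([weather_by_date.loc[d, "eto_mm"] for d in season_dates])
        et_lgp = upscale_et_lgp(
            [sc.date for sc in in_season],
            [etf_grids[sc.scene_id] for sc in in_season],
            season_dates,
            eto,
        )
        # yield from the mid-season scene's SAVI (peak canopy)
        mid = min(
            in_season,
            key=lambda sc: abs(
                (sc.date - frow["sowing"]).days - len(season_dates) // 2
            ),
        )
        savi = compute_savi(mid.red, mid.nir)
        model = REFERENCE_YIELD_MODELS[frow["crop"]]
        yp = predict_yield(model, savi)
        wf_grid = wf_rs_blue(et_lgp, yp, config.convention, config.yield_floor_t_ha)

        write_band(raster_dir / f"et_lgp_{fid}.tif", et_lgp)
        write_band(raster_dir / f"yp_{fid}.tif", yp)
        write_band(raster_dir / f"wf_b_{fid}.tif", wf_grid)

        mask = masks[fid]
        valid = mask & (wf_grid != NODATA)
        rows.append(
            {
                "field_id": fid,
                "crop": frow["crop"],
                "et_lgp_mm": float(np.mean(et_lgp[mask & (et_lgp != NODATA)])),
                "yp_t_ha": float(np.mean(yp[mask & (yp != NODATA)])),
                "wf_rs_blue": float(np.mean(wf_grid[valid])) if valid.any() else np.nan,
                "n_pixels": int(valid.sum()),
            }
        )
    pd.DataFrame(rows).to_csv(config.outdir / "wf_rs.csv", index=False)


def stage_evaluate(config: RunConfig) -> None:
    agro = pd.read_csv(_require(config.outdir / "wf_agro.csv", "wf-agro"))
    rs = pd.read_csv(_require(config.outdir / "wf_rs.csv", "wf-rs"))
    paired, reports = paired_report_table(agro, rs)
    paired.to_csv(config.outdir / "paired.csv", index=False)
    rows = []
    for crop, rep in reports.items():
        if rep is None:
            rows.append({"crop": crop, "n": 1, "note": "agreement stats undefined (n<2)"})
        else:
            rows.append({"crop": crop, **rep.to_dict(), "note": ""})
    pd.DataFrame(rows).to_csv(config.outdir / "evaluation.csv", index=False)
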