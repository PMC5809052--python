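"""Remote-sensing branch: SAVI, SSEB ET fraction, seasonal ET, yield and blue WF.

The simplified surface energy balance (SSEB) scales land-surface temperature
linearly between a hot anchor T_h (zero-ET bare soil) and a cold anchor T_c
(fully transpiring canopy) to obtain a per-pixel ET fraction,

    ETf = (T_h - T_s) / (T_h - T_c),  clipped to [0, 1],

which multiplies the day's reference ET to give actual ET. Per-scene ET
fractions are upscaled to a season total by assigning each season day to its
nearest acquisition in time. Yield is predicted from the soil-adjusted
vegetation index (SAVI) at peak growth via a per-crop linear model, and the
blue water footprint of each pixel is seasonal ET volume divided by
predicted yield.

No aerodynamic-resistance or iterative sensible-heat computation is
performed: this is SSEB's linear LST scaling, not SEBAL/METRIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date

import numpy as np
import statsmodels.api as sm

from .raster import NODATA, SceneRaster
from .wf import VOLUME_FACTORS

__all__ = [
    "AnchorPair",
    "YieldModel",
    "REFERENCE_YIELD_MODELS",
    "compute_savi",
    "select_anchors",
    "et_fraction",
    "eta_daily",
    "upscale_et_lgp",
    "fit_yield_model",
    "predict_yield",
    "wf_rs_blue",
]


@dataclass(frozen=True)
class AnchorPair:
    """Hot/cold reference temperatures for one scene, with selection provenance."""

    t_hot_k: float
    t_cold_k: float
    n_hot_px: int = 0
    n_cold_px: int = 0
    hot_savi_pctl: float = 10.0
    cold_savi_pctl: float = 90.0
    tail_pct: float = 1.0

    def __post_init__(self) -> None:
        if not self.t_hot_k > self.t_cold_k:
            raise ValueError("hot anchor must be warmer than cold anchor")


@dataclass
class YieldModel:
    """Linear SAVI-to-yield model Y = slope * SAVI + intercept (t/ha).

    ``validation`` and ``cross_validation`` hold agreement diagnostics
    (R2, RMSE%, NSE, MBE%) on the fitting split and the held-out split.
    """

    crop: str
    slope: float
    intercept: float
    validation: dict | None = None
    cross_validation: dict | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("model coefficients must be finite")


#: Published reference coefficients for the two study crops, usable without fitting.
REFERENCE_YIELD_MODELS = {
    "maize": YieldModel(crop="maize", slope=44.265, intercept=11.147),
    "carrot": YieldModel(crop="carrot", slope=87.223, intercept=5.686),
}


def compute_savi(red: np.ndarray, nir: np.ndarray, soil_factor: float = 0.5) -> np.ndarray:
    """Soil-adjusted vegetation index with soil-brightness term L.

    SAVI = (NIR - red) / (NIR + red + L) * (1 + L); L = 0 reduces to NDVI.
    Nodata in either band propagates.
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if red.shape != nir.shape:
        raise ValueError("red and NIR grids must be aligned")
    valid = (red != NODATA) & (nir != NODATA)
    if not valid.any():
        raise ValueError("empty scene: no valid reflectance pixels")
    out = np.full(red.shape, NODATA, dtype=float)
    denom = nir[valid] + red[valid] + soil_factor
    out[valid] = (nir[valid] - red[valid]) / denom * (1.0 + soil_factor)
    return out


def select_anchors(
    scene: SceneRaster,
    crop_mask: np.ndarray,
    savi: np.ndarray | None = None,
    tail_pct: float = 1.0,
    cold_savi_pctl: float = 90.0,
    hot_savi_pctl: float = 10.0,
    min_pixels: int = 10,
) -> AnchorPair:
    """SAVI-conditioned percentile anchors for one scene.

    The cold anchor is the mean LST of the coldest ``tail_pct`` % among
    densely vegetated pixels (SAVI above its ``cold_savi_pctl`` percentile
    inside the crop mask); the hot anchor is the mean LST of the hottest
    ``tail_pct`` % among sparsely vegetated pixels (SAVI below its
    ``hot_savi_pctl`` percentile over the whole valid scene). Raises on
    thermally degenerate scenes (T_h <= T_c).
    """
    if savi is None:
        savi = compute_savi(scene.red, scene.nir)
    valid = scene.valid_mask & (savi != NODATA)
    inside = valid & crop_mask.astype(bool)
    outside = valid & ~crop_mask.astype(bool)
    if inside.sum() < min_pixels or outside.sum() < min_pixels:
        raise ValueError(
            f"need >= {min_pixels} valid pixels inside and outside the crop mask"
        )

    cold_pool_savi = np.percentile(savi[inside], cold_savi_pctl)
    cold_pool = valid & (savi >= cold_pool_savi) & crop_mask.astype(bool)
    hot_pool_savi = np.percentile(savi[valid], hot_savi_pctl)
    hot_pool = valid & (savi <= hot_pool_savi)

    def _tail_mean(lst: np.ndarray, coldest: bool) -> tuple[float, int]:
        n = max(1, int(np.ceil(lst.size * tail_pct / 100.0)))
        ordered = np.sort(lst)
        tail = ordered[:n] if coldest else ordered[-n:]
        return float(tail.mean()), n

    t_cold, n_cold = _tail_mean(scene.lst_k[cold_pool], coldest=True)
    t_hot, n_hot = _tail_mean(scene.lst_k[hot_pool], coldest=False)
    if t_hot <= t_cold:
        raise ValueError(
            f"degenerate scene: hot anchor {t_hot:.2f} K <= cold anchor {t_cold:.2f} K"
        )
    return AnchorPair(
        t_hot_k=t_hot,
        t_cold_k=t_cold,
        n_hot_px=n_hot,
        n_cold_px=n_cold,
        hot_savi_pctl=hot_savi_pctl,
        cold_savi_pctl=cold_savi_pctl,
        tail_pct=tail_pct,
    )


def et_fraction(lst_k: np.ndarray, anchors: AnchorPair) -> np.ndarray:
    """Per-pixel ET fraction (T_h - T_s)/(T_h - T_c), clipped to [0, 1]."""
    lst_k = np.asarray(lst_k, dtype=float)
    out = np.full(lst_k.shape, NODATA, dtype=float)
    valid = lst_k != NODATA
    frac = (anchors.t_hot_k - lst_k[valid]) / (anchors.t_hot_k - anchors.t_cold_k)
    out[valid] = np.clip(frac, 0.0, 1.0)
    return out


def eta_daily(etf: np.ndarray, eto_mm_d: float, k: float = 1.0) -> np.ndarray:
    """Actual ET (mm/day): ETa = ETf * k * ETo, nodata propagated."""
    if eto_mm_d < 0:
        raise ValueError("reference ET must be >= 0")
    etf = np.asarray(etf, dtype=float)
    out = np.full(etf.shape, NODATA, dtype=float)
    valid = etf != NODATA
    out[valid] = etf[valid] * k * eto_mm_d
    return out


def upscale_et_lgp(
    scene_dates: list[Date],
    etf_grids: list[np.ndarray],
    daily_dates: list[Date],
    daily_eto_mm: np.ndarray,
) -> np.ndarray:
    """Season-total ET grid (mm) from per-scene ET fractions.

    The season days are partitioned into periods, each day owning the scene
    nearest in time (ties go to the earlier scene); the seasonal total is
    ET_lgp = sum_i (sum of ETo over period i's days) * ETf_i — the period
    ETo enters as a total, which keeps the result in mm.
    """
    if len(scene_dates) != len(etf_grids):
        raise ValueError("one ETf grid per scene date required")
    if not scene_dates:
        raise ValueError("no scene within the season")
    daily_eto_mm = np.asarray(daily_eto_mm, dtype=float)
    if len(daily_dates) != daily_eto_mm.size:
        raise ValueError("daily dates and ETo must align")

    order = np.argsort([d.toordinal() for d in scene_dates])
    scene_ords = np.array([scene_dates[i].toordinal() for i in order])
    grids = [np.asarray(etf_grids[i], dtype=float) for i in order]

    day_ords = np.array([d.toordinal() for d in daily_dates])
    # nearest scene per day; ties broken toward the earlier scene
    dist = np.abs(day_ords[:, None] - scene_ords[None, :])
    owner = np.argmin(dist, axis=1)

    total = np.zeros(grids[0].shape, dtype=float)
    nodata_mask = np.zeros(grids[0].shape, dtype=bool)
    for i, grid in enumerate(grids):
        period_eto = float(daily_eto_mm[owner == i].sum())
        nodata_mask |= grid == NODATA
        total += np.where(grid == NODATA, 0.0, grid) * period_eto
    total[nodata_mask] = NODATA
    return total


def fit_yield_model(
    savi: np.ndarray,
    yield_t_ha: np.ndarray,
    crop: str = "",
    train_frac: float = 0.60,
    seed: int = 0,
) -> YieldModel:
    """Ordinary least squares of observed yield on peak-season SAVI.

    Samples are shuffled with ``seed`` and split ``train_frac`` /
    (1 - train_frac); coefficients come from the training split and
    agreement diagnostics (R2, RMSE%, NSE, MBE%) are reported for both
    splits.
    """
    from .evaluation import compare_estimates  # late import: avoids a cycle

    savi = np.asarray(savi, dtype=float)
    yield_t_ha = np.asarray(yield_t_ha, dtype=float)
    if savi.size != yield_t_ha.size:
        raise ValueError("SAVI and yield samples must align")
    if savi.size < 10:
        raise ValueError("need at least 10 samples to fit a yield model")
    if np.ptp(savi) == 0:
        raise ValueError("degenerate samples: SAVI is constant")

    rng = np.random.default_rng(seed)
    idx = rng.permutation(savi.size)
    n_train = int(round(train_frac * savi.size))
    train, test = idx[:n_train], idx[n_train:]

    fit = sm.OLS(yield_t_ha[train], sm.add_constant(savi[train])).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])

    def _diag(split: np.ndarray) -> dict:
        pred = slope * savi[split] + intercept
        rep = compare_estimates(yield_t_ha[split], pred)
        return {
            "r2": rep.r2,
            "rmse_pct": rep.rmse_pct,
            "nse": rep.nse,
            "mbe_pct": rep.mbe_pct,
            "n": rep.n,
        }

    return YieldModel(
        crop=crop,
        slope=slope,
        intercept=intercept,
        validation=_diag(train),
        cross_validation=_diag(test) if test.size >= 2 else None,
    )


def predict_yield(model: YieldModel, savi: np.ndarray) -> np.ndarray:
    """Predicted yield grid (t/ha): linear model evaluation floored at 0."""
    savi = np.asarray(savi, dtype=float)
    out = np.full(savi.shape, NODATA, dtype=float)
    valid = savi != NODATA
    out[valid] = np.maximum(model.slope * savi[valid] + model.intercept, 0.0)
    return out


def wf_rs_blue(
    et_lgp_mm: np.ndarray,
    yield_grid_t_ha: np.ndarray,
    convention: str = "equation",
    yield_floor_t_ha: float = 1.0,
) -> np.ndarray:
    """Per-pixel blue water footprint (m^3/t) from seasonal ET and yield.

    Seasonal ET depth converts to a volume per area under the chosen
    convention and is divided by predicted yield. Pixels whose yield falls
    below ``yield_floor_t_ha`` (field borders, bare patches) become nodata
    rather than generating unbounded footprints.
    """
    et_lgp_mm = np.asarray(et_lgp_mm, dtype=float)
    yield_grid_t_ha = np.asarray(yield_grid_t_ha, dtype=float)
    if et_lgp_mm.shape != yield_grid_t_ha.shape:
        raise ValueError("ET and yield grids must be aligned")
    try:
        factor = VOLUME_FACTORS[convention]
    except KeyError:
        raise ValueError(f"unknown unit convention {convention!r}") from None
    out = np.full(et_lgp_mm.shape, NODATA, dtype=float)
    valid = (
        (et_lgp_mm != NODATA)
        & (yield_grid_t_ha != NODATA)
        & (yield_grid_t_ha >= yield_floor_t_ha)
    )
    out[valid] = et_lgp_mm[valid] * factor / yield_grid_t_ha[valid]
    return out
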