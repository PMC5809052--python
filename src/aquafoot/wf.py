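"""Green/blue/grey water-footprint accounting per field.

Partitions daily crop evapotranspiration into a green (rain-fed) and a blue
(irrigation-fed) component, accumulates them into seasonal crop water use
(CWU, volume per area), converts a leached nitrogen load into grey
assimilation water use (AWU), and divides by yield to obtain the water
footprint (WF) of the harvest in m^3 per tonne.

Two volume conventions are supported. The physically standard conversion of
a water depth over an area is 10 m^3/ha per mm (``convention="equation"``,
the default). A second mode, ``convention="table"``, applies a factor of
100 m^3/ha per mm; it exists solely to reproduce published field-study
tabulations whose WF columns reconcile only under that factor, and every
result carries an explicit flag saying which convention produced it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GreyParams",
    "WFResult",
    "VOLUME_FACTORS",
    "partition_daily_et",
    "accumulate_cwu",
    "grey_load",
    "awu_grey",
    "wf_components",
    "aggregate_report",
]

#: m^3/ha contributed by 1 mm of depth, per unit convention.
VOLUME_FACTORS = {"equation": 10.0, "table": 100.0}


@dataclass(frozen=True)
class GreyParams:
    """Grey-water parameters for a single pollutant (nitrate).

    alpha is the flat-rate fraction of the applied nitrogen assumed to leach
    below the root zone; c_max the ambient water-quality standard and c_nat
    the natural background concentration of the receiving water body.
    """

    alpha: float = 0.10
    c_max_mg_l: float = 11.5
    c_nat_mg_l: float = 0.0
    ar_kg_ha: float = 125.0  # nitrogen application rate

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("leaching fraction alpha must lie in [0, 1]")
        if self.c_max_mg_l <= self.c_nat_mg_l:
            raise ValueError("c_max must exceed c_nat")
        if self.ar_kg_ha < 0:
            raise ValueError("application rate must be >= 0")


@dataclass
class WFResult:
    """Water-footprint components of one field's harvest.

    Volumes per area are in m^3/ha with companion depths in mm; WF
    components in m^3 per tonne of yield. ``convention`` records the
    depth-to-volume factor used (see module docstring).
    """

    field_id: str
    crop: str
    yield_t_ha: float
    cwu_green_m3_ha: float
    cwu_blue_m3_ha: float
    awu_grey_m3_ha: float
    depth_green_mm: float
    depth_blue_mm: float
    depth_grey_mm: float
    wf_green: float
    wf_blue: float
    wf_grey: float
    wf_total: float
    convention: str

    def __post_init__(self) -> None:
        assert abs(self.wf_total - (self.wf_green + self.wf_blue + self.wf_grey)) < 1e-9


def partition_daily_et(etc_mm: float, p_eff_mm: float) -> tuple[float, float]:
    """Split one day's crop ET into (green, blue) components.

    ET_green = min(ETc, P_eff) — rain supplies demand first;
    ET_blue  = max(0, ETc - P_eff) — irrigation covers the remainder.
    The two sum to ETc whenever rain does not exceed demand.
    """
    if etc_mm < 0 or p_eff_mm < 0:
        raise ValueError("ETc and P_eff must be >= 0")
    green = min(etc_mm, p_eff_mm)
    blue = max(0.0, etc_mm - p_eff_mm)
    return green, blue


def accumulate_cwu(
    et_green_mm, et_blue_mm, convention: str = "equation"
) -> dict[str, float]:
    """Seasonal green/blue crop water use from daily ET components.

    Returns depths (mm, the plain sums) and volumes per area (m^3/ha) under
    the chosen convention.
    """
    factor = _volume_factor(convention)
    depth_green = float(np.sum(np.asarray(et_green_mm, dtype=float)))
    depth_blue = float(np.sum(np.asarray(et_blue_mm, dtype=float)))
    if depth_green < 0 or depth_blue < 0:
        raise ValueError("ET component sums must be >= 0")
    return {
        "depth_green_mm": depth_green,
        "depth_blue_mm": depth_blue,
        "cwu_green_m3_ha": depth_green * factor,
        "cwu_blue_m3_ha": depth_blue * factor,
    }


def _volume_factor(convention: str) -> float:
    try:
        return VOLUME_FACTORS[convention]
    except KeyError:
        raise ValueError(
            f"unknown unit convention {convention!r}; expected one of {sorted(VOLUME_FACTORS)}"
        ) from None


def grey_load(params: GreyParams) -> float:
    """Leached pollutant load L = alpha * AR (kg/ha)."""
    return params.alpha * params.ar_kg_ha


def awu_grey(l_leached_kg_ha: float, params: GreyParams) -> float:
    """Grey assimilation water use (m^3/ha) diluting a leached load.

    Dimensionally: L [kg/ha] = 1e6 L [mg/ha]; dividing by the allowable
    concentration increment (c_max - c_nat) [mg/l] gives litres/ha, and
    1e-3 m^3/l yields AWU = 1000 * L / (c_max - c_nat) m^3/ha.
    """
    if l_leached_kg_ha < 0:
        raise ValueError("leached load must be >= 0")
    return 1000.0 * l_leached_kg_ha / (params.c_max_mg_l - params.c_nat_mg_l)


def wf_components(
    field_id: str,
    crop: str,
    yield_t_ha: float,
    cwu_green_m3_ha: float,
    cwu_blue_m3_ha: float,
    awu_grey_m3_ha: float,
    convention: str = "equation",
) -> WFResult:
    """Water footprint of a harvest: each component volume divided by yield.

    WF_x = CWU_x / Y (m^3/t); WF_total is their sum. The volumes are taken
    as already being in the stated convention; the factor only back-fills the
    companion depths.
    """
    if yield_t_ha <= 0:
        raise ValueError("yield must be positive")
    for v in (cwu_green_m3_ha, cwu_blue_m3_ha, awu_grey_m3_ha):
        if v < 0:
            raise ValueError("water-use volumes must be >= 0")
    factor = _volume_factor(convention)
    wf_g = cwu_green_m3_ha / yield_t_ha
    wf_b = cwu_blue_m3_ha / yield_t_ha
    wf_gr = awu_grey_m3_ha / yield_t_ha
    return WFResult(
        field_id=field_id,
        crop=crop,
        yield_t_ha=yield_t_ha,
        cwu_green_m3_ha=cwu_green_m3_ha,
        cwu_blue_m3_ha=cwu_blue_m3_ha,
        awu_grey_m3_ha=awu_grey_m3_ha,
        depth_green_mm=cwu_green_m3_ha / factor,
        depth_blue_mm=cwu_blue_m3_ha / factor,
        depth_grey_mm=awu_grey_m3_ha / factor,
        wf_green=wf_g,
        wf_blue=wf_b,
        wf_grey=wf_gr,
        wf_total=wf_g + wf_b + wf_gr,
        convention=convention,
    )


def aggregate_report(results: list[WFResult]) -> pd.DataFrame:
    """Per-crop arithmetic means of WF components with percentage shares.

    The share of a component is its mean divided by the mean total, in
    percent (2-decimal precision is left to presentation). One row per crop.
    """
    if not results:
        raise ValueError("need at least one field result")
    frame = pd.DataFrame(
        {
            "crop": [r.crop for r in results],
            "yield_t_ha": [r.yield_t_ha for r in results],
            "wf_green": [r.wf_green for r in results],
            "wf_blue": [r.wf_blue for r in results],
            "wf_grey": [r.wf_grey for r in results],
            "wf_total": [r.wf_total for r in results],
        }
    )
    means = frame.groupby("crop", sort=False).mean()
    means["n_fields"] = frame.groupby("crop", sort=False).size()
    for comp in ("green", "blue", "grey"):
        means[f"share_{comp}_pct"] = 100.0 * means[f"wf_{comp}"] / means["wf_total"]
    return means.reset_index()
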