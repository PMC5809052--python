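"""Agreement statistics between paired estimates (two WF branches, yield models).

Standard definitions: R2 is the squared Pearson correlation; RMSE the root
mean squared difference; MBE the mean signed difference with the fixed sign
convention predicted - observed; NSE the Nash-Sutcliffe efficiency
1 - SSE/SST, i.e. skill relative to predicting the observed mean.
Percentage forms normalise by the observed mean. The regression p-value is
the F-test of the simple linear regression of predicted on observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EvalReport", "compare_estimates", "paired_report_table"]


@dataclass(frozen=True)
class EvalReport:
    n: int
    r2: float
    rmse: float
    rmse_pct: float
    mbe: float
    mbe_pct: float
    nse: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "n": self.n, "r2": self.r2, "rmse": self.rmse, "rmse_pct": self.rmse_pct,
            "mbe": self.mbe, "mbe_pct": self.mbe_pct, "nse": self.nse,
            "p_value": self.p_value,
        }


def compare_estimates(observed, predicted) -> EvalReport:
    """Full agreement report between an observed and a predicted series.

    Raises if fewer than 2 pairs or if the observed series is constant
    (R2 and NSE are then undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.ptp(obs) == 0:
        raise ValueError("observed series is constant: R2/NSE undefined")

    diff = pred - obs
    rmse = float(np.sqrt(np.mean(diff**2)))
    mbe = float(np.mean(diff))
    obs_mean = float(np.mean(obs))
    sst = float(np.sum((obs - obs_mean) ** 2))
    nse = 1.0 - float(np.sum(diff**2)) / sst

    lin = stats.linregress(obs, pred)
    r2 = float(lin.rvalue**2)

    scale = 100.0 / obs_mean if obs_mean != 0 else float("nan")
    return EvalReport(
        n=int(obs.size),
        r2=r2,
        rmse=rmse,
        rmse_pct=rmse * scale,
        mbe=mbe,
        mbe_pct=mbe * scale,
        nse=nse,
        p_value=float(lin.pvalue),
    )


def paired_report_table(
    agro: pd.DataFrame, rs: pd.DataFrame, value_col_agro: str = "wf_blue",
    value_col_rs: str = "wf_rs_blue",
) -> tuple[pd.DataFrame, dict[str, EvalReport | None]]:
    """Field-by-field comparison of the two blue-WF branches.

    Both inputs need ``field_id`` and ``crop`` columns plus their value
    column. Returns one row per field with both estimates and their
    difference, and a per-crop dict of agreement reports (None where a crop
    has fewer than 2 paired fields, in which case the stats are undefined).
    Disjoint field_id sets are an error.
    """
    for frame, col in ((agro, value_col_agro), (rs, value_col_rs)):
        missing = {"field_id", "crop", col} - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
    merged = agro[["field_id", "crop", value_col_agro]].merge(
        rs[["field_id", value_col_rs]], on="field_id", how="inner"
    )
    if merged.empty:
        raise ValueError("no matching field_ids between the two branches")
    merged["difference"] = merged[value_col_rs] - merged[value_col_agro]

    reports: dict[str, EvalReport | None] = {}
    for crop, grp in merged.groupby("crop", sort=False):
        if len(grp) >= 2 and np.ptp(grp[value_col_agro].to_numpy()) > 0:
            reports[crop] = compare_estimates(grp[value_col_agro], grp[value_col_rs])
        else:
            reports[crop] = None
    return merged, reports
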