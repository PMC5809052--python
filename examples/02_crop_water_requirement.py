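"""Seasonal crop water requirement and salinity leaching for one maize field.

Uses the bundled reference records: the spring maize calendar, the staged
crop-coefficient profile, the monthly climatology (spread to daily reference
ET), and the field's soil/irrigation-water salinity.
"""

from datetime import timedelta

import numpy as np

from aquafoot import (
    SyntheticConfig,
    build_kc_curve,
    crop_et_series,
    generate_weather,
    gross_irrigation,
    leaching_depth,
    leaching_fraction,
)
from aquafoot.fixtures import kc_profile_for, load_table

seasons = load_table("crop_seasons").set_index("field_id")
salinity = load_table("field_salinity").set_index("field_id")
field = "PAL"
rec = seasons.loc[field]

weather = {r.date: r for r in generate_weather(SyntheticConfig())}
season_days = [
    rec["sowing"] + timedelta(days=i)
    for i in range((rec["harvest"] - rec["sowing"]).days + 1)
]
eto = np.array([weather[d].eto_mm for d in season_days])
rain = np.array([weather[d].rain_mm for d in season_days])

kc = build_kc_curve(kc_profile_for(rec["crop"], rec["season"]), len(season_days))
series = crop_et_series(season_days, eto, kc, rain)

f = leaching_fraction(salinity.loc[field, "ecw_mean"], salinity.loc[field, "ece_shallow_mean"])
lr = leaching_depth(series.cwr_mm, f)

print(f"{field} ({rec['crop']}, {rec['season']}): {len(season_days)}-day season")
print(f"  crop water requirement : {series.cwr_mm:7.0f} mm")
print(f"  leaching fraction      : {f:7.3f}")
print(f"  leaching requirement   : {lr:7.0f} mm")
print(f"  gross irrigation @70%  : {gross_irrigation(series.cwr_mm + lr):7.0f} mm")

lr_record = leaching_depth(float(rec["cwr_mm"]), f)
print(f"  at the recorded CWR of {rec['cwr_mm']} mm the same fraction gives "
      f"LR = {lr_record:.0f} mm (field record: {rec['lr_mm']} mm)")

# CWR is the season's sum of Kc-weighted reference ET; the extra leaching
# depth flushes salts so the root-zone salinity stays below the crop's
# tolerance, and the 70% sprinkler efficiency inflates both into the gross
# application the pivot must actually deliver. The synthetic climatology
# spreads monthly ETo uniformly, so its CWR sits below the field record
# computed from daily weather; the leaching arithmetic itself reproduces
# the recorded depth exactly when fed the recorded CWR.
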