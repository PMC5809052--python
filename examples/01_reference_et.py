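"""Daily grass-reference evapotranspiration from one day of weather forcing.

Builds a mid-summer arid-climate weather record and evaluates the
Penman-Monteith combination equation, then shows how wind drives the
aerodynamic term.
"""

from datetime import date

from aquafoot import MeteoRecord, penman_monteith_eto

record = MeteoRecord(
    date=date(2016, 7, 15),
    tmean_c=37.1, tmin_c=28.2, tmax_c=46.0,
    u2_ms=6.7,            # mean daily wind at 2 m
    rn_mj=22.0,           # net radiation, MJ/m^2/day
    es_kpa=6.39, ea_kpa=1.6,
)

eto = penman_monteith_eto(record, elevation_m=400.0)
print(f"ETo on {record.date}: {eto:.1f} mm/day")
for u2 in (0.0, 3.0, 6.7):
    calm = MeteoRecord(**{**record.__dict__, "u2_ms": u2})
    print(f"  wind {u2:>4.1f} m/s -> ETo {penman_monteith_eto(calm):.1f} mm/day")

# A hyper-arid summer day evaporates on the order of 15-20 mm of water from a
# well-watered reference surface; the wind sweep shows most of it is
# advective (vapour-pressure-deficit driven), not radiative.
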