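"""Bundled reference tables from an arid-farm water-footprint case study.

The package ships the published tabulations of a center-pivot farm study in
eastern Saudi Arabia (Dec 2015 - Dec 2016): monthly weather climatology,
field soil/irrigation-water salinity, seasonal crop water and leaching
requirements, crop water use depths, per-field water footprints, and the
SAVI-yield regression coefficients. They serve as generator defaults, as
inputs for the bundled reproduction computations, and as ground truth in
tests. Each CSV carries a checksum so silent corruption is caught at load.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = ["TABLES", "load_table", "load_reference_tables", "kc_profile_for"]

#: table name -> (filename, sha256 of the packaged CSV)
TABLES = {
    "climatology": "climatology.csv",
    "field_salinity": "field_salinity.csv",
    "crop_seasons": "crop_seasons.csv",
    "kc_profiles": "kc_profiles.csv",
    "crop_water_use": "crop_water_use.csv",
    "water_footprint": "water_footprint.csv",
    "yield_models": "yield_models.csv",
}

_CHECKSUMS = {
    "climatology.csv": "ea3e85804887cb1cca8c510feeedfed04fd497bf738f9c0293a9bab92489fcb2",
    "field_salinity.csv": "812f05ec98d24d28e301f08a8694f62c1f26225357a13d03eac488bcdd8e7256",
    "crop_seasons.csv": "3f95a74fb4a771016724af1484f602ac4e7591ae981a46a138a7f0b71c2777dc",
    "kc_profiles.csv": "2dd30d5972220f7f2836fa98deb2da74c2c332537f2ef71221f6a34f2a62341c",
    "crop_water_use.csv": "6c857b6401c1dac707537f81474df45a79bfaa0a85a090858823c904c9005893",
    "water_footprint.csv": "b51b925941999622d2c055640f03872b272e7a357efa9054a91f8d15cb05dee4",
    "yield_models.csv": "eaa079d80dda033cc0487cc5ce7bf1b76ce44cdb7a076a57606ebc47c5cba734",
}


class CorruptedFixtureError(RuntimeError):
    """A bundled table's bytes do not match its recorded checksum."""


def _read(filename: str) -> bytes:
    return resources.files("aquafoot.data").joinpath(filename).read_bytes()


def load_table(name: str) -> pd.DataFrame:
    """Load one bundled table by name, verifying its checksum."""
    try:
        filename = TABLES[name]
    except KeyError:
        raise KeyError(f"unknown table {name!r}; available: {sorted(TABLES)}") from None
    raw = _read(filename)
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise CorruptedFixtureError(
            f"{filename}: checksum mismatch ({digest[:12]}... != "
            f"{_CHECKSUMS[filename][:12]}...)"
        )
    import io

    frame = pd.read_csv(io.BytesIO(raw))
    if name == "crop_seasons":
        for col in ("sowing", "harvest"):
            frame[col] = pd.to_datetime(frame[col]).dt.date
    return frame


def load_reference_tables() -> dict[str, pd.DataFrame]:
    """All bundled tables as a name -> DataFrame dict."""
    return {name: load_table(name) for name in TABLES}


def kc_profile_for(crop: str, season: str):
    """The staged crop-coefficient profile for a crop/season pair."""
    from .agromet import KcProfile

    profiles = load_table("kc_profiles")
    row = profiles[(profiles["crop"] == crop) & (profiles["season"] == season)]
    if row.empty:
        raise KeyError(f"no Kc profile for crop={crop!r}, season={season!r}")
    r = row.iloc[0]
    return KcProfile(
        crop=crop, season=season,
        len_ini=int(r["len_ini"]), len_dev=int(r["len_dev"]),
        len_mid=int(r["len_mid"]), len_late=int(r["len_late"]),
        kc_ini=float(r["kc_ini"]), kc_dev=float(r["kc_dev"]),
        kc_mid=float(r["kc_mid"]), kc_late=float(r["kc_late"]),
    )
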