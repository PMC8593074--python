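"""Reading and writing the pipeline's tabular and raster artifacts.

Tracks and presence/absence tables travel as CSV; environmental stacks and
prediction maps as NetCDF (classic format via the SciPy backend); configs
as YAML.  The field-survey reference tables (tagging summary, haul-out
census totals) ship with the package as CSV.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import xarray as xr
import yaml

TRACK_DTYPES = {"individual_id": str, "location_class": str}


def read_tracks(path) -> pd.DataFrame:
    """Read an Argos-style track CSV (individual_id, timestamp ISO-8601,
    lon, lat, location_class, optional depth_m)."""
    df = pd.read_csv(path, dtype=TRACK_DTYPES, parse_dates=["timestamp"])
    return df.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(drop=True)


def write_tracks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def write_stack(stack: xr.Dataset, path) -> None:
    """Write a stack as NetCDF3 (no compression; bool land mask as int8)."""
    ds = stack.copy()
    if "land" in ds and ds["land"].dtype == bool:
        ds["land"] = ds["land"].astype("int8")
    ds.to_netcdf(path, engine="scipy")


def read_stack(path) -> xr.Dataset:
    ds = xr.load_dataset(path, engine="scipy")
    if "land" in ds:
        ds["land"] = ds["land"].astype(bool)
    return ds


def read_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def write_config(obj: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("sealhab").joinpath("data", name)))


def load_tagging_table() -> pd.DataFrame:
    """Deployment summary of the 15 satellite tags (id, morphometrics, tag
    type, deployment date, track duration, trip count and duration stats)."""
    return pd.read_csv(_data_path("tagging_table.csv"), dtype={"individual_id": str})


def load_haulout_totals() -> pd.DataFrame:
    """Total seals counted per haul-out across the two transect censuses."""
    return pd.read_csv(_data_path("haulout_totals.csv"))
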