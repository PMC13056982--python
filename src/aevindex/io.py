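"""Reading and writing gridded fields and tables.

Fields travel as CF-style NetCDF (classic format via the scipy engine)
with dims (member?, time, lat, lon), ``year``/``month`` integer time
coordinates, and a mandatory ``units`` attribute per variable.  Sea-ice
concentration is held internally as a fraction in [0, 1]; files storing
percent are normalised on read with a logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

log = logging.getLogger("aevindex")

REQUIRED_COORDS = ("lat", "lon", "year", "month")
PERCENT_UNITS = {"%", "percent", "Percent"}


class FormatError(ValueError):
    """A file does not match the expected layout."""


def write_fields(fields: dict[str, xr.DataArray], path: str | Path) -> None:
    """Write a set of fields as one classic-format NetCDF file."""
    ds = xr.Dataset({name: da for name, da in fields.items()})
    ds.to_netcdf(path, engine="scipy")


def read_fields(path: str | Path) -> dict[str, xr.DataArray]:
    """Read fields back, validating coordinates and unit attributes.

    Raises :class:`FormatError` naming any missing coordinate or units
    attribute.  SIC in percent units is converted to fraction.
    """
    ds = xr.load_dataset(path, engine="scipy")
    missing = [c for c in REQUIRED_COORDS if c not in ds.coords and c not in ds.variables]
    if missing:
        raise FormatError(f"missing coordinate variables: {missing}")
    out: dict[str, xr.DataArray] = {}
    for name, da in ds.data_vars.items():
        if "units" not in da.attrs:
            raise FormatError(f"variable {name!r} has no units attribute")
        if name.upper() == "SIC" and da.attrs["units"] in PERCENT_UNITS:
            log.warning("normalising SIC from percent to fraction")
            da = (da / 100.0).assign_attrs(units="1")
        out[name] = da
    return out


def write_colonies(colonies: pd.DataFrame, path: str | Path) -> None:
    colonies.to_csv(path, index=False)


def read_colonies(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"colony_id", "lat", "lon", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"colony table missing columns: {sorted(missing)}")
    return df


def write_mask(mask: np.ndarray, grid, path: str | Path, name: str = "mask") -> None:
    """Write a boolean mask as a CF-style byte field."""
    da = xr.DataArray(
        mask.astype("i1"),
        dims=("lat", "lon"),
        coords={"lat": grid.lat_centers, "lon": grid.lon_centers},
        name=name,
        attrs={"units": "1", "flag_values": "0, 1"},
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_mask(path: str | Path, name: str = "mask") -> np.ndarray:
    ds = xr.load_dataset(path, engine="scipy")
    return np.asarray(ds[name].values, dtype=bool)
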