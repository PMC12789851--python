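"""Gridded-array file I/O and the dimension-name conventions.

Fields travel as self-describing netCDF files (classic format via the scipy
backend, so float64 payloads round-trip bit for bit) with the fixed
dimension names (lat, lon, depth, time, state).  The ocean mask and cell
area weights are stored as the variables ``mask`` (int8) and
``area_weights`` alongside the data variables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import xarray as xr

from .diagnostics import GriddedField
from .exceptions import SchemaError

__all__ = ["write_grid", "read_grid", "require_dims", "field_to_dataset",
           "dataset_to_field", "DIM_ORDER"]

DIM_ORDER = ("lat", "lon", "depth", "time", "state", "population")


def require_dims(ds: xr.Dataset | xr.DataArray, *dims: str) -> None:
    """Raise SchemaError naming the first dimension absent from the object."""
    for d in dims:
        if d not in ds.dims:
            raise SchemaError(f"required dimension {d!r} is missing")


def _validate_dims(ds: xr.Dataset) -> None:
    unknown = set(ds.dims) - set(DIM_ORDER)
    if unknown:
        raise SchemaError(
            f"unknown dimensions {sorted(unknown)}; allowed: {DIM_ORDER}"
        )


def write_grid(ds: xr.Dataset, path: str | Path) -> None:
    """Write a dataset as a classic netCDF file."""
    _validate_dims(ds)
    ds.to_netcdf(path, engine="scipy")


def read_grid(path: str | Path, required_dims: tuple[str, ...] = ()) -> xr.Dataset:
    """Read a gridded-array file, checking the dimension-name convention."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    ds = xr.open_dataset(path, engine="scipy").load()
    _validate_dims(ds)
    require_dims(ds, *required_dims)
    return ds


def field_to_dataset(field: GriddedField, name: str = "field") -> xr.Dataset:
    """Bundle a GriddedField's data, mask and weights into one dataset."""
    ds = xr.Dataset({name: field.data})
    ds["mask"] = field.mask.astype(np.int8)
    ds["area_weights"] = field.area_weights
    return ds


def dataset_to_field(ds: xr.Dataset, name: str | None = None) -> GriddedField:
    """Rebuild a GriddedField from a dataset written by field_to_dataset.

    Without an explicit variable name, the single non-mask/weights data
    variable is used.
    """
    reserved = {"mask", "area_weights"}
    if name is None:
        candidates = [v for v in ds.data_vars if v not in reserved]
        if len(candidates) != 1:
            raise SchemaError(
                f"cannot infer the data variable among {sorted(ds.data_vars)}"
            )
        name = candidates[0]
    if name not in ds:
        raise SchemaError(f"variable {name!r} not in file")
    mask = ds["mask"].astype(bool) if "mask" in ds else None
    weights = ds["area_weights"] if "area_weights" in ds else None
    return GriddedField(ds[name], mask, weights)
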