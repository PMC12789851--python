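"""Ocean-color and pigment-diversity diagnostics on gridded fields.

The pipeline: monthly blue-to-green irradiance ratio (B/G = E495/E545)
averaged over the top 200 m, decadal (120-month) means, the mean annual
variance of the monthly B/G, five-class Fisher-Jenks classification with
area-weighted class-transition accounting, and the acclimation index (the
per-cell sum over depth and month of the number of chromatic-acclimator
states present, min-max normalized to a baseline decade).

All "% of ocean area" statistics are area-weighted (cosine-of-latitude
weights by default) over unmasked cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import xarray as xr

from .exceptions import (
    DegenerateNormalizationError,
    IncompatibleGridError,
    InvalidParameterError,
    MissingWindowError,
)
from .jenks import fisher_jenks_breaks

__all__ = [
    "GriddedField",
    "ClassMap",
    "AcclimationIndexField",
    "TransitionSummary",
    "cosine_area_weights",
    "bg_ratio",
    "decadal_mean",
    "annual_variance",
    "classify",
    "transition_fractions",
    "acclimation_index",
    "normalize_index",
    "fisher_jenks_breaks",
]

logger = logging.getLogger(__name__)


def cosine_area_weights(lat: np.ndarray, lon: np.ndarray) -> xr.DataArray:
    """Relative cell-area weights on a regular lat-lon grid: cos(latitude)."""
    w = np.cos(np.deg2rad(np.asarray(lat, float)))
    w = np.clip(w, 0.0, None)
    return xr.DataArray(
        np.repeat(w[:, None], len(lon), axis=1),
        dims=("lat", "lon"),
        coords={"lat": lat, "lon": lon},
    )


@dataclass
class GriddedField:
    """A lat-lon(-depth-time) array plus ocean mask and cell-area weights."""

    data: xr.DataArray  # dims include (lat, lon)
    mask: xr.DataArray | None = None  # bool over (lat, lon); True = ocean
    area_weights: xr.DataArray | None = None  # over (lat, lon)

    def __post_init__(self) -> None:
        if "lat" not in self.data.dims or "lon" not in self.data.dims:
            raise IncompatibleGridError("gridded field needs lat and lon dims")
        if self.mask is None:
            self.mask = xr.ones_like(
                self.data.isel({d: 0 for d in self.data.dims if d not in ("lat", "lon")}),
                dtype=bool,
            )
        if self.area_weights is None:
            self.area_weights = cosine_area_weights(
                self.data["lat"].values, self.data["lon"].values
            )
        w = self.area_weights
        if np.any(~np.isfinite(w.values)) or np.any(w.values < 0):
            raise InvalidParameterError("area weights must be finite and >= 0")

    def with_data(self, data: xr.DataArray) -> "GriddedField":
        return GriddedField(data, self.mask, self.area_weights)

    def unmasked(self) -> np.ndarray:
        """Flattened values of ocean cells (2-D fields only)."""
        return self.data.values[self.mask.values]

    def weighted_fraction(self, condition: np.ndarray) -> float:
        """Area fraction of unmasked cells satisfying a boolean condition."""
        w = self.area_weights.values
        m = self.mask.values
        return float(np.sum(w[m & condition]) / np.sum(w[m]))


@dataclass
class ClassMap:
    """Per-cell Fisher-Jenks class labels plus the defining break values."""

    labels: xr.DataArray  # int, 1..k over (lat, lon)
    breaks: np.ndarray  # k-1 ascending values
    k: int

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, float)
        if self.breaks.size != self.k - 1 or np.any(np.diff(self.breaks) <= 0):
            raise InvalidParameterError("need k-1 strictly ascending breaks")


@dataclass
class TransitionSummary:
    """Area-weighted class-transition accounting between two epochs."""

    unchanged: float
    to_higher: float
    to_lower: float
    matrix: np.ndarray  # (k, k) weighted fractions, rows = epoch-0 class


@dataclass
class AcclimationIndexField:
    """Raw (summed present-state counts) and normalized acclimation index."""

    raw: GriddedField
    normalized: GriddedField | None = None
    baseline_min: float | None = None
    baseline_max: float | None = None


def _layer_thickness(depth: np.ndarray) -> np.ndarray:
    """Layer thickness from midpoints: bounds halfway between neighbors,
    the top bound at 0 and the bottom bound extrapolated symmetrically."""
    depth = np.asarray(depth, float)
    if depth.size == 1:
        return np.array([1.0])
    edges = np.concatenate([[0.0], 0.5 * (depth[1:] + depth[:-1]),
                            [depth[-1] + 0.5 * (depth[-1] - depth[-2])]])
    return np.diff(edges)


def bg_ratio(
    e495: GriddedField,
    e545: GriddedField,
    max_depth: float = 200.0,
    mode: str = "mean_of_ratio",
) -> GriddedField:
    """Blue-to-green irradiance ratio E495/E545.

    With a depth dimension present, the default is the thickness-weighted
    mean over layers shallower than ``max_depth`` of the per-layer ratio
    (``mode="mean_of_ratio"``); ``mode="ratio_of_mean"`` instead divides the
    depth-averaged irradiances.  Cells with non-positive E545 are masked out
    of the result (their count is logged).
    """
    if e495.data.dims != e545.data.dims or e495.data.shape != e545.data.shape:
        raise IncompatibleGridError("E495 and E545 must share dims and shape")
    if mode not in ("mean_of_ratio", "ratio_of_mean"):
        raise InvalidParameterError(f"unknown B/G mode {mode!r}")

    a, b = e495.data, e545.data
    if "depth" in a.dims:
        depth = a["depth"].values
        keep = depth <= max_depth
        thick = xr.DataArray(_layer_thickness(depth)[keep],
                             dims=("depth",), coords={"depth": depth[keep]})
        a = a.sel(depth=depth[keep])
        b = b.sel(depth=depth[keep])
        if mode == "mean_of_ratio":
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = (a / b).weighted(thick).mean("depth")
        else:
            ratio = a.weighted(thick).mean("depth") / b.weighted(thick).mean("depth")
        bad_src = (b <= 0).any("depth")
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = a / b
        bad_src = b <= 0

    bad = bad_src
    for d in bad.dims:
        if d not in ("lat", "lon"):
            bad = bad.any(d)
    mask = e495.mask & ~bad
    n_bad = int((e495.mask & bad).sum())
    if n_bad:
        logger.warning("bg_ratio: masked %d cells with non-positive E545", n_bad)
        ratio = ratio.where(~bad)
    return GriddedField(ratio, mask, e495.area_weights)


def _window_slice(series: xr.DataArray, nominal_year: float) -> xr.DataArray:
    if "year" not in series.coords:
        raise MissingWindowError("series needs a fractional 'year' coordinate on time")
    year = series["year"]
    win = series.where((year >= nominal_year - 5) & (year < nominal_year + 5), drop=True)
    n = win.sizes.get("time", 0)
    if n != 120:
        have = set(np.floor(win["year"].values).astype(int)) if n else set()
        want = set(range(int(nominal_year) - 5, int(nominal_year) + 5))
        raise MissingWindowError(
            f"decadal window [{nominal_year - 5}, {nominal_year + 5}) has {n} months, "
            f"needs 120; missing years: {sorted(want - have)}"
        )
    return win


def decadal_mean(series: GriddedField, nominal_year: float) -> GriddedField:
    """Per-cell mean over the 120 months [nominal-5, nominal+5)."""
    win = _window_slice(series.data, nominal_year)
    return series.with_data(win.mean("time"))


def annual_variance(series: GriddedField, nominal_year: float) -> GriddedField:
    """Mean over the window's 10 years of each year's population variance
    (ddof=0) of the 12 monthly values."""
    win = _window_slice(series.data, nominal_year)
    years = np.floor(win["year"].values).astype(int)
    out = None
    for y in np.unique(years):
        v = win.isel(time=np.nonzero(years == y)[0]).var("time", ddof=0)
        out = v if out is None else out + v
    return series.with_data(out / np.unique(years).size)


def classify(field: GriddedField, breaks: np.ndarray) -> ClassMap:
    """Assign each cell the 1-based class of its value given ascending breaks
    (value <= breaks[0] -> class 1, ..., value > breaks[-1] -> class k)."""
    breaks = np.asarray(breaks, float)
    labels = np.searchsorted(breaks, field.data.values, side="left") + 1
    da = xr.DataArray(labels, dims=field.data.dims, coords=field.data.coords)
    return ClassMap(da.where(field.mask, 0).astype(int), breaks, k=breaks.size + 1)


def transition_fractions(
    class_t0: ClassMap,
    class_t1: ClassMap,
    mask: xr.DataArray,
    weights: xr.DataArray,
) -> TransitionSummary:
    """Area-weighted fractions of ocean cells that kept, raised or lowered
    their class between epochs, plus the full k x k transition matrix."""
    if class_t0.k != class_t1.k:
        raise IncompatibleGridError("class maps have different k")
    if class_t0.labels.shape != class_t1.labels.shape:
        raise IncompatibleGridError("class maps on different grids")
    k = class_t0.k
    c0 = class_t0.labels.values
    c1 = class_t1.labels.values
    m = mask.values
    w = weights.values
    total = float(np.sum(w[m]))
    if total == 0:
        raise InvalidParameterError("no unmasked area")
    matrix = np.zeros((k, k))
    for i in range(1, k + 1):
        for j in range(1, k + 1):
            matrix[i - 1, j - 1] = np.sum(w[m & (c0 == i) & (c1 == j)]) / total
    return TransitionSummary(
        unchanged=float(np.trace(matrix)),
        to_higher=float(np.sum(np.triu(matrix, 1))),
        to_lower=float(np.sum(np.tril(matrix, -1))),
        matrix=matrix,
    )


def acclimation_index(
    ca_biomass: GriddedField, presence_threshold: float = 0.05
) -> AcclimationIndexField:
    """Raw acclimation index: per cell, the sum over depth and month of the
    number of CA states whose biomass is at least ``presence_threshold`` of
    the local total CA biomass (zero-biomass cells contribute nothing).
    """
    if not 0.0 < presence_threshold < 1.0:
        raise InvalidParameterError("presence threshold must be in (0, 1)")
    da = ca_biomass.data
    for d in ("state", "depth", "time"):
        if d not in da.dims:
            raise IncompatibleGridError(f"CA biomass field lacks dim {d!r}")
    total = da.sum("state")
    present = (da >= presence_threshold * total) & (total > 0)
    raw = present.sum(("state", "depth", "time"))
    n_empty = int(((total == 0).all(("depth", "time")) & ca_biomass.mask).sum())
    if n_empty:
        logger.info("acclimation_index: %d ocean cells have no CA biomass", n_empty)
    return AcclimationIndexField(raw=ca_biomass.with_data(raw))


def normalize_index(
    raw: AcclimationIndexField, baseline: AcclimationIndexField
) -> AcclimationIndexField:
    """Min-max rescale a raw index by the baseline epoch's range.

    The baseline field maps into [0, 1]; other epochs use the same affine map
    unclamped, so values outside [0, 1] flag change beyond the baseline range.
    """
    base = baseline.raw.unmasked()
    lo, hi = float(np.min(base)), float(np.max(base))
    if lo == hi:
        raise DegenerateNormalizationError("baseline index has zero range")
    norm = (raw.raw.data - lo) / (hi - lo)
    return AcclimationIndexField(
        raw=raw.raw,
        normalized=raw.raw.with_data(norm),
        baseline_min=lo,
        baseline_max=hi,
    )
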