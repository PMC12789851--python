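"""Synthetic gridded fields and paired forcing scenarios.

Everything the diagnostics pipeline consumes can be generated here with
known ground truth: monthly blue (495 nm) and green (545 nm) irradiance
fields with prescribed per-cell trend signs and seasonal-variance changes,
chromatic-acclimator state fields with prescribed present-state counts,
mean fields with prescribed Fisher-Jenks class transitions, change fields
with a prescribed 2x2 sign table, and baseline/future forcing pairs for the
water-column model (the future surrogate reduces nutrient supply and scales
the seasonal amplitude of the surface color cycle).

Each generator returns its bookkeeping (the exact truth it embedded) next to
the data, so pipeline recoveries are exact-expectation checks when noise is
off.  All randomness flows from one seed through numpy's default PCG64
generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import xarray as xr

from .diagnostics import GriddedField
from .exceptions import InvalidParameterError
from .watercolumn import Forcing, seasonal_surface_spectrum

__all__ = [
    "SyntheticSpec",
    "make_bg_fields",
    "make_ca_state_fields",
    "make_class_transition_fields",
    "make_sign_fields",
    "make_scenarios",
]


@dataclass
class SyntheticSpec:
    """Shape and structure of the synthetic global-like fields.

    fraction_bluer      share of ocean cells given a positive B/G trend
    fraction_var_down   share of cells whose seasonal B/G variance shrinks
    trend_magnitude     relative change of the mean B/G between epochs
    seasonal_amplitude  seasonal B/G half-range as a fraction of the mean
    noise_sd            s.d. of independent monthly noise on log-irradiance
    """

    n_lat: int = 36
    n_lon: int = 72
    n_depth: int = 5
    n_month: int = 120
    fraction_bluer: float = 0.76
    fraction_var_down: float = 0.64
    trend_magnitude: float = 0.2
    seasonal_amplitude: float = 0.15
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.fraction_bluer, self.fraction_var_down):
            if not 0.0 <= f <= 1.0:
                raise InvalidParameterError("fractions must be in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.n_month % 12:
            raise InvalidParameterError("n_month must be whole years")

    @property
    def grid_shape(self) -> tuple[int, int, int, int]:
        return (self.n_lat, self.n_lon, self.n_depth, self.n_month)

    def coords(self) -> dict[str, np.ndarray]:
        return {
            "lat": np.linspace(-90, 90, self.n_lat + 2)[1:-1],
            "lon": np.linspace(0, 360, self.n_lon, endpoint=False),
            "depth": 20.0 * (np.arange(self.n_depth) + 0.5),
        }


def _assign_signs(rng: np.random.Generator, n_cells: int, fraction_pos: float):
    """Random cell partition with round(fraction * n) positive cells."""
    n_pos = int(round(fraction_pos * n_cells))
    signs = np.full(n_cells, -1.0)
    signs[:n_pos] = 1.0
    rng.shuffle(signs)
    return signs, n_pos / n_cells


def make_bg_fields(
    spec: SyntheticSpec,
) -> tuple[xr.Dataset, xr.Dataset, dict[str, Any]]:
    """Two epochs of monthly (E495, E545) fields with prescribed structure.

    Per cell: a baseline mean B/G, a trend sign (positive in
    ``fraction_bluer`` of cells, magnitude ``trend_magnitude``), and a
    sinusoidal seasonal cycle whose amplitude is halved in
    ``fraction_var_down`` of cells by epoch 2 and increased by half
    elsewhere.  E545 is constant in time so the B/G carries the structure;
    both irradiances get independent lognormal monthly noise of s.d.
    ``noise_sd``.  Epoch time axes are centered on nominal years 2000 and
    2100.  Returns (epoch-2000 dataset, epoch-2100 dataset, truth dict).
    """
    rng = np.random.default_rng(spec.seed)
    nlat, nlon, nz, nt = spec.grid_shape
    ncell = nlat * nlon

    base_bg = rng.uniform(0.6, 1.8, size=ncell)
    trend_sign, got_bluer = _assign_signs(rng, ncell, spec.fraction_bluer)
    var_sign, got_down = _assign_signs(rng, ncell, spec.fraction_var_down)
    amp0 = spec.seasonal_amplitude * base_bg
    amp1 = amp0 * np.where(var_sign > 0, 0.5, 1.5)  # var_sign>0 means variance down
    bg1 = base_bg * (1.0 + trend_sign * spec.trend_magnitude)

    coords = spec.coords()
    month_phase = np.sin(2.0 * np.pi * (np.arange(nt) % 12) / 12.0)
    e545_level = 10.0 * np.exp(-coords["depth"] / 60.0)  # umol m-2 s-1 nm-1

    def epoch(mean_bg, amp, first_year):
        bg = mean_bg[None, :] + amp[None, :] * month_phase[:, None]  # (t, cell)
        bg = np.clip(bg, 0.05, None)
        e545 = np.broadcast_to(
            e545_level[None, None, :], (nt, ncell, nz)
        ).copy()
        e495 = bg[:, :, None] * e545
        if spec.noise_sd > 0:
            e495 *= np.exp(spec.noise_sd * rng.standard_normal(e495.shape))
            e545 *= np.exp(spec.noise_sd * rng.standard_normal(e545.shape))
        shape4 = (nt, nlat, nlon, nz)
        years = first_year + np.arange(nt) / 12.0 + 1.0 / 24.0
        ds = xr.Dataset(
            {
                "E495": (("time", "lat", "lon", "depth"), e495.reshape(shape4)),
                "E545": (("time", "lat", "lon", "depth"), e545.reshape(shape4)),
            },
            coords={**coords, "time": np.arange(nt), "year": ("time", years)},
        )
        return ds

    ds0 = epoch(base_bg, amp0, 2000 - spec.n_month / 24.0)
    ds1 = epoch(bg1, amp1, 2100 - spec.n_month / 24.0)
    truth = {
        "trend_sign": trend_sign.reshape(nlat, nlon),
        "var_change_sign": -var_sign.reshape(nlat, nlon),  # + means variance up
        "achieved_fraction_bluer": got_bluer,
        "achieved_fraction_var_down": got_down,
        "mean_bg_2000": base_bg.reshape(nlat, nlon),
        "mean_bg_2100": bg1.reshape(nlat, nlon),
    }
    return ds0, ds1, truth


def make_ca_state_fields(
    spec: SyntheticSpec,
    n_states: int = 6,
    counts: np.ndarray | None = None,
    presence_threshold: float = 0.05,
) -> tuple[GriddedField, dict[str, Any]]:
    """CA biomass over (lat, lon, depth, time, state) with prescribed
    present-state counts.

    ``counts`` (broadcastable to (lat, lon, depth, time), values 1..n_states)
    prescribes how many states are present at each depth and month; absent
    states get zero biomass and present states equal shares, so the raw
    acclimation index recovers ``counts.sum(over depth and time)`` exactly
    for any threshold below 1/n_states.
    """
    rng = np.random.default_rng(spec.seed + 1)
    nlat, nlon, nz, nt = spec.grid_shape
    if counts is None:
        counts = rng.integers(1, n_states + 1, size=(nlat, nlon, nz, nt))
    counts = np.broadcast_to(np.asarray(counts, int), (nlat, nlon, nz, nt))
    if counts.min() < 1 or counts.max() > n_states:
        raise InvalidParameterError(f"counts must lie in 1..{n_states}")
    if presence_threshold >= 1.0 / n_states:
        raise InvalidParameterError(
            "presence_threshold must be below 1/n_states for exact recovery"
        )
    state_idx = np.arange(n_states)
    present = state_idx[None, None, None, None, :] < counts[..., None]
    biomass = present / counts[..., None]  # equal shares summing to 1
    coords = spec.coords()
    da = xr.DataArray(
        biomass,
        dims=("lat", "lon", "depth", "time", "state"),
        coords={**coords, "time": np.arange(nt), "state": state_idx + 1},
    )
    truth = {"counts": counts, "raw_index": counts.sum(axis=(2, 3))}
    return GriddedField(da), truth


def make_class_transition_fields(
    spec: SyntheticSpec,
    k: int = 5,
    fraction_higher: float = 0.27,
    fraction_lower: float = 0.08,
    jitter: float = 0.01,
) -> tuple[GriddedField, GriddedField, dict[str, Any]]:
    """Two epoch-mean fields with prescribed class-transition fractions.

    Cells sit at k well-separated levels (within-class jitter much smaller
    than the gaps, so Fisher-Jenks recovers the classes); between epochs a
    ``fraction_higher`` share of cells moves up one class and
    ``fraction_lower`` moves down one (cells in the top/bottom class are
    never asked to move out of range).  Weights are uniform so cell
    fractions equal area fractions exactly.
    """
    if fraction_higher + fraction_lower > 1:
        raise InvalidParameterError("transition fractions exceed 1")
    rng = np.random.default_rng(spec.seed + 2)
    nlat, nlon = spec.n_lat, spec.n_lon
    ncell = nlat * nlon
    levels = 1.0 + 2.0 * np.arange(k)  # gaps of 2 >> jitter

    cls0 = rng.integers(0, k, size=ncell)
    if np.unique(cls0).size < k:
        raise InvalidParameterError("grid too small to populate every class")
    move = np.zeros(ncell, int)
    n_up = int(round(fraction_higher * ncell))
    n_dn = int(round(fraction_lower * ncell))
    movable_up = np.nonzero(cls0 < k - 1)[0]
    movable_dn = np.nonzero(cls0 > 0)[0]
    if movable_up.size < n_up or movable_dn.size < n_dn + n_up:
        raise InvalidParameterError("grid too small for requested fractions")
    up_cells = rng.choice(movable_up, size=n_up, replace=False)
    move[up_cells] = 1
    remaining = np.setdiff1d(movable_dn, up_cells)
    dn_cells = rng.choice(remaining, size=n_dn, replace=False)
    move[dn_cells] = -1
    cls1 = cls0 + move

    def field_of(cls, sentinel: bool):
        # jitter stays strictly below the per-class sentinel maximum, so the
        # Fisher-Jenks breaks fitted on the epoch-0 field (class maxima =
        # level + jitter) bound both epochs' values exactly
        vals = levels[cls] + jitter * rng.uniform(0.0, 0.5, size=ncell)
        if sentinel:
            for c in range(k):
                vals[np.nonzero(cls == c)[0][0]] = levels[c] + jitter
        return vals

    coords = spec.coords()
    uniform_w = xr.DataArray(
        np.ones((nlat, nlon)), dims=("lat", "lon"),
        coords={"lat": coords["lat"], "lon": coords["lon"]},
    )

    def wrap(vals):
        da = xr.DataArray(
            vals.reshape(nlat, nlon), dims=("lat", "lon"),
            coords={"lat": coords["lat"], "lon": coords["lon"]},
        )
        return GriddedField(da, area_weights=uniform_w)

    truth = {
        "class_2000": cls0.reshape(nlat, nlon) + 1,
        "class_2100": cls1.reshape(nlat, nlon) + 1,
        "fraction_higher": n_up / ncell,
        "fraction_lower": n_dn / ncell,
        "fraction_unchanged": 1.0 - (n_up + n_dn) / ncell,
    }
    return wrap(field_of(cls0, sentinel=True)), wrap(field_of(cls1, sentinel=False)), truth


def make_sign_fields(
    table: dict[str, int],
    spec: SyntheticSpec | None = None,
) -> tuple[GriddedField, GriddedField, dict[str, Any]]:
    """Change fields (dx, dy) realizing a prescribed 2x2 sign table exactly.

    ``table`` gives cell counts for keys both_pos, x_pos_y_neg, x_neg_y_pos,
    both_neg; the grid is sized to hold exactly their sum (one row), weights
    uniform, magnitudes random in [0.5, 1.5).
    """
    keys = ("both_pos", "x_pos_y_neg", "x_neg_y_pos", "both_neg")
    missing = set(keys) - set(table)
    if missing:
        raise InvalidParameterError(f"sign table missing {sorted(missing)}")
    n = sum(int(table[k]) for k in keys)
    if n < 1:
        raise InvalidParameterError("empty sign table")
    seed = spec.seed if spec is not None else 0
    rng = np.random.default_rng(seed + 3)
    sx = np.concatenate([
        np.full(table["both_pos"], 1), np.full(table["x_pos_y_neg"], 1),
        np.full(table["x_neg_y_pos"], -1), np.full(table["both_neg"], -1),
    ]).astype(float)
    sy = np.concatenate([
        np.full(table["both_pos"], 1), np.full(table["x_pos_y_neg"], -1),
        np.full(table["x_neg_y_pos"], 1), np.full(table["both_neg"], -1),
    ]).astype(float)
    perm = rng.permutation(n)
    sx, sy = sx[perm], sy[perm]
    dx = sx * rng.uniform(0.5, 1.5, n)
    dy = sy * rng.uniform(0.5, 1.5, n)

    lat = np.array([0.0])
    lon = np.arange(n, dtype=float)
    uniform_w = xr.DataArray(np.ones((1, n)), dims=("lat", "lon"),
                             coords={"lat": lat, "lon": lon})

    def wrap(v):
        da = xr.DataArray(v.reshape(1, n), dims=("lat", "lon"),
                          coords={"lat": lat, "lon": lon})
        return GriddedField(da, area_weights=uniform_w)

    truth = {k: int(table[k]) for k in keys}
    return wrap(dx), wrap(dy), truth


@dataclass
class ScenarioConfig:
    """Knobs of the paired baseline/future water-column scenarios.

    The future surrogate captures the two pathways of spectral change:
    stratification-driven nutrient decline (``nutrient_scale``) and a changed
    seasonal amplitude of the surface color cycle (``color_amp_scale`` < 1
    mimics gyre-like stabilization of the light color, > 1 the high-latitude
    amplification).
    """

    par_mean: float = 150.0
    par_seasonal_amp: float = 0.3
    green_weight_mean: float = 0.45
    color_seasonal_amp: float = 0.8
    nutrient_supply: float = 0.02  # mmol m-3 d-1 into the bottom layer
    mixing_rate: float = 0.5
    cdom_a440: float = 0.01
    nutrient_scale: float = 0.7  # future / baseline
    color_amp_scale: float = 0.25  # future / baseline

    def __post_init__(self) -> None:
        for name in ("par_mean", "nutrient_supply", "nutrient_scale",
                     "color_amp_scale"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


def make_scenarios(config: ScenarioConfig | None = None) -> tuple[Forcing, Forcing]:
    """Baseline and future forcings differing only in the documented knobs."""
    cfg = config or ScenarioConfig()

    def forcing(nutrient_scale: float, color_scale: float, label: str) -> Forcing:
        spectrum = seasonal_surface_spectrum(
            par_mean=cfg.par_mean,
            par_seasonal_amp=cfg.par_seasonal_amp,
            green_weight_mean=cfg.green_weight_mean,
            color_seasonal_amp=cfg.color_seasonal_amp * color_scale,
        )
        supply = cfg.nutrient_supply * nutrient_scale
        return Forcing(
            surface_spectrum=spectrum,
            nutrient_supply=lambda doy, s=supply: s,
            mixing_rate=cfg.mixing_rate,
            cdom_a440=cfg.cdom_a440,
            scenario_label=label,
        )

    baseline = forcing(1.0, 1.0, "baseline")
    future = forcing(cfg.nutrient_scale, cfg.color_amp_scale, "future")
    return baseline, future
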