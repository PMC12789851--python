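"""Pigment-type absorption spectra for marine *Synechococcus*.

Three pigment types are represented by their chlorophyll-specific absorption
spectra on the photosynthetically active range (400-700 nm, 5-nm bands):

* blue specialist (BS): constitutively high PUB:PEB (~1.4),
* green specialist (GS): constitutively low PUB:PEB (~0.4),
* chromatic acclimator (CA): six discrete acclimation states spanning the
  green-acclimated (~0.67) to blue-acclimated (~1.4) phenotypes, generated by
  linear interpolation between the two end members.

PUB (phycourobilin) absorbs blue light with a peak near 495 nm and PEB
(phycoerythrobilin) absorbs green light with a peak near 545 nm.  The PUB:PEB
ratio is operationalized throughout as the ratio of absorption at the 495-nm
band to absorption at the 545-nm band, the only version of the chromophore
ratio computable from a spectrum alone.

Spectra are parametric surrogates: sums of Gaussian pigment bands
(chlorophyll-a at 440/675 nm, phycocyanin at 620 nm, PUB at 495 nm, PEB at
545 nm) whose PUB and PEB amplitudes are solved exactly so the 495:545
absorption ratio matches the requested PUB:PEB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateSpectrumError,
    IncompatibleGridError,
    InvalidParameterError,
)

__all__ = [
    "WavelengthGrid",
    "AbsorptionSpectrum",
    "ShapeParams",
    "PigmentTypeSpec",
    "build_endmember_spectrum",
    "interpolate_ca_states",
    "pub_peb_ratio",
    "default_pigment_types",
    "read_spectrum",
    "write_spectrum",
    "PUB_PEAK_NM",
    "PEB_PEAK_NM",
]

PUB_PEAK_NM = 495.0
PEB_PEAK_NM = 545.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform grid of band centers in nm (default 400, 405, ..., 700)."""

    wavelengths: np.ndarray
    band_width: float = 5.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise InvalidParameterError("wavelength grid needs >= 2 bands")
        steps = np.diff(wl)
        if np.any(steps <= 0) or not np.allclose(steps, self.band_width):
            raise InvalidParameterError(
                "band centers must increase uniformly by band_width"
            )

    @classmethod
    def default(cls) -> "WavelengthGrid":
        return cls(np.arange(400.0, 701.0, 5.0), band_width=5.0)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def index_of(self, nm: float) -> int:
        """Index of the band centered exactly at ``nm``."""
        idx = np.nonzero(np.isclose(self.wavelengths, nm))[0]
        if idx.size == 0:
            raise IncompatibleGridError(f"grid has no band centered at {nm} nm")
        return int(idx[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.band_width == other.band_width
            and self.wavelengths.shape == other.wavelengths.shape
            and bool(np.all(self.wavelengths == other.wavelengths))
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.band_width, self.wavelengths.tobytes()))


@dataclass
class AbsorptionSpectrum:
    """Chlorophyll-specific absorption per band, m^2 (mg chl)^-1."""

    grid: WavelengthGrid
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_bands,):
            raise IncompatibleGridError(
                f"values length {v.size} != grid bands {self.grid.n_bands}"
            )
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise InvalidParameterError("absorption values must be finite and >= 0")
        self.values = v

    def at(self, nm: float) -> float:
        return float(self.values[self.grid.index_of(nm)])


def pub_peb_ratio(spectrum: AbsorptionSpectrum) -> float:
    """The 495:545 absorption band ratio, the spectral proxy for PUB:PEB."""
    a_blue = spectrum.at(PUB_PEAK_NM)
    a_green = spectrum.at(PEB_PEAK_NM)
    if a_green == 0.0:
        raise DegenerateSpectrumError("absorption at 545 nm is zero")
    return a_blue / a_green


@dataclass(frozen=True)
class ShapeParams:
    """Gaussian-mixture shape of a surrogate pigment spectrum.

    Amplitudes are m^2 (mg chl)^-1 at the band peak; widths are Gaussian
    sigmas in nm.  ``phycobilin_total`` is the summed amplitude of the PUB and
    PEB bands; their split is solved from the target PUB:PEB ratio.
    """

    sigma_nm: float = 15.0
    chl_blue_amp: float = 0.030  # chlorophyll-a Soret band, 440 nm
    chl_red_amp: float = 0.020  # chlorophyll-a red band, 675 nm
    phycocyanin_amp: float = 0.010  # 620 nm
    phycobilin_total: float = 0.080
    baseline: float = 0.002

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise InvalidParameterError("Gaussian width must be positive")
        for name in ("chl_blue_amp", "chl_red_amp", "phycocyanin_amp", "baseline"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.phycobilin_total <= 0:
            raise InvalidParameterError("phycobilin_total must be positive")


_FIXED_PEAKS_NM = (440.0, 620.0, 675.0)


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def build_endmember_spectrum(
    target_pub_peb: float,
    shape: ShapeParams | None = None,
    grid: WavelengthGrid | None = None,
    label: str = "",
) -> AbsorptionSpectrum:
    """Construct a surrogate spectrum whose 495:545 ratio equals the target.

    The PUB (495 nm) and PEB (545 nm) Gaussian amplitudes ``p`` and ``g`` are
    the exact solution of::

        a(495) / a(545) = target,   p + g = phycobilin_total

    where a(.) includes the fixed chlorophyll/phycocyanin bands and baseline.

    Raises
    ------
    InvalidParameterError
        If the target ratio is non-positive or so extreme that one phycobilin
        amplitude would have to be negative.
    """
    if target_pub_peb <= 0:
        raise InvalidParameterError("PUB:PEB target must be positive")
    shape = shape or ShapeParams()
    grid = grid or WavelengthGrid.default()
    wl = grid.wavelengths

    fixed_amps = (shape.chl_blue_amp, shape.phycocyanin_amp, shape.chl_red_amp)
    background = shape.baseline + sum(
        amp * _gauss(wl, ctr, shape.sigma_nm)
        for amp, ctr in zip(fixed_amps, _FIXED_PEAKS_NM)
    )
    b_blue = float(
        shape.baseline
        + sum(
            amp * math.exp(-0.5 * ((PUB_PEAK_NM - ctr) / shape.sigma_nm) ** 2)
            for amp, ctr in zip(fixed_amps, _FIXED_PEAKS_NM)
        )
    )
    b_green = float(
        shape.baseline
        + sum(
            amp * math.exp(-0.5 * ((PEB_PEAK_NM - ctr) / shape.sigma_nm) ** 2)
            for amp, ctr in zip(fixed_amps, _FIXED_PEAKS_NM)
        )
    )

    # cross-talk of one phycobilin band evaluated at the other's peak
    r = target_pub_peb
    c = math.exp(-0.5 * ((PUB_PEAK_NM - PEB_PEAK_NM) / shape.sigma_nm) ** 2)
    s = shape.phycobilin_total
    # (b_blue + p + g*c) = r * (b_green + p*c + g)  with  p + g = s
    g = (r * b_green - b_blue - s * (1.0 - r * c)) / ((c - 1.0) * (1.0 + r))
    p = s - g
    if p < 0 or g < 0:
        raise InvalidParameterError(
            f"PUB:PEB target {r} unreachable with phycobilin_total {s}"
        )

    values = (
        background
        + p * _gauss(wl, PUB_PEAK_NM, shape.sigma_nm)
        + g * _gauss(wl, PEB_PEAK_NM, shape.sigma_nm)
    )
    return AbsorptionSpectrum(grid, values, label=label or f"endmember r={r:g}")


def interpolate_ca_states(
    green_end: AbsorptionSpectrum,
    blue_end: AbsorptionSpectrum,
    n_states: int = 6,
) -> list[AbsorptionSpectrum]:
    """Linearly interpolate the CA end members into ``n_states`` spectra.

    State ``i`` (1-based) has values ``(1-w) * green + w * blue`` with
    ``w = (i-1)/(n_states-1)``; state 1 is the green-acclimated end member
    and state ``n_states`` the blue-acclimated one.
    """
    if green_end.grid != blue_end.grid:
        raise IncompatibleGridError("CA end members are on different grids")
    if n_states < 2:
        raise InvalidParameterError("need at least 2 acclimation states")
    states = []
    for i in range(n_states):
        w = i / (n_states - 1)
        values = (1.0 - w) * green_end.values + w * blue_end.values
        states.append(
            AbsorptionSpectrum(green_end.grid, values, label=f"CA{i + 1}")
        )
    return states


@dataclass
class PigmentTypeSpec:
    """A pigment type and its (one or six) state spectra."""

    name: str  # "BS", "GS" or "CA"
    state_spectra: list[AbsorptionSpectrum]
    pub_peb_ratios: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.name not in ("BS", "GS", "CA"):
            raise InvalidParameterError(f"unknown pigment type {self.name!r}")
        if not self.state_spectra:
            raise InvalidParameterError("pigment type needs >= 1 state spectrum")
        if not self.pub_peb_ratios:
            self.pub_peb_ratios = [pub_peb_ratio(s) for s in self.state_spectra]

    @property
    def n_states(self) -> int:
        return len(self.state_spectra)


#: Default PUB:PEB ratios: fixed specialists and the CA acclimation endpoints.
DEFAULT_RATIOS = {
    "BS": 1.4,
    "GS": 0.4,
    "CA_green": 0.67,
    "CA_blue": 1.4,
}


def default_pigment_types(
    shape: ShapeParams | None = None,
    grid: WavelengthGrid | None = None,
    n_ca_states: int = 6,
    ratios: dict[str, float] | None = None,
) -> dict[str, PigmentTypeSpec]:
    """The standard three pigment types: BS, GS and a six-state CA."""
    r = dict(DEFAULT_RATIOS)
    if ratios:
        r.update(ratios)
    shape = shape or ShapeParams()
    grid = grid or WavelengthGrid.default()
    bs = build_endmember_spectrum(r["BS"], shape, grid, label="BS")
    gs = build_endmember_spectrum(r["GS"], shape, grid, label="GS")
    ca_green = build_endmember_spectrum(r["CA_green"], shape, grid, label="CA green end")
    ca_blue = build_endmember_spectrum(r["CA_blue"], shape, grid, label="CA blue end")
    ca_states = interpolate_ca_states(ca_green, ca_blue, n_ca_states)
    return {
        "BS": PigmentTypeSpec("BS", [bs]),
        "GS": PigmentTypeSpec("GS", [gs]),
        "CA": PigmentTypeSpec("CA", ca_states),
    }


def write_spectrum(spectrum: AbsorptionSpectrum, path) -> None:
    """Write a spectrum as two-column text (wavelength nm, absorption)."""
    data = np.column_stack([spectrum.grid.wavelengths, spectrum.values])
    header = f"label: {spectrum.label}\nwavelength_nm absorption_m2_per_mg_chl"
    np.savetxt(path, data, header=header)


def read_spectrum(path, band_width: float = 5.0) -> AbsorptionSpectrum:
    """Read a two-column (wavelength, absorption) text spectrum."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise InvalidParameterError("spectrum file must have two columns")
    grid = WavelengthGrid(data[:, 0], band_width=band_width)
    return AbsorptionSpectrum(grid, data[:, 1])
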