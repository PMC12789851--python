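"""Inherent optical properties of the water column other than phytoplankton.

Pure-seawater absorption follows the shape of published laboratory
measurements (Pope & Fry-style spectrophotometry): minimal near 420 nm,
rising gently through the green and steeply into the red.  Only the ordering
a_w(545) > a_w(495) matters for the blue-to-green diagnostics; the table is a
literature-style constant, not a fit.

CDOM (colored dissolved organic matter) plus detritus is modeled as a single
exponentially decaying absorption term, the standard one-parameter form
a(l) = a(440) * exp(-S * (l - 440)).
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidParameterError
from .spectra import WavelengthGrid

__all__ = ["water_absorption", "cdom_absorption"]

# Pure-water absorption coefficient, m^-1, at 10-nm intervals from 400 to
# 700 nm (literature-style values; visible-range minimum near 420 nm).
_WATER_TABLE_NM = np.arange(400.0, 701.0, 10.0)
_WATER_TABLE_A = np.array(
    [
        0.00663, 0.00473, 0.00454, 0.00495, 0.00635,
        0.00922, 0.00979, 0.01060, 0.01270, 0.01500,
        0.02040, 0.03250, 0.04090, 0.04340, 0.04740,
        0.05650, 0.06190, 0.06950, 0.08960, 0.13510,
        0.22240, 0.26440, 0.27550, 0.29160, 0.31080,
        0.34000, 0.41000, 0.43900, 0.46500, 0.51600,
        0.62400,
    ]
)


def water_absorption(grid: WavelengthGrid | None = None) -> np.ndarray:
    """Pure-seawater absorption (m^-1) interpolated onto a wavelength grid."""
    grid = grid or WavelengthGrid.default()
    wl = grid.wavelengths
    if wl.min() < _WATER_TABLE_NM[0] or wl.max() > _WATER_TABLE_NM[-1]:
        raise InvalidParameterError(
            "pure-water table covers 400-700 nm only"
        )
    return np.interp(wl, _WATER_TABLE_NM, _WATER_TABLE_A)


def cdom_absorption(
    grid: WavelengthGrid | None = None,
    a440: float = 0.01,
    slope: float = 0.014,
) -> np.ndarray:
    """Combined CDOM + detritus absorption (m^-1): a440 * exp(-S*(l-440))."""
    if a440 < 0 or slope < 0:
        raise InvalidParameterError("CDOM amplitude and slope must be >= 0")
    grid = grid or WavelengthGrid.default()
    return a440 * np.exp(-slope * (grid.wavelengths - 440.0))
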