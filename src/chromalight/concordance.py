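"""Spatial sign-concordance between two change fields.

Used to ask whether the change in chromatic-acclimator biomass and the change
in the acclimation index move in the same direction cell by cell: each ocean
cell is classified by the pair (sign dx, sign dy); cells with an exactly zero
sign in either field are excluded (and counted).  Reported are the
area-weighted 2x2 sign table, the agreement fraction, the Matthews
correlation coefficient (MCC) of the table and the (unweighted) Spearman rank
correlation of the raw values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .diagnostics import GriddedField
from .exceptions import (
    EmptyConcordanceError,
    IncompatibleGridError,
    UndefinedCorrelationError,
)

__all__ = [
    "ConcordanceResult",
    "sign_mcc",
    "mcc_from_counts",
    "spearman_rho",
    "agreement_fraction",
    "concordance",
]

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceResult:
    """2x2 weighted sign table and its summary statistics.

    counts holds (both_positive, x_pos_y_neg, x_neg_y_pos, both_negative);
    with area weighting these are weighted areas rather than cell counts.
    """

    counts: dict[str, float] = field(default_factory=dict)
    agreement_fraction: float = float("nan")
    mcc: float = float("nan")
    spearman_rho: float = float("nan")
    n_excluded_zero: int = 0
    mcc_degenerate: bool = False


def mcc_from_counts(tp: float, fp: float, fn: float, tn: float) -> tuple[float, bool]:
    """Matthews correlation of a 2x2 table; a zero denominator factor gives
    (0.0, True) by convention."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0, True
    return float((tp * tn - fp * fn) / np.sqrt(denom)), False


def _signed_cells(dx: GriddedField, dy: GriddedField, weighted: bool):
    if dx.data.shape != dy.data.shape:
        raise IncompatibleGridError("dx and dy on different grids")
    m = dx.mask.values & dy.mask.values
    x = dx.data.values[m]
    y = dy.data.values[m]
    w = dx.area_weights.values[m] if weighted else np.ones(x.size)
    sx, sy = np.sign(x), np.sign(y)
    nonzero = (sx != 0) & (sy != 0)
    n_excl = int(np.sum(~nonzero))
    if not np.any(nonzero):
        raise EmptyConcordanceError("every cell has a zero sign in dx or dy")
    return sx[nonzero], sy[nonzero], w[nonzero], n_excl


def sign_mcc(
    dx: GriddedField, dy: GriddedField, weighted: bool = True
) -> ConcordanceResult:
    """Sign-agreement table and MCC between two change fields."""
    sx, sy, w, n_excl = _signed_cells(dx, dy, weighted)
    tp = float(np.sum(w[(sx > 0) & (sy > 0)]))
    fp = float(np.sum(w[(sx > 0) & (sy < 0)]))
    fn = float(np.sum(w[(sx < 0) & (sy > 0)]))
    tn = float(np.sum(w[(sx < 0) & (sy < 0)]))
    mcc, degenerate = mcc_from_counts(tp, fp, fn, tn)
    if degenerate:
        logger.warning("sign_mcc: zero marginal in the sign table; MCC set to 0")
    agree = (tp + tn) / (tp + fp + fn + tn)
    return ConcordanceResult(
        counts={"both_pos": tp, "x_pos_y_neg": fp, "x_neg_y_pos": fn, "both_neg": tn},
        agreement_fraction=float(agree),
        mcc=mcc,
        n_excluded_zero=n_excl,
        mcc_degenerate=degenerate,
    )


def agreement_fraction(
    dx: GriddedField, dy: GriddedField, weighted: bool = True
) -> float:
    """Weighted fraction of non-zero-sign cells where dx and dy agree in sign."""
    return sign_mcc(dx, dy, weighted).agreement_fraction


def spearman_rho(dx: GriddedField, dy: GriddedField) -> float:
    """Unweighted Spearman rank correlation (midranks for ties) over ocean cells."""
    m = dx.mask.values & dy.mask.values
    x = dx.data.values[m]
    y = dy.data.values[m]
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 unmasked cells")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("rank correlation of a constant field")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def concordance(
    dx: GriddedField, dy: GriddedField, weighted: bool = True
) -> ConcordanceResult:
    """Full concordance report: sign table, agreement, MCC and Spearman."""
    result = sign_mcc(dx, dy, weighted)
    result.spearman_rho = spearman_rho(dx, dy)
    return result
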