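"""Scalar validity metrics for external validation of QSAR models.

This module implements the agreement statistics the five criterion
families consume:

* ``squared_correlation`` -- r², the squared Pearson correlation between
  experimental and calculated activity.
* ``rto_slopes`` -- K and K', the slopes of least-squares regression lines
  constrained through the origin, in the two directions.
* ``r0sq_eq3`` / ``r0prime_sq_eq4`` / ``r0sq_eq5`` -- three published
  conventions for the coefficient of determination of the through-origin
  fit. The literature is not consistent about how the reverse-direction
  r₀'² is computed, so the reverse form takes an explicit convention tag
  (see :class:`Eq4Convention`).
* ``rm_squared`` -- Roy's r²m = r²·(1 − √(r² − r₀²)), undefined (the
  :data:`ND` sentinel) when r² < r₀².
* ``concordance_cc`` -- Lin's concordance correlation coefficient, which
  penalises location and scale shifts as well as scatter.

All functions are pure and operate on :class:`~qsarval.pairs.ActivityPairs`;
rounding to reporting precision happens only in the report writer.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, UsageError
from .pairs import ActivityPairs

__all__ = [
    "ND",
    "Eq4Convention",
    "MetricSet",
    "squared_correlation",
    "rto_slopes",
    "r0sq_eq3",
    "r0prime_sq_eq4",
    "r0sq_eq5",
    "rm_squared",
    "concordance_cc",
    "compute_metric_set",
]


class _NotDeterminable:
    """Singleton sentinel for metrics that are undefined at their inputs.

    Distinct from NaN so downstream verdicts can tell "could not be
    computed" apart from "computed and failed". Renders as ``"ND"``.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ND"

    def __reduce__(self):
        return (_NotDeterminable, ())


ND = _NotDeterminable()


class Eq4Convention(str, enum.Enum):
    """How the reverse-direction through-origin r₀'² is computed.

    printed
        Literal published form: residual ``y_exp − K'·y_pred`` against the
        centered total sum of squares of ``y_exp``. Can be strongly
        negative because K' is the wrong-direction slope for that residual.
    swapped_centered
        Standard reverse-axis form (the default): residual
        ``y_pred − K'·y_exp`` against the centered total sum of squares of
        ``y_pred``.
    uncentered
        Same residual with an uncentered denominator ``Σ y_pred²``;
        algebraically identical to the textbook through-origin r₀² of
        :func:`r0sq_eq5`.
    """

    PRINTED = "printed"
    SWAPPED_CENTERED = "swapped_centered"
    UNCENTERED = "uncentered"


def _centered_ss(x: np.ndarray, name: str) -> float:
    ss = float(np.sum((x - x.mean()) ** 2))
    if ss == 0.0:
        raise DegenerateInputError(f"{name} is constant; centered metric undefined")
    return ss


def squared_correlation(pairs: ActivityPairs) -> float:
    """Squared Pearson correlation r² between experimental and calculated
    activity.

    Symmetric in its arguments and invariant to affine rescaling of either
    vector; consequently a perfectly anti-correlated prediction also scores
    r² = 1 (the sign is reported separately in :class:`MetricSet`).
    """
    pairs.require_n(3, "squared correlation")
    x, y = pairs.y_exp, pairs.y_pred
    sxx = _centered_ss(x, "y_exp")
    syy = _centered_ss(y, "y_pred")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    return sxy * sxy / (sxx * syy)


def rto_slopes(pairs: ActivityPairs) -> tuple[float, float]:
    """Slopes (K, K') of the two least-squares regressions through the
    origin.

    K fits experimental on calculated (``y_exp ≈ K·y_pred``); K' fits the
    reverse direction (``y_pred ≈ K'·y_exp``). Both are Σ(y_exp·y_pred)
    over the respective sum of squares.
    """
    pairs.require_n(2, "through-origin slopes")
    x, y = pairs.y_exp, pairs.y_pred
    sxx = float(np.sum(x * x))
    syy = float(np.sum(y * y))
    if syy == 0.0:
        raise DegenerateInputError("y_pred is all zero; slope K undefined")
    if sxx == 0.0:
        raise DegenerateInputError("y_exp is all zero; slope K' undefined")
    sxy = float(np.sum(x * y))
    return sxy / syy, sxy / sxx


def r0sq_eq3(pairs: ActivityPairs) -> float:
    """Forward through-origin coefficient of determination.

    1 minus the ratio of the residual sum of squares of the through-origin
    fit ``y_exp ≈ K·y_pred`` to the centered total sum of squares of
    ``y_exp``. Never exceeds :func:`squared_correlation` because the
    origin constraint can only increase the residual sum of squares.
    """
    pairs.require_n(3, "through-origin r0^2")
    k, _ = rto_slopes(pairs)
    x, y = pairs.y_exp, pairs.y_pred
    ss_tot = _centered_ss(x, "y_exp")
    ss_res = float(np.sum((x - k * y) ** 2))
    return 1.0 - ss_res / ss_tot


def r0prime_sq_eq4(
    pairs: ActivityPairs,
    convention: Eq4Convention | str = Eq4Convention.SWAPPED_CENTERED,
) -> float:
    """Reverse-direction through-origin coefficient of determination.

    See :class:`Eq4Convention` for the three selectable forms.
    """
    try:
        convention = Eq4Convention(convention)
    except ValueError:
        raise UsageError(
            f"unknown Eq. 4 convention {convention!r}; expected one of "
            f"{[c.value for c in Eq4Convention]}"
        ) from None
    pairs.require_n(3, "through-origin r0'^2")
    _, k_prime = rto_slopes(pairs)
    x, y = pairs.y_exp, pairs.y_pred
    if convention is Eq4Convention.PRINTED:
        ss_tot = _centered_ss(x, "y_exp")
        ss_res = float(np.sum((x - k_prime * y) ** 2))
        return 1.0 - ss_res / ss_tot
    ss_res = float(np.sum((y - k_prime * x) ** 2))
    if convention is Eq4Convention.SWAPPED_CENTERED:
        ss_tot = _centered_ss(y, "y_pred")
    else:  # UNCENTERED
        ss_tot = float(np.sum(y * y))
        if ss_tot == 0.0:
            raise DegenerateInputError("y_pred is all zero")
    return 1.0 - ss_res / ss_tot


def r0sq_eq5(pairs: ActivityPairs) -> float:
    """Direction-symmetric through-origin r₀² (textbook form).

    The squared uncentered correlation (Σ y_exp·y_pred)² / (Σy_exp²·Σy_pred²);
    identical in both regression directions, hence reported as a single
    value. Equals K·K' exactly.
    """
    pairs.require_n(2, "uncentered r0^2")
    x, y = pairs.y_exp, pairs.y_pred
    sxx = float(np.sum(x * x))
    syy = float(np.sum(y * y))
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateInputError("all-zero activity vector")
    sxy = float(np.sum(x * y))
    return sxy * sxy / (sxx * syy)


def rm_squared(r2: float, r0sq: float):
    """Roy's r²m = r²·(1 − √(r² − r₀²)).

    Returns the :data:`ND` sentinel when r² < r₀², in which case the square
    root is undefined — a situation that arises routinely when r₀² is
    computed with the uncentered convention, where r₀² commonly exceeds r².
    ND is a value, not an error, so verdicts can report it.
    """
    r2 = float(r2)
    r0sq = float(r0sq)
    if not (math.isfinite(r2) and math.isfinite(r0sq)):
        raise UsageError("r2 and r0sq must be finite")
    if r2 < r0sq:
        return ND
    return r2 * (1.0 - math.sqrt(r2 - r0sq))


def concordance_cc(pairs: ActivityPairs) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2·S_xy / (S_xx + S_yy + n·(x̄ − ȳ)²) with centered sums of
    squares/products. Equals 1 only for exact agreement; bounded by the
    Pearson correlation in magnitude; driven toward 0 by constant bias
    that leaves r² untouched.
    """
    pairs.require_n(3, "concordance correlation")
    x, y = pairs.y_exp, pairs.y_pred
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    syy = float(np.sum((y - ym) ** 2))
    if sxx == 0.0 and syy == 0.0:
        raise DegenerateInputError("both activity vectors constant; CCC undefined")
    sxy = float(np.sum((x - xm) * (y - ym)))
    denom = sxx + syy + pairs.n * (xm - ym) ** 2
    if denom == 0.0:
        # only possible when both vectors are the same constant, caught above
        raise DegenerateInputError("degenerate CCC denominator")
    return 2.0 * sxy / denom


@dataclass(frozen=True)
class MetricSet:
    """All scalar validity metrics for one split pair.

    ``rm2`` may be the :data:`ND` sentinel. ``pearson_sign`` is +1/-1 and
    flags anti-correlated predictions, which the squared statistics cannot
    distinguish from good ones.
    """

    r2: float
    k: float
    k_prime: float
    r0sq_eq3: float
    r0prime_sq_eq4: float
    r0sq_eq5: float
    rm2: object
    ccc: float
    convention_eq4: Eq4Convention
    pearson_sign: int


def compute_metric_set(
    pairs: ActivityPairs,
    eq4_convention: Eq4Convention | str = Eq4Convention.SWAPPED_CENTERED,
) -> MetricSet:
    """Compute every metric for one split pair in one pass."""
    r2 = squared_correlation(pairs)
    k, k_prime = rto_slopes(pairs)
    r0 = r0sq_eq3(pairs)
    r0p = r0prime_sq_eq4(pairs, eq4_convention)
    r0u = r0sq_eq5(pairs)
    sxy = float(
        np.sum((pairs.y_exp - pairs.y_exp.mean()) * (pairs.y_pred - pairs.y_pred.mean()))
    )
    return MetricSet(
        r2=r2,
        k=k,
        k_prime=k_prime,
        r0sq_eq3=r0,
        r0prime_sq_eq4=r0p,
        r0sq_eq5=r0u,
        rm2=rm_squared(r2, r0),
        ccc=concordance_cc(pairs),
        convention_eq4=Eq4Convention(eq4_convention),
        pearson_sign=1 if sxy >= 0 else -1,
    )
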