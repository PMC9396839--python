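"""Paired experimental/calculated activity vectors.

:class:`ActivityPairs` is the fundamental container every metric operates
on: one vector of experimental (measured) log-scale biological activities
and one vector of model-calculated activities for the same compounds, in
the same order. Activities are unitless log quantities (pIC50 and kin);
no unit handling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientDataError, QsarvalError

__all__ = ["ActivityPairs"]


def _as_float_vector(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise QsarvalError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise QsarvalError(f"{name} contains non-finite values (NaN or inf)")
    return arr


@dataclass(frozen=True)
class ActivityPairs:
    """Experimental and calculated activities for one data split.

    Parameters
    ----------
    y_exp : array-like of float
        Experimental activity values (log scale, unitless).
    y_pred : array-like of float
        Model-calculated activity values on the same scale.

    Raises
    ------
    QsarvalError
        If the vectors differ in length or contain non-finite entries.
    """

    y_exp: np.ndarray
    y_pred: np.ndarray
    ids: tuple = field(default=(), compare=False)

    def __post_init__(self):
        y_exp = _as_float_vector(self.y_exp, "y_exp")
        y_pred = _as_float_vector(self.y_pred, "y_pred")
        if y_exp.shape != y_pred.shape:
            raise QsarvalError(
                f"length mismatch: {y_exp.size} experimental vs "
                f"{y_pred.size} calculated values"
            )
        if y_exp.size == 0:
            raise InsufficientDataError("empty activity vectors")
        y_exp.flags.writeable = False
        y_pred.flags.writeable = False
        object.__setattr__(self, "y_exp", y_exp)
        object.__setattr__(self, "y_pred", y_pred)
        if self.ids and len(self.ids) != y_exp.size:
            raise QsarvalError("ids length does not match activity vectors")

    @property
    def n(self) -> int:
        """Number of compounds."""
        return int(self.y_exp.size)

    def require_n(self, minimum: int, what: str) -> None:
        if self.n < minimum:
            raise InsufficientDataError(
                f"{what} requires at least {minimum} compounds, got {self.n}"
            )

    def __eq__(self, other):
        if not isinstance(other, ActivityPairs):
            return NotImplemented
        return (
            np.array_equal(self.y_exp, other.y_exp)
            and np.array_equal(self.y_pred, other.y_pred)
        )

    __hash__ = None
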