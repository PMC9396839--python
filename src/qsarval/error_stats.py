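"""Absolute-error summaries and the training-vs-test error comparison.

The fourth criterion family judges a model by whether its prediction
errors on the held-out test set are statistically indistinguishable from
its resubstitution errors on the training set: a model that fits the
training compounds much better than it predicts new ones is suspect even
when its test-set r² looks fine. The comparison is a two-sided independent
two-sample t-test on the per-compound absolute errors.

Absolute errors are also binned into three fixed subgroups
(< 0.1, 0.1–0.2, > 0.2 log units) for frequency plots, and signed
residuals are exposed for diagnostic scatter plots.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, QsarvalError, UsageError
from .pairs import ActivityPairs

__all__ = [
    "TTestVariant",
    "ErrorSummary",
    "ErrorComparison",
    "absolute_errors",
    "error_summary",
    "frequency_bins",
    "compare_errors",
    "residuals",
]

#: Bin edges for the absolute-error frequency subgroups (activity log units).
#: Boundary rule: [0, 0.1), [0.1, 0.2], (0.2, inf) — exact 0.1 and 0.2 fall
#: in the middle bin.
BIN_EDGES = (0.1, 0.2)


class TTestVariant(str, enum.Enum):
    STUDENT = "student"  # pooled variance
    WELCH = "welch"      # unequal variance


@dataclass(frozen=True)
class ErrorSummary:
    """Mean/SD of absolute errors plus the three frequency-bin proportions."""

    aae: float
    sd: float
    n: int
    bins: tuple[float, float, float]


@dataclass(frozen=True)
class ErrorComparison:
    """Result of the two-sided independent t-test on absolute errors."""

    t_statistic: float
    p_value: float
    variant: TTestVariant
    sidedness: str = "two-sided"


def absolute_errors(pairs: ActivityPairs) -> np.ndarray:
    """Per-compound absolute error |y_exp − y_pred|, order-preserving."""
    return np.abs(pairs.y_exp - pairs.y_pred)


def residuals(pairs: ActivityPairs) -> np.ndarray:
    """Signed residual y_exp − y_pred per compound."""
    return pairs.y_exp - pairs.y_pred


def frequency_bins(aes) -> tuple[float, float, float]:
    """Proportions of absolute errors below 0.1, in [0.1, 0.2], and above 0.2.

    Returned as fractions summing to one; the report writer renders them as
    percentages.
    """
    aes = _validated_aes(aes)
    lo, hi = BIN_EDGES
    n = aes.size
    small = int(np.sum(aes < lo))
    large = int(np.sum(aes > hi))
    return (small / n, (n - small - large) / n, large / n)


def _validated_aes(aes) -> np.ndarray:
    arr = np.asarray(aes, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("empty absolute-error sequence")
    if not np.all(np.isfinite(arr)):
        raise QsarvalError("absolute errors contain non-finite values")
    if np.any(arr < 0):
        raise QsarvalError("absolute errors must be non-negative")
    return arr


def error_summary(aes, ddof: int = 1) -> ErrorSummary:
    """Summarise a sequence of absolute errors.

    ``sd`` uses the sample (n−1) denominator by default; pass ``ddof=0``
    for the population form. A single observation gets sd 0.
    """
    arr = _validated_aes(aes)
    if ddof not in (0, 1):
        raise UsageError("ddof must be 0 or 1")
    sd = 0.0 if arr.size <= ddof else float(arr.std(ddof=ddof))
    return ErrorSummary(
        aae=float(arr.mean()),
        sd=sd,
        n=int(arr.size),
        bins=frequency_bins(arr),
    )


def compare_errors(
    train_aes,
    test_aes,
    variant: TTestVariant | str = TTestVariant.STUDENT,
) -> ErrorComparison:
    """Two-sided independent t-test between training and test absolute errors.

    ``student`` (default) pools the variances; ``welch`` does not assume
    equal variances. When both groups have zero variance the test is
    degenerate: equal means give p = 1 by convention, unequal means p = 0.
    """
    try:
        variant = TTestVariant(variant)
    except ValueError:
        raise UsageError(
            f"unknown t-test variant {variant!r}; expected 'student' or 'welch'"
        ) from None
    a = _validated_aes(train_aes)
    b = _validated_aes(test_aes)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            "t-test requires at least 2 absolute errors per group"
        )
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return ErrorComparison(0.0, 1.0, variant)
        return ErrorComparison(float("inf"), 0.0, variant)
    res = stats.ttest_ind(a, b, equal_var=(variant is TTestVariant.STUDENT))
    return ErrorComparison(float(res.statistic), float(res.pvalue), variant)
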