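"""The five criterion families and per-model/batch verdicts.

Each published criterion family is one ``method*`` function returning a
:class:`CriterionVerdict` that records, for every sub-rule, the exact
numeric comparison performed. No composite overall score is produced:
the point of running all five side by side is that they disagree in
instructive ways.

method 1 (Golbraikh–Tropsha)
    r² > 0.6; a through-origin slope K or K' in (0.85, 1.15); and a
    relative gap (r² − r₀²)/r² below 0.1 in at least one direction.
    Negative gaps (r₀² exceeding r²) satisfy the strict "< 0.1" test.
method 2 (Roy r²m)
    r²m > 0.5; an ND (undefined) r²m fails.
method 3 (concordance)
    CCC > 0.8.
method 4 (error comparison)
    r² > 0.6 and no significant train/test difference in absolute errors
    (two-sided independent t-test, p > 0.05).
method 5 (error vs training range)
    GOOD if AAE ≤ 0.1·range and AAE + 3·SD ≤ 0.2·range; BAD if
    AAE > 0.15·range or AAE + 3·SD > 0.25·range; MODERATE otherwise.
    The multiplier ordering makes GOOD and BAD mutually exclusive.

``evaluate_model`` runs everything on raw per-compound data;
``evaluate_summary`` runs what it can from a published summary row,
marking sub-checks that need raw data (slopes, CCC, p-value) as
unavailable unless a reference row supplies the published values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .datasets import ModelDataset
from .error_stats import (
    ErrorComparison,
    ErrorSummary,
    TTestVariant,
    absolute_errors,
    compare_errors,
    error_summary,
)
from .exceptions import DegenerateInputError, InsufficientDataError, UsageError
from .metrics import ND, Eq4Convention, MetricSet, compute_metric_set, rm_squared
from .tables import SummaryRecord, Table2Reference

__all__ = [
    "METHOD_IDS",
    "SubCheck",
    "CriterionVerdict",
    "ValidationConfig",
    "ValidationReport",
    "method1_verdict",
    "method2_verdict",
    "method3_verdict",
    "method4_verdict",
    "method5_classify",
    "evaluate_model",
    "evaluate_summary",
    "batch_summary",
]

METHOD_IDS = (
    "m1_golbraikh_tropsha",
    "m2_rm2",
    "m3_ccc",
    "m4_error_ttest",
    "m5_mae_range",
)


@dataclass(frozen=True)
class SubCheck:
    """One named rule with the numeric comparison that decided it.

    ``passed`` is None when the rule could not be evaluated (summary mode
    without the needed raw-data statistic).
    """

    name: str
    passed: bool | None
    detail: str


@dataclass(frozen=True)
class CriterionVerdict:
    method_id: str
    outcome: str  # valid|invalid|unavailable for m1-m4; good|moderate|bad for m5
    subchecks: tuple[SubCheck, ...]

    def subcheck(self, name: str) -> SubCheck:
        for sc in self.subchecks:
            if sc.name == name:
                return sc
        raise KeyError(name)


def _combine(method_id: str, checks: list[SubCheck]) -> CriterionVerdict:
    """All-rules-must-pass combination with unavailable propagation."""
    if any(sc.passed is False for sc in checks):
        outcome = "invalid"
    elif any(sc.passed is None for sc in checks):
        outcome = "unavailable"
    else:
        outcome = "valid"
    return CriterionVerdict(method_id, outcome, tuple(checks))


def method1_verdict(
    r2: float,
    k: float | None,
    k_prime: float | None,
    r0sq: float,
    r0prime_sq: float,
) -> CriterionVerdict:
    """Golbraikh–Tropsha rule set (rules I–III).

    ``k``/``k_prime`` may be None (unknown, summary mode without published
    slopes); the slope rule is then marked unavailable.
    """
    for name, v in (("r2", r2), ("r0sq", r0sq), ("r0prime_sq", r0prime_sq)):
        if not math.isfinite(v):
            raise UsageError(f"{name} must be finite")
    if r2 == 0.0:
        raise DegenerateInputError("r2 = 0: rule III ratio undefined")
    checks = [
        SubCheck("r2_gt_0.6", r2 > 0.6, f"r2={r2:.3f} > 0.6 is {r2 > 0.6}")
    ]
    if k is None or k_prime is None:
        checks.append(
            SubCheck("slope_in_band", None, "K/K' unavailable in summary mode")
        )
    else:
        ok = (0.85 < k < 1.15) or (0.85 < k_prime < 1.15)
        checks.append(
            SubCheck(
                "slope_in_band",
                ok,
                f"K={k:.3f}, K'={k_prime:.3f}; 0.85 < K or K' < 1.15 is {ok}",
            )
        )
    ratio1 = (r2 - r0sq) / r2
    ratio2 = (r2 - r0prime_sq) / r2
    ok3 = ratio1 < 0.1 or ratio2 < 0.1
    checks.append(
        SubCheck(
            "ratio_lt_0.1",
            ok3,
            f"(r2-r0^2)/r2={ratio1:.3f}, (r2-r0'^2)/r2={ratio2:.3f}; "
            f"either < 0.1 is {ok3}",
        )
    )
    return _combine("m1_golbraikh_tropsha", checks)


def method2_verdict(rm2) -> CriterionVerdict:
    """Roy criterion: r²m > 0.5; ND counts as failing."""
    if rm2 is ND:
        sc = SubCheck("rm2_gt_0.5", False, "rm2 undefined (r2 < r0^2)")
    else:
        rm2 = float(rm2)
        sc = SubCheck("rm2_gt_0.5", rm2 > 0.5, f"rm2={rm2:.3f} > 0.5 is {rm2 > 0.5}")
    return _combine("m2_rm2", [sc])


def method3_verdict(ccc: float | None) -> CriterionVerdict:
    """Concordance criterion: CCC > 0.8 (strict)."""
    if ccc is None:
        sc = SubCheck("ccc_gt_0.8", None, "CCC unavailable in summary mode")
    else:
        ccc = float(ccc)
        if not -1.0 - 1e-9 <= ccc <= 1.0 + 1e-9:
            raise UsageError(f"CCC must lie in [-1, 1], got {ccc}")
        sc = SubCheck("ccc_gt_0.8", ccc > 0.8, f"CCC={ccc:.3f} > 0.8 is {ccc > 0.8}")
    return _combine("m3_ccc", [sc])


def method4_verdict(r2: float, p_value: float | None) -> CriterionVerdict:
    """Error-comparison criterion: r² > 0.6 and t-test p > 0.05."""
    if not math.isfinite(r2):
        raise UsageError("r2 must be finite")
    checks = [SubCheck("r2_gt_0.6", r2 > 0.6, f"r2={r2:.3f} > 0.6 is {r2 > 0.6}")]
    if p_value is None:
        checks.append(
            SubCheck("p_gt_0.05", None, "t-test p-value unavailable in summary mode")
        )
    else:
        p = float(p_value)
        checks.append(
            SubCheck("p_gt_0.05", p > 0.05, f"p={p:.3g} > 0.05 is {p > 0.05}")
        )
    return _combine("m4_error_ttest", checks)


def method5_classify(
    test_aae: float, test_sd: float, training_range: float
) -> CriterionVerdict:
    """Classify test-set predictivity against the training activity range.

    Thresholds scale with the training range; GOOD and BAD are mutually
    exclusive because 0.1 < 0.15 and 0.2 < 0.25.
    """
    if training_range <= 0 or not math.isfinite(training_range):
        raise DegenerateInputError(
            f"training range must be positive, got {training_range}"
        )
    if test_aae < 0 or test_sd < 0:
        raise UsageError("AAE and SD must be non-negative")
    spread = test_aae + 3.0 * test_sd
    good1 = test_aae <= 0.10 * training_range
    good2 = spread <= 0.20 * training_range
    bad1 = test_aae > 0.15 * training_range
    bad2 = spread > 0.25 * training_range
    if good1 and good2:
        outcome = "good"
    elif bad1 or bad2:
        outcome = "bad"
    else:
        outcome = "moderate"
    checks = (
        SubCheck(
            "aae_le_0.10_range",
            good1,
            f"AAE={test_aae:.3f} <= {0.10 * training_range:.3f} is {good1}",
        ),
        SubCheck(
            "aae3sd_le_0.20_range",
            good2,
            f"AAE+3SD={spread:.3f} <= {0.20 * training_range:.3f} is {good2}",
        ),
        SubCheck(
            "aae_gt_0.15_range",
            bad1,
            f"AAE={test_aae:.3f} > {0.15 * training_range:.3f} is {bad1}",
        ),
        SubCheck(
            "aae3sd_gt_0.25_range",
            bad2,
            f"AAE+3SD={spread:.3f} > {0.25 * training_range:.3f} is {bad2}",
        ),
    )
    return CriterionVerdict("m5_mae_range", outcome, checks)


@dataclass(frozen=True)
class ValidationConfig:
    """Tunable choices for a full evaluation."""

    ttest_variant: TTestVariant = TTestVariant.STUDENT
    eq4_convention: Eq4Convention = Eq4Convention.SWAPPED_CENTERED
    sd_ddof: int = 1

    def __post_init__(self):
        object.__setattr__(self, "ttest_variant", TTestVariant(self.ttest_variant))
        object.__setattr__(
            self, "eq4_convention", Eq4Convention(self.eq4_convention)
        )


@dataclass(frozen=True)
class ValidationReport:
    """Everything computed for one model: metrics, error summaries, the
    train/test comparison, and the five verdicts."""

    model_id: str
    mode: str  # "raw" or "summary"
    test_metrics: MetricSet | None
    train_errors: ErrorSummary | None
    test_errors: ErrorSummary | None
    error_comparison: ErrorComparison | None
    training_range: float
    verdicts: dict = field(default_factory=dict)

    @property
    def m5_class(self) -> str:
        return self.verdicts["m5_mae_range"].outcome


def evaluate_model(
    dataset: ModelDataset, config: ValidationConfig | None = None
) -> ValidationReport:
    """Run all five criterion families on one raw-data model."""
    config = config or ValidationConfig()
    try:
        metrics = compute_metric_set(dataset.test, config.eq4_convention)
        train_aes = absolute_errors(dataset.train)
        test_aes = absolute_errors(dataset.test)
        train_sum = error_summary(train_aes, ddof=config.sd_ddof)
        test_sum = error_summary(test_aes, ddof=config.sd_ddof)
        comparison = compare_errors(train_aes, test_aes, config.ttest_variant)
        training_range = float(dataset.train.y_exp.max() - dataset.train.y_exp.min())
        verdicts = {
            "m1_golbraikh_tropsha": method1_verdict(
                metrics.r2,
                metrics.k,
                metrics.k_prime,
                metrics.r0sq_eq3,
                metrics.r0prime_sq_eq4,
            ),
            "m2_rm2": method2_verdict(metrics.rm2),
            "m3_ccc": method3_verdict(metrics.ccc),
            "m4_error_ttest": method4_verdict(metrics.r2, comparison.p_value),
            "m5_mae_range": method5_classify(
                test_sum.aae, test_sum.sd, training_range
            ),
        }
    except (DegenerateInputError, InsufficientDataError, UsageError) as exc:
        raise type(exc)(f"model {dataset.model_id}: {exc}") from exc
    return ValidationReport(
        model_id=dataset.model_id,
        mode="raw",
        test_metrics=metrics,
        train_errors=train_sum,
        test_errors=test_sum,
        error_comparison=comparison,
        training_range=training_range,
        verdicts=verdicts,
    )


def evaluate_summary(
    record: SummaryRecord, reference: Table2Reference | None = None
) -> ValidationReport:
    """Run the criteria from a published summary row.

    The summary row carries r², the r₀² variants, error means/SDs and the
    training range; slopes, CCC and the p-value need raw data and are
    taken from the published ``reference`` row when given, else marked
    unavailable. r²m is recomputed from r² and the forward r₀².
    """
    k = reference.k if reference else None
    k_prime = reference.k_prime if reference else None
    ccc = reference.ccc if reference else None
    p_value = reference.p_value if reference else None
    rm2 = rm_squared(record.r2, record.r0sq_eq3)
    verdicts = {
        "m1_golbraikh_tropsha": method1_verdict(
            record.r2, k, k_prime, record.r0sq_eq3, record.r0prime_sq_eq4
        ),
        "m2_rm2": method2_verdict(rm2),
        "m3_ccc": method3_verdict(ccc),
        "m4_error_ttest": method4_verdict(record.r2, p_value),
        "m5_mae_range": method5_classify(
            record.aae_test, record.sd_test, record.training_range
        ),
    }
    metrics = MetricSet(
        r2=record.r2,
        k=math.nan if k is None else k,
        k_prime=math.nan if k_prime is None else k_prime,
        r0sq_eq3=record.r0sq_eq3,
        r0prime_sq_eq4=record.r0prime_sq_eq4,
        r0sq_eq5=record.r0sq_eq5,
        rm2=rm2,
        ccc=math.nan if ccc is None else ccc,
        convention_eq4=Eq4Convention.PRINTED,
        pearson_sign=1,
    )
    train_errors = ErrorSummary(
        aae=record.aae_train, sd=record.sd_train, n=record.n_train, bins=None
    )
    test_errors = ErrorSummary(
        aae=record.aae_test, sd=record.sd_test, n=record.n_test, bins=None
    )
    comparison = (
        None
        if p_value is None
        else ErrorComparison(math.nan, float(p_value), TTestVariant.STUDENT)
    )
    return ValidationReport(
        model_id=record.model_id,
        mode="summary",
        test_metrics=metrics,
        train_errors=train_errors,
        test_errors=test_errors,
        error_comparison=comparison,
        training_range=record.training_range,
        verdicts=verdicts,
    )


def _percent(count: int, total: int) -> int:
    return int(math.floor(100.0 * count / total + 0.5))


def batch_summary(reports) -> dict:
    """Valid/invalid counts per criterion, method-5 class percentages, and
    pairwise criterion-agreement counts for a batch of reports."""
    reports = list(reports)
    if not reports:
        raise InsufficientDataError("batch_summary requires at least one report")
    n = len(reports)
    out: dict = {"n_models": n}
    for mid in METHOD_IDS[:4]:
        counts = {"valid": 0, "invalid": 0, "unavailable": 0}
        for rep in reports:
            counts[rep.verdicts[mid].outcome] += 1
        out[mid] = counts
    m5 = {"good": 0, "moderate": 0, "bad": 0}
    for rep in reports:
        m5[rep.verdicts["m5_mae_range"].outcome] += 1
    out["m5_mae_range"] = dict(m5)
    out["m5_percent"] = {k: _percent(v, n) for k, v in m5.items()}
    out["r2_below_0.6"] = sum(
        1 for rep in reports if rep.test_metrics.r2 < 0.6
    )
    agreement = {}
    for i, a in enumerate(METHOD_IDS[:4]):
        for b in METHOD_IDS[i + 1 : 4]:
            agreement[f"{a}&{b}"] = sum(
                1
                for rep in reports
                if rep.verdicts[a].outcome == "valid"
                and rep.verdicts[b].outcome == "valid"
            )
    out["both_valid"] = agreement
    return out
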