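"""Report serialization and rendering.

All internal computation is kept in full floating precision; rounding to
the published 2–3 decimal places happens here, half-away-from-zero. The
ND sentinel renders literally as ``"ND"``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from .criteria import CriterionVerdict, SubCheck, ValidationReport
from .error_stats import ErrorComparison, ErrorSummary, TTestVariant
from .exceptions import UsageError
from .metrics import ND, Eq4Convention, MetricSet

__all__ = [
    "round_half_away",
    "render_number",
    "report_to_dict",
    "report_from_dict",
    "table2_row",
    "write_report",
    "read_report",
]

TSV_COLUMNS = (
    "model",
    "r2",
    "k",
    "k_prime",
    "ratio1",
    "ratio2",
    "rm2",
    "ccc",
    "p_value",
    "m1",
    "m2",
    "m3",
    "m4",
    "aae_train",
    "sd_train",
    "aae_test",
    "sd_test",
    "training_range",
    "aae_plus_3sd",
    "x010",
    "x020",
    "x015",
    "x025",
    "m5_class",
)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (the convention of the
    published tables), unlike Python's banker's rounding."""
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def render_number(value, ndigits: int = 2) -> str:
    """Format a metric at reporting precision; ND and NaN render as ND."""
    if value is ND:
        return "ND"
    value = float(value)
    if math.isnan(value):
        return "ND"
    return f"{round_half_away(value, ndigits):.{ndigits}f}"


def _scalar(value):
    if value is ND:
        return "ND"
    if isinstance(value, float) and math.isnan(value):
        return None
    if hasattr(value, "value") and isinstance(value, (Eq4Convention, TTestVariant)):
        return value.value
    return value


def report_to_dict(report: ValidationReport) -> dict:
    """JSON-serializable dictionary form of a report (lossless except for
    NaN placeholders, which become null)."""
    m = report.test_metrics
    out = {
        "model_id": report.model_id,
        "mode": report.mode,
        "training_range": report.training_range,
        "test_metrics": None
        if m is None
        else {
            "r2": m.r2,
            "k": _scalar(m.k),
            "k_prime": _scalar(m.k_prime),
            "r0sq_eq3": m.r0sq_eq3,
            "r0prime_sq_eq4": m.r0prime_sq_eq4,
            "r0sq_eq5": m.r0sq_eq5,
            "rm2": _scalar(m.rm2),
            "ccc": _scalar(m.ccc),
            "convention_eq4": m.convention_eq4.value,
            "pearson_sign": m.pearson_sign,
        },
        "train_errors": _errors_to_dict(report.train_errors),
        "test_errors": _errors_to_dict(report.test_errors),
        "error_comparison": None
        if report.error_comparison is None
        else {
            "t_statistic": _scalar(report.error_comparison.t_statistic),
            "p_value": report.error_comparison.p_value,
            "variant": report.error_comparison.variant.value,
            "sidedness": report.error_comparison.sidedness,
        },
        "verdicts": {
            mid: {
                "method_id": v.method_id,
                "outcome": v.outcome,
                "subchecks": [
                    {"name": sc.name, "passed": sc.passed, "detail": sc.detail}
                    for sc in v.subchecks
                ],
            }
            for mid, v in report.verdicts.items()
        },
    }
    return out


def _errors_to_dict(summary: ErrorSummary | None):
    if summary is None:
        return None
    return {
        "aae": summary.aae,
        "sd": summary.sd,
        "n": summary.n,
        "bins": None if summary.bins is None else list(summary.bins),
    }


def _errors_from_dict(d):
    if d is None:
        return None
    return ErrorSummary(
        aae=d["aae"],
        sd=d["sd"],
        n=d["n"],
        bins=None if d["bins"] is None else tuple(d["bins"]),
    )


def _metric_back(value):
    if value == "ND":
        return ND
    if value is None:
        return math.nan
    return value


def report_from_dict(d: dict) -> ValidationReport:
    """Reconstruct a report written by :func:`report_to_dict`."""
    m = d["test_metrics"]
    metrics = None
    if m is not None:
        metrics = MetricSet(
            r2=m["r2"],
            k=_metric_back(m["k"]),
            k_prime=_metric_back(m["k_prime"]),
            r0sq_eq3=m["r0sq_eq3"],
            r0prime_sq_eq4=m["r0prime_sq_eq4"],
            r0sq_eq5=m["r0sq_eq5"],
            rm2=_metric_back(m["rm2"]),
            ccc=_metric_back(m["ccc"]),
            convention_eq4=Eq4Convention(m["convention_eq4"]),
            pearson_sign=m["pearson_sign"],
        )
    comp = d["error_comparison"]
    comparison = None
    if comp is not None:
        comparison = ErrorComparison(
            t_statistic=math.nan
            if comp["t_statistic"] is None
            else comp["t_statistic"],
            p_value=comp["p_value"],
            variant=TTestVariant(comp["variant"]),
            sidedness=comp["sidedness"],
        )
    verdicts = {
        mid: CriterionVerdict(
            method_id=v["method_id"],
            outcome=v["outcome"],
            subchecks=tuple(
                SubCheck(sc["name"], sc["passed"], sc["detail"])
                for sc in v["subchecks"]
            ),
        )
        for mid, v in d["verdicts"].items()
    }
    return ValidationReport(
        model_id=d["model_id"],
        mode=d["mode"],
        test_metrics=metrics,
        train_errors=_errors_from_dict(d["train_errors"]),
        test_errors=_errors_from_dict(d["test_errors"]),
        error_comparison=comparison,
        training_range=d["training_range"],
        verdicts=verdicts,
    )


def table2_row(report: ValidationReport) -> dict:
    """One published-layout row (rendered strings) for a report."""
    m = report.test_metrics
    r = report.training_range
    ratio1 = (m.r2 - m.r0sq_eq3) / m.r2
    ratio2 = (m.r2 - m.r0prime_sq_eq4) / m.r2
    te = report.test_errors
    p = (
        None
        if report.error_comparison is None
        else report.error_comparison.p_value
    )
    short = {
        "m1": "m1_golbraikh_tropsha",
        "m2": "m2_rm2",
        "m3": "m3_ccc",
        "m4": "m4_error_ttest",
    }
    row = {
        "model": report.model_id,
        "r2": render_number(m.r2, 3),
        "k": render_number(m.k, 2),
        "k_prime": render_number(m.k_prime, 2),
        "ratio1": render_number(ratio1, 3),
        "ratio2": render_number(ratio2, 3),
        "rm2": render_number(m.rm2, 2),
        "ccc": render_number(m.ccc, 2),
        "p_value": "ND" if p is None else render_number(p, 2),
        **{col: report.verdicts[mid].outcome for col, mid in short.items()},
        "aae_train": "ND"
        if report.train_errors is None
        else render_number(report.train_errors.aae, 3),
        "sd_train": "ND"
        if report.train_errors is None
        else render_number(report.train_errors.sd, 3),
        "aae_test": render_number(te.aae, 3),
        "sd_test": render_number(te.sd, 3),
        "training_range": render_number(r, 2),
        "aae_plus_3sd": render_number(te.aae + 3.0 * te.sd, 2),
        "x010": render_number(0.10 * r, 2),
        "x020": render_number(0.20 * r, 2),
        "x015": render_number(0.15 * r, 2),
        "x025": render_number(0.25 * r, 2),
        "m5_class": {"good": "G", "moderate": "M", "bad": "B"}[report.m5_class],
    }
    return row


def write_report(report_or_batch, path=None, fmt: str = "json") -> str:
    """Serialize one report (or a batch) as JSON or published-layout TSV.

    Returns the serialized text; writes it to ``path`` when given.
    """
    if isinstance(report_or_batch, ValidationReport):
        batch = [report_or_batch]
        single = True
    else:
        batch = list(report_or_batch)
        single = False
    if fmt == "json":
        payload = report_to_dict(batch[0]) if single else [
            report_to_dict(rep) for rep in batch
        ]
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
    elif fmt == "tsv":
        lines = ["\t".join(TSV_COLUMNS)]
        for rep in batch:
            row = table2_row(rep)
            lines.append("\t".join(str(row[c]) for c in TSV_COLUMNS))
        text = "\n".join(lines) + "\n"
    else:
        raise UsageError(f"unknown report format {fmt!r}; expected json or tsv")
    if path is not None:
        Path(path).write_text(text)
    return text


def read_report(path):
    """Read back a JSON report (or list of reports)."""
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, list):
        return [report_from_dict(d) for d in payload]
    return report_from_dict(payload)
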