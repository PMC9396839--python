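"""No-download reproduction of the 44-model comparison.

From the embedded summary table alone, every derivable quantity of the
published comparison is recomputed: the rule-III ratio terms, r²m, the
AAE+3SD and range-multiple columns, the method-5 letter, and — using the
published slopes, CCC and p-values as inputs where raw data would be
needed — the method 1–4 verdicts and their headline counts.
"""

from __future__ import annotations

import pandas as pd

from .criteria import evaluate_summary
from .metrics import ND, rm_squared
from .tables import load_table1_fixture, load_table2_reference

__all__ = ["reproduce_table2", "headline_counts", "method1_invalid_count"]

_OUTCOME_LETTER = {"good": "G", "moderate": "M", "bad": "B"}


def reproduce_table2() -> pd.DataFrame:
    """Recompute the derived columns and verdicts for all 44 models.

    Returns a full-precision DataFrame (one row per model) with recomputed
    quantities alongside the published reference values; rendering to the
    published precision is left to the report writer.
    """
    rows = []
    for rec, ref in zip(load_table1_fixture(), load_table2_reference()):
        rep = evaluate_summary(rec, ref)
        rm2 = rm_squared(rec.r2, rec.r0sq_eq3)
        rows.append(
            {
                "model": int(rec.model_id),
                "r2": rec.r2,
                "k": ref.k,
                "k_prime": ref.k_prime,
                "ratio1": (rec.r2 - rec.r0sq_eq3) / rec.r2,
                "ratio2": (rec.r2 - rec.r0prime_sq_eq4) / rec.r2,
                "rm2": float("nan") if rm2 is ND else rm2,
                "rm2_is_nd": rm2 is ND,
                "ccc_ref": ref.ccc,
                "p_value_ref": ref.p_value,
                "aae_plus_3sd": rec.aae_test + 3.0 * rec.sd_test,
                "x010": 0.10 * rec.training_range,
                "x020": 0.20 * rec.training_range,
                "x015": 0.15 * rec.training_range,
                "x025": 0.25 * rec.training_range,
                "m1": rep.verdicts["m1_golbraikh_tropsha"].outcome,
                "m2": rep.verdicts["m2_rm2"].outcome,
                "m3": rep.verdicts["m3_ccc"].outcome,
                "m4": rep.verdicts["m4_error_ttest"].outcome,
                "m5_class": _OUTCOME_LETTER[rep.m5_class],
                "m5_class_published": ref.m5_class,
            }
        )
    return pd.DataFrame(rows).set_index("model", drop=False)


def headline_counts(frame: pd.DataFrame | None = None) -> dict:
    """The comparison's headline counts, recomputed from the fixture."""
    df = reproduce_table2() if frame is None else frame
    n = len(df)
    published = df["m5_class_published"].value_counts()
    recomputed = df["m5_class"].value_counts()
    return {
        "n_models": n,
        "r2_below_0.6": int((df["r2"] < 0.6).sum()),
        "m1_invalid": int((df["m1"] == "invalid").sum()),
        "m2_valid": int((df["m2"] == "valid").sum()),
        "m3_valid": int((df["m3"] == "valid").sum()),
        "m4_valid": int((df["m4"] == "valid").sum()),
        "m3_and_m4_valid": int(
            ((df["m3"] == "valid") & (df["m4"] == "valid")).sum()
        ),
        "m5_counts": {c: int(recomputed.get(c, 0)) for c in "GMB"},
        "m5_counts_published": {c: int(published.get(c, 0)) for c in "GMB"},
        "m5_percent_published": {
            c: round(100.0 * published.get(c, 0) / n) for c in "GMB"
        },
    }


def method1_invalid_count() -> int:
    """Number of the 44 models failing the full Golbraikh–Tropsha rule set."""
    return headline_counts()["m1_invalid"]
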