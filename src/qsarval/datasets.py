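"""Reading, writing and sanity-checking per-model activity datasets.

The on-disk format is a single CSV per model with a fixed header::

    compound_id,split,y_exp,y_calc

``split`` is ``train`` or ``test``; activities are unitless log-scale
values with period decimals, UTF-8, comma-separated. A tolerant converter
for two-column (experimental, calculated) per-split files is provided for
data published in looser layouts.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .error_stats import absolute_errors
from .exceptions import InsufficientDataError, SchemaError
from .pairs import ActivityPairs

__all__ = [
    "ModelDataset",
    "Issue",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "convert_split_files",
]

REQUIRED_COLUMNS = ("compound_id", "split", "y_exp", "y_calc")
SPLIT_LABELS = ("train", "test")


@dataclass(frozen=True)
class ModelDataset:
    """A training split, a test split and provenance for one QSAR model."""

    model_id: str
    train: ActivityPairs
    test: ActivityPairs
    source: str = ""

    def __post_init__(self):
        self.train.require_n(3, f"model {self.model_id} training split")
        self.test.require_n(3, f"model {self.model_id} test split")
        shared = set(self.train.ids) & set(self.test.ids)
        if shared:
            raise SchemaError(
                f"model {self.model_id}: compound ids appear in both splits "
                f"(test-set leakage): {sorted(shared)[:5]}"
            )

    @property
    def training_range(self) -> float:
        """Max minus min of the training split's experimental activity."""
        return float(self.train.y_exp.max() - self.train.y_exp.min())


def read_dataset(path, *, model_id: str | None = None) -> ModelDataset:
    """Parse and validate one model CSV.

    Raises :class:`SchemaError` for missing columns, unknown split labels
    or non-numeric activities (with the offending row number), and
    :class:`InsufficientDataError` when either split has fewer than 3 rows.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    bad_splits = sorted(set(frame["split"]) - set(SPLIT_LABELS))
    if bad_splits:
        raise SchemaError(
            f"{path}: unknown split label(s) {bad_splits}; expected "
            f"{list(SPLIT_LABELS)}"
        )
    for col in ("y_exp", "y_calc"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() | ~np.isfinite(numeric)
        if bad.any():
            # +2: one for the header line, one for zero-based indexing
            row = int(bad.idxmax()) + 2
            raise SchemaError(
                f"{path}: non-numeric {col} value {frame[col][bad.idxmax()]!r} "
                f"at line {row}"
            )
        frame[col] = numeric
    splits = {}
    for label in SPLIT_LABELS:
        part = frame[frame["split"] == label]
        if len(part) < 3:
            raise InsufficientDataError(
                f"{path}: {label} split has {len(part)} rows, need at least 3"
            )
        splits[label] = ActivityPairs(
            part["y_exp"].to_numpy(),
            part["y_calc"].to_numpy(),
            ids=tuple(part["compound_id"]),
        )
    return ModelDataset(
        model_id=model_id or path.stem,
        train=splits["train"],
        test=splits["test"],
        source=str(path),
    )


def write_dataset(dataset: ModelDataset, path) -> None:
    """Write a dataset back to the standard CSV schema."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(REQUIRED_COLUMNS)
        for label, pairs in (("train", dataset.train), ("test", dataset.test)):
            ids = pairs.ids or [f"{label[0].upper()}{i + 1}" for i in range(pairs.n)]
            for cid, ye, yc in zip(ids, pairs.y_exp, pairs.y_pred):
                writer.writerow([cid, label, repr(float(ye)), repr(float(yc))])


@dataclass(frozen=True)
class Issue:
    """A data-quality warning. Issues are data, not exceptions."""

    kind: str
    split: str
    message: str


def validate_dataset(dataset: ModelDataset) -> list[Issue]:
    """Screen a parsed dataset for common data problems.

    Flags duplicated compound ids within a split, constant activity
    columns, and extreme absolute-error outliers (AE > mean + 3·SD),
    which in published datasets usually trace back to typographic errors
    in the source activities.
    """
    issues: list[Issue] = []
    for label in SPLIT_LABELS:
        pairs: ActivityPairs = getattr(dataset, label)
        if pairs.ids:
            seen: dict = {}
            for cid in pairs.ids:
                seen[cid] = seen.get(cid, 0) + 1
            for cid, count in seen.items():
                if count > 1:
                    issues.append(
                        Issue(
                            "duplicate_id",
                            label,
                            f"compound id {cid!r} appears {count} times",
                        )
                    )
        for name, vec in (("y_exp", pairs.y_exp), ("y_calc", pairs.y_pred)):
            if np.ptp(vec) == 0:
                issues.append(
                    Issue("constant_column", label, f"{name} is constant ({vec[0]})")
                )
        aes = absolute_errors(pairs)
        if aes.size >= 3 and aes.std(ddof=1) > 0:
            cut = aes.mean() + 3.0 * aes.std(ddof=1)
            for idx in np.nonzero(aes > cut)[0]:
                cid = pairs.ids[idx] if pairs.ids else f"row {idx}"
                issues.append(
                    Issue(
                        "ae_outlier",
                        label,
                        f"compound {cid}: AE {aes[idx]:.3f} exceeds "
                        f"mean+3SD ({cut:.3f})",
                    )
                )
    return issues


_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _read_two_column(path) -> tuple[np.ndarray, np.ndarray]:
    """Tolerant reader for a per-split file of (experimental, calculated)
    pairs: comma, tab or whitespace separated, with or without a header."""
    rows = []
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = [p for p in re.split(r"[,\t;]+|\s+", line) if p]
        if len(parts) < 2:
            raise SchemaError(f"{path}: line {line_no}: expected two columns")
        if not (_NUMBER_RE.match(parts[0]) and _NUMBER_RE.match(parts[1])):
            if line_no == 1:  # header line
                continue
            raise SchemaError(f"{path}: line {line_no}: non-numeric values {parts[:2]}")
        rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise SchemaError(f"{path}: no numeric rows found")
    arr = np.asarray(rows)
    return arr[:, 0], arr[:, 1]


def convert_split_files(train_path, test_path, out_path, model_id="converted") -> ModelDataset:
    """Convert two loose per-split files into the standard CSV schema."""
    tr_exp, tr_calc = _read_two_column(train_path)
    te_exp, te_calc = _read_two_column(test_path)
    dataset = ModelDataset(
        model_id=model_id,
        train=ActivityPairs(
            tr_exp, tr_calc, ids=tuple(f"T{i + 1}" for i in range(tr_exp.size))
        ),
        test=ActivityPairs(
            te_exp, te_calc, ids=tuple(f"E{i + 1}" for i in range(te_exp.size))
        ),
        source=f"{train_path} + {test_path}",
    )
    write_dataset(dataset, out_path)
    return dataset
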