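"""Diagnostic figures: absolute-error frequency bars and residual scatter.

matplotlib is imported lazily so the computational API has no hard
plotting dependency.
"""

from __future__ import annotations

from .error_stats import residuals
from .pairs import ActivityPairs

__all__ = ["ae_frequency_chart", "residual_plot"]

_BIN_LABELS = ("< 0.1", "0.1–0.2", "> 0.2")


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def ae_frequency_chart(train_bins, test_bins, path, title: str = "") -> None:
    """Grouped bar chart of the three AE subgroups for both splits.

    ``train_bins``/``test_bins`` are the bin proportions from
    :func:`~qsarval.error_stats.frequency_bins` (fractions; rendered as
    percentages).
    """
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = range(len(_BIN_LABELS))
    width = 0.35
    ax.bar(
        [i - width / 2 for i in x],
        [100 * b for b in train_bins],
        width,
        label="training set",
    )
    ax.bar(
        [i + width / 2 for i in x],
        [100 * b for b in test_bins],
        width,
        label="test set",
    )
    ax.set_xticks(list(x), _BIN_LABELS)
    ax.set_xlabel("absolute error (log units)")
    ax.set_ylabel("relative frequency (%)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def residual_plot(
    train: ActivityPairs, test: ActivityPairs, path, title: str = ""
) -> None:
    """Signed residuals (experimental − calculated) against experimental
    activity for both splits."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(
        train.y_exp, residuals(train), s=18, alpha=0.7, label="training set"
    )
    ax.scatter(
        test.y_exp, residuals(test), s=26, marker="s", alpha=0.8, label="test set"
    )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("experimental activity")
    ax.set_ylabel("residual (exp − calc)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
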