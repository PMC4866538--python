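"""Simple diagnostic figures for scan output."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def pvalue_histogram(results: pd.DataFrame, path: str | Path,
                     bins: int = 50) -> None:
    """Histogram of per-variant p-values; a healthy null is flat."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(results["p"], bins=bins, range=(0, 1), color="#4878a8",
            edgecolor="white")
    ax.axhline(len(results) / bins, color="grey", ls="--", lw=1,
               label="uniform expectation")
    ax.set_xlabel("GLMM p-value")
    ax.set_ylabel("variants")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def manhattan_windows(windows: pd.DataFrame, path: str | Path,
                      alpha: float = 0.05) -> None:
    """Window -log10(p) along the genome, significant windows highlighted."""
    fig, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    ticks, labels = [], []
    for arm, sub in windows.groupby("arm", sort=False):
        x = (sub["start"] + sub["end"]) / 2 + offset
        y = -np.log10(np.maximum(sub["p"], 1e-300))
        sig = sub["significant"] if "significant" in sub else \
            sub["p"] < alpha
        ax.scatter(x[~sig], y[~sig], s=6, color="#9aa5b1")
        ax.scatter(x[sig], y[sig], s=10, color="#c0392b")
        ticks.append(offset + (sub["end"].max()) / 2)
        labels.append(str(arm))
        offset += sub["end"].max() + 1
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels)
    ax.set_ylabel("-log10 window p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
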