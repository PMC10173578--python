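"""Minimal forest-style plotting for MR result tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def forest_mediation(frame: pd.DataFrame, path: str | Path) -> None:
    """Forest plot of total/direct ORs with the PM annotated per row."""
    import numpy as np

    n = len(frame)
    fig, ax = plt.subplots(figsize=(7, 1 + 0.6 * n))
    y = np.arange(n)[::-1]
    ax.errorbar(frame["total_or"], y + 0.15, fmt="o", color="C0", label="total OR")
    ax.errorbar(frame["direct_or"], y - 0.15, fmt="s", color="C1", label="direct OR")
    for yi, (_, row) in zip(y, frame.iterrows()):
        ax.annotate(f"PM {row['pm_percent']:.2f}%", (1.02, yi),
                    xycoords=("axes fraction", "data"), fontsize=8)
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(frame["mediators"])
    ax.set_xlabel("odds ratio")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def forest_univariable(frame: pd.DataFrame, path: str | Path) -> None:
    """Forest plot of one row per exposure-outcome-method estimate."""
    import numpy as np

    n = len(frame)
    fig, ax = plt.subplots(figsize=(7, 1 + 0.4 * n))
    y = np.arange(n)[::-1]
    mid = frame.get("or", frame["beta"])
    lo = frame.get("or_ci_low", frame["ci_low"])
    hi = frame.get("or_ci_high", frame["ci_high"])
    ax.errorbar(mid, y, xerr=[mid - lo, hi - mid], fmt="o", color="C0", ms=3, lw=1)
    ref = 1.0 if "or" in frame else 0.0
    ax.axvline(ref, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    labels = frame["exposure"].astype(str) + "->" + frame["outcome"].astype(str) \
        + " (" + frame["method"] + ")"
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xlabel("odds ratio" if "or" in frame else "beta")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
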