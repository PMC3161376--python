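"""Matplotlib renderings of the standard result displays.

Forest plot with the unadjusted companion grayed out, CEAC, and tornado
with the stochastic reference bar at the bottom.  All functions return
the figure; pass ``path`` to also write it to disk.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evidence import MetaResult, forest_data
from .influence import TornadoResult


def _save(fig, path):
    if path is not None:
        fig.savefig(Path(path), bbox_inches="tight", dpi=150)
    return fig


def forest_plot(result: MetaResult, path: str | Path | None = None):
    """Forest plot on the OR scale; adjusted in black, unadjusted grayed."""
    table = forest_data(result)
    adj = table[table["variant"] == "adjusted"].reset_index(drop=True)
    unadj = table[table["variant"] == "unadjusted"].reset_index(drop=True)
    n = len(adj)
    fig, ax = plt.subplots(figsize=(6, 0.5 * n + 1.5))
    ys = np.arange(n)[::-1]
    for frame, color, offset in ((unadj, "0.7", 0.18), (adj, "black", 0.0)):
        if frame.empty:
            continue
        ax.errorbar(
            frame["or"], ys + offset,
            xerr=[frame["or"] - frame["or_low"], frame["or_high"] - frame["or"]],
            fmt="s", color=color, ecolor=color, capsize=2, markersize=4,
        )
    ax.axvline(1.0, color="0.5", linewidth=0.8, linestyle="--")
    ax.set_yticks(ys)
    ax.set_yticklabels(adj["row"])
    ax.set_xscale("log")
    ax.set_xlabel("Odds ratio (log scale)")
    ax.set_title(f"Meta-analysis ({result.method}); gray = unadjusted")
    fig.tight_layout()
    return _save(fig, path)


def ceac_plot(ceac_df: pd.DataFrame, path: str | Path | None = None):
    """One acceptability curve per (strategy, treatment) alternative."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col in ceac_df.columns:
        label = f"strategy {col[0]}, {col[1]}" if isinstance(col, tuple) else str(col)
        ax.plot(ceac_df.index, ceac_df[col], label=label)
    ax.set_xlabel("Willingness to pay per QALY")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    return _save(fig, path)


def tornado_plot(result: TornadoResult, path: str | Path | None = None):
    """Horizontal tornado; widest bars on top, PSA reference bar at the bottom.

    Bars narrower than 1e-12 of the outcome scale are left out of the plot
    (they remain in the tabular output), as are ICER bars flagged
    non-interpretable.
    """
    bars = [
        b
        for b in result.sorted_bars()
        if b.interpretable and b.width > 1e-12 * max(1.0, abs(result.base_outcome))
    ]
    n = len(bars) + (1 if result.reference is not None else 0)
    fig, ax = plt.subplots(figsize=(7, 0.45 * max(n, 1) + 1.2))
    ys = np.arange(len(bars))[::-1]
    for y, b in zip(ys, bars):
        lo, hi = sorted((b.outcome_low, b.outcome_high))
        ax.barh(y, hi - lo, left=lo, height=0.6, color="#4878a8")
        ax.plot([b.base_outcome], [y], "k|", markersize=10)
    labels = [b.parameter for b in bars]
    if result.reference is not None:
        mean, interval = result.reference
        y_ref = -1.2
        if interval is not None:
            ax.plot(interval, [y_ref, y_ref], color="0.3", linewidth=2)
        ax.plot([mean], [y_ref], "o", color="0.3")
        ax.axhline(-0.6, color="0.8", linewidth=0.8)
        ax.set_yticks(list(ys) + [y_ref])
        ax.set_yticklabels(labels + ["PSA reference"])
    else:
        ax.set_yticks(ys)
        ax.set_yticklabels(labels)
    ax.axvline(result.base_outcome, color="0.6", linewidth=0.8, linestyle="--")
    ax.set_xlabel(result.outcome_label)
    fig.tight_layout()
    return _save(fig, path)
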