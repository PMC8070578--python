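"""Agreement plots: method-comparison scatter with line of unity, and
Bland-Altman plots with bias and 1.96-SD limits of agreement."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import BlandAltmanResult, bland_altman


def scatter_with_unity(x, y, xlabel="method 1", ylabel="method 2", ax=None):
    """Scatter of paired scores with the line of unity (perfect agreement)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ax.scatter(x, y, s=18, alpha=0.7, edgecolor="none")
    lo = min(x.min(), y.min()) - 1
    hi = max(x.max(), y.max()) + 1
    ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="line of unity")
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_aspect("equal")
    ax.legend(frameon=False)
    return ax


def bland_altman_plot(x=None, y=None, result: BlandAltmanResult | None = None, ax=None, title=None):
    """Bland-Altman plot: per-pair mean vs difference, bias and LoA lines."""
    if result is None:
        result = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4))
    ax.scatter(result.means, result.differences, s=18, alpha=0.7, edgecolor="none")
    ax.axhline(result.bias, color="k", lw=1, label=f"bias = {result.bias:.2f}")
    for v, lab in ((result.loa_low, "-1.96 SD"), (result.loa_high, "+1.96 SD")):
        ax.axhline(v, color="k", lw=1, ls="--")
        ax.annotate(f"{lab} = {v:.2f}", (0.99, v), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title, fontsize=10)
    return ax
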