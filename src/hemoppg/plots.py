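"""Optional diagnostic plots (scatter, Bland-Altman, error grid)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .evaluate import bland_altman, error_grid


def _axes():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def scatter_plot(y_ref, y_pred, path: str | Path) -> None:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(4, 4))
    lim = (min(np.min(y_ref), np.min(y_pred)) - 1, max(np.max(y_ref), np.max(y_pred)) + 1)
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.scatter(y_ref, y_pred, s=12, alpha=0.7)
    ax.set_xlabel("Reference Hb (g/dL)")
    ax.set_ylabel("Estimated Hb (g/dL)")
    ax.set_xlim(lim), ax.set_ylim(lim)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def bland_altman_plot(y_ref, y_pred, path: str | Path) -> None:
    plt = _axes()
    ba = bland_altman(y_ref, y_pred)
    mean_val = (np.asarray(y_ref) + np.asarray(y_pred)) / 2
    diff = np.asarray(y_pred) - np.asarray(y_ref)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(mean_val, diff, s=12, alpha=0.7)
    for level, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(level, color="r", ls=style, lw=0.8)
    ax.set_xlabel("Mean Hb (g/dL)")
    ax.set_ylabel("Estimated - reference (g/dL)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def error_grid_plot(y_ref, y_pred, path: str | Path) -> None:
    plt = _axes()
    pct, labels = error_grid(y_ref, y_pred)
    colors = {"A": "tab:green", "B": "tab:orange", "C": "tab:red"}
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    lo = min(np.min(y_ref), np.min(y_pred)) - 1
    hi = max(np.max(y_ref), np.max(y_pred)) + 1
    grid = np.linspace(lo, hi, 2)
    for off, style in ((0, "-"), (1, "--"), (2, ":")):
        ax.plot(grid, grid + off, "k" + style, lw=0.7)
        if off:
            ax.plot(grid, grid - off, "k" + style, lw=0.7)
    for z in "ABC":
        m = labels == z
        ax.scatter(np.asarray(y_ref)[m], np.asarray(y_pred)[m], s=12,
                   color=colors[z], label=f"{z}: {pct['ABC'.index(z)]:.1f}%")
    ax.legend(loc="upper left", fontsize=8)
    ax.set_xlabel("Reference Hb (g/dL)")
    ax.set_ylabel("Estimated Hb (g/dL)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
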