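"""Cosmetic figures for the sensitivity analyses (PNG export)."""

from __future__ import annotations

from pathlib import Path

from .uncertainty import PSAResult, TornadoResult

__all__ = ["plot_bcr_histogram", "plot_tornado"]


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_bcr_histogram(result: PSAResult, path: str | Path, width: float = 1.0):
    """Histogram of simulated benefit-cost ratios (unit-width bins)."""
    plt = _axes()
    hist = result.bcr_histogram(width)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(hist["bin_left"], hist["count"], width=width, align="edge", edgecolor="white")
    ax.axvline(result.base_bcr, color="k", linestyle="--", label=f"base case {result.base_bcr:.2f}")
    ax.set_xlabel("benefit-cost ratio")
    ax.set_ylabel("draws")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(result: TornadoResult, path: str | Path):
    """Horizontal tornado bars around the base-case BCR."""
    plt = _axes()
    t = result.table.iloc[::-1]  # largest swing on top
    fig, ax = plt.subplots(figsize=(7, 4))
    lo = t[["bcr_low", "bcr_high"]].min(axis=1)
    hi = t[["bcr_low", "bcr_high"]].max(axis=1)
    ax.barh(t["parameter"], hi - lo, left=lo, color="steelblue")
    ax.axvline(result.base_bcr, color="k", linestyle="--")
    ax.set_xlabel("benefit-cost ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
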