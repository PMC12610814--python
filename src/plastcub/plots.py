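"""Diagnostic figures: ENC-plot, ENC-ratio histogram, PR2 and neutrality."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .indices import enc_expected

__all__ = ["enc_plot_figure", "enc_ratio_histogram", "pr2_figure",
           "neutrality_figure"]


def enc_plot_figure(result, path=None):
    """Observed ENC against GC3 with the expected null curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    t = result.table
    ax.scatter(t["GC3"], t["ENC"], s=14, alpha=0.7, label="genes")
    x = np.linspace(0.001, 0.999, 200)
    ax.plot(x, [enc_expected(v) for v in x], "k-", lw=1, label="expected")
    ax.set_xlabel("GC3")
    ax.set_ylabel("ENC")
    ax.set_ylim(15, 65)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def enc_ratio_histogram(result, path=None):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(result.table["ENC_ratio"], bins=20, edgecolor="k")
    ax.axvline(-result.window, color="r", ls="--", lw=1)
    ax.axvline(result.window, color="r", ls="--", lw=1)
    ax.set_xlabel("ENC ratio (expected - observed)/expected")
    ax.set_ylabel("genes")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def pr2_figure(points, path=None):
    """PR2 scatter with the quadrant lines through the unbiased centre."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(points["x"], points["y"], s=14, alpha=0.7)
    ax.axhline(0.5, color="k", lw=0.8)
    ax.axvline(0.5, color="k", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3/(G3+C3)")
    ax.set_ylabel("A3/(A3+T3)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def neutrality_figure(result, path=None):
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    t = result.table
    ax.scatter(t["GC3"], t["GC12"], s=14, alpha=0.7)
    lim = (0, max(1.0, t[["GC3", "GC12"]].max().max()))
    x = np.linspace(*lim, 50)
    ax.plot(x, x, "k--", lw=0.8, label="y = x")
    if np.isfinite(result.slope):
        ax.plot(x, result.intercept + result.slope * x, "r-", lw=1,
                label=f"fit: slope {result.slope:.2f}")
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
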