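"""Convenience plots; the CSV tables remain the source of record."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _pyplot():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_ld_decay(decay: pd.DataFrame, path: str) -> None:
    """Mean r² per distance bin, one line per population."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for pop, df in decay.groupby("population"):
        lo = df["lo_mb"].to_numpy()
        hi = df["hi_mb"].to_numpy()
        mid = np.where(np.isinf(hi), lo + 0.15, (lo + hi) / 2)
        ax.plot(mid, df["mean_r2"], marker="o", ms=3, label=pop)
    ax.set_xlabel("distance (Mb)")
    ax.set_ylabel("mean $r^2$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ne(trajectories: pd.DataFrame, path: str) -> None:
    """Ancestral Ne over generations ago, one line per population."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for pop, df in trajectories.groupby("population"):
        ok = df["ne"].notna()
        ax.plot(df.loc[ok, "t"], df.loc[ok, "ne"], marker="o", ms=3, label=pop)
    ax.set_xscale("log")
    ax.set_xlabel("generations ago")
    ax.set_ylabel("$N_e$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca(scores: pd.DataFrame, path: str) -> None:
    """Individuals on the first two principal components, by population."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 5))
    for pop, df in scores.groupby("population"):
        ax.scatter(df["PC1"], df["PC2"], s=10, label=pop)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
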