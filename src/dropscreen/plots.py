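"""Matplotlib views of the screening statistics (histograms and time courses)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_stoichiometry", "plot_dead_target_fraction", "plot_killing_distribution"]


def plot_stoichiometry(joint: pd.DataFrame, path: str | Path) -> None:
    """Heatmap of the effector × target co-encapsulation fractions."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(joint.to_numpy(), origin="lower", cmap="viridis")
    ax.set_xlabel("target cells per droplet")
    ax.set_ylabel("effector cells per droplet")
    fig.colorbar(im, ax=ax, label="fraction of droplets")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dead_target_fraction(dtf: pd.DataFrame, path: str | Path) -> None:
    """Time course of the dead-target fraction with the spontaneous baseline."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(dtf.index, dtf["dead_target_fraction"], "o-", label="1 effector, 2-4 targets")
    ax.plot(dtf.index, dtf["baseline_dead_fraction"], "s--", label="target-only baseline")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("fraction of dead target cells")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_killing_distribution(dist: pd.Series, path: str | Path) -> None:
    """Bar chart of killing events per NK cell at the assay endpoint."""
    fig, ax = plt.subplots(figsize=(4.0, 3.2))
    ax.bar(np.arange(len(dist)), dist.to_numpy(), color="#356a9b")
    ax.set_xticks(np.arange(len(dist)), dist.index)
    ax.set_xlabel("killing events per NK cell")
    ax.set_ylabel("fraction of droplets")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
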