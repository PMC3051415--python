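"""Minimal figure analogs: stacked ancestry bar plots and MDS scatter."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

_PALETTE = ("#d95f02", "#1b9e77", "#7570b3", "#e7298a", "#666666")


def plot_ancestry_bars(
    Q: pd.DataFrame, groups: Sequence[str], path: str | Path
) -> None:
    """Per-individual stacked ancestry proportions ordered by group."""
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    Qo = Q.to_numpy()[order]
    fig, ax = plt.subplots(figsize=(10, 3))
    bottom = np.zeros(len(Qo))
    x = np.arange(len(Qo))
    for k, pop in enumerate(Q.columns):
        ax.bar(
            x, Qo[:, k], bottom=bottom, width=1.0,
            color=_PALETTE[k % len(_PALETTE)], label=str(pop), linewidth=0,
        )
        bottom += Qo[:, k]
    for g in np.unique(groups):
        centre = np.flatnonzero(groups[order] == g).mean()
        ax.text(centre, -0.06, str(g), ha="center", va="top", fontsize=7,
                transform=ax.get_xaxis_transform())
    ax.set_xlim(-0.5, len(Qo) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry")
    ax.set_xticks([])
    ax.legend(fontsize=7, ncol=len(Q.columns), loc="upper center",
              bbox_to_anchor=(0.5, 1.15), frameon=False)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_mds(
    coordinates: np.ndarray,
    labels: Sequence[str],
    path: str | Path,
    dims: tuple[int, int] = (0, 1),
) -> None:
    """2-D scatter of two MDS dimensions coloured by group."""
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    for k, g in enumerate(np.unique(labels)):
        sub = coordinates[labels == g]
        ax.scatter(
            sub[:, dims[0]], sub[:, dims[1]], s=10, alpha=0.7,
            color=_PALETTE[k % len(_PALETTE)], label=str(g),
        )
    ax.set_xlabel(f"dimension {dims[0] + 1}")
    ax.set_ylabel(f"dimension {dims[1] + 1}")
    ax.legend(fontsize=7, frameon=False)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
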