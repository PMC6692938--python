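"""Static figure helpers: signature heatmap and PCA scatter.

High methylation renders yellow, low blue, matching the usual two-way
methylation heatmap palette.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import BetaMatrix


def heatmap(matrix: BetaMatrix, path, labels: pd.Series | None = None) -> None:
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(matrix.values.to_numpy(dtype=float), aspect="auto",
                   cmap="cividis", vmin=0, vmax=1)
    ax.set_xlabel("samples")
    ax.set_ylabel("CpG probes")
    if labels is not None:
        ax.set_xticks(range(matrix.shape[1]))
        ax.set_xticklabels([str(labels.get(s, "")) for s in matrix.sample_ids],
                           rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label="beta")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pca_scatter(scores: pd.DataFrame, path,
                color_by: pd.Series | None = None) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    if color_by is not None:
        for value in pd.unique(color_by):
            idx = color_by[color_by == value].index
            sub = scores.loc[scores.index.intersection(idx)]
            ax.scatter(sub["PC1"], sub["PC2"], label=str(value), s=25)
        ax.legend(fontsize=7)
    else:
        ax.scatter(scores["PC1"], scores["PC2"], s=25)
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
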