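"""Optional heatmap rendering of FC matrices.

The composite convention: lower triangle shows all group-mean Fisher-Z
values, upper triangle only the significant ones.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .connectivity import composite_matrix

__all__ = ["fc_heatmap"]


def fc_heatmap(
    group_mean_z: np.ndarray,
    significant: np.ndarray | None = None,
    labels: list[str] | None = None,
    title: str = "",
    path: str | Path | None = None,
):
    """Render a (composite) FC matrix; returns the matplotlib figure.

    With ``significant`` given, the upper triangle is masked to the
    significant edges; without it the full matrix is drawn.
    """
    mat = (composite_matrix(group_mean_z, significant)
           if significant is not None else group_mean_z)
    vmax = float(np.abs(mat).max()) or 1.0
    fig, ax = plt.subplots(figsize=(5, 4.4))
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    fig.colorbar(im, ax=ax, label="Fisher-Z")
    if labels is not None and len(labels) <= 30:
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
        ax.set_yticks(range(len(labels)), labels, fontsize=6)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
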