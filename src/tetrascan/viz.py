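"""Figure rendering: correlation heatmaps and R-value boxplots.

Figures are best-effort side outputs; all quantitative surfaces of the
pipeline are TSV/BED/JSON. The heatmap uses a fixed diverging scale
over [-1, 1] with deep blue for high correlation, and draws the ORF
track along the top and left axes when annotation is supplied.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib import cm
from matplotlib.colors import Normalize

from .io import FeatureInterval
from .tetra import CorrelationMatrix

_NORM = Normalize(vmin=-1.0, vmax=1.0)
_CMAP = cm.RdBu  # low = red, high = deep blue


def matrix_to_rgb(r: np.ndarray) -> np.ndarray:
    """Map a correlation matrix to RGBA pixel values on the fixed
    [-1, 1] diverging scale (the exact mapping the heatmap uses)."""
    return _CMAP(_NORM(np.asarray(r, dtype=float)))


def render_heatmap(
    matrix: CorrelationMatrix,
    out: str | os.PathLike,
    intervals: list[FeatureInterval] | None = None,
) -> str:
    """Render the window-correlation heatmap plus an R-value boxplot.

    Returns the output path. The parent directory is created if needed.
    """
    out = str(out)
    parent = os.path.dirname(out)
    if parent:
        os.makedirs(parent, exist_ok=True)
    n = len(matrix.windows)
    fig, (ax, bx) = plt.subplots(
        1, 2, figsize=(9, 6.5), gridspec_kw={"width_ratios": [4, 1]}
    )
    ax.imshow(matrix_to_rgb(matrix.r), interpolation="nearest", origin="upper")
    ax.set_title(f"{matrix.seq_id}  (mean r = {matrix.mean_r:.2f} ± {matrix.sd_r:.2f})")
    ax.set_xlabel("window index")
    ax.set_ylabel("window index")
    if intervals:
        step = matrix.windows[1].start - matrix.windows[0].start if n > 1 else 1
        for iv in intervals:
            if iv.seq_id != matrix.seq_id or iv.kind not in ("CDS", "rRNA"):
                continue
            w0 = (iv.start - 1) / step
            w1 = (iv.end - 1) / step
            color = "black" if iv.kind == "CDS" else "green"
            ax.plot([w0, w1], [-1.5, -1.5], lw=3, color=color, clip_on=False)
            ax.plot([-1.5, -1.5], [w0, w1], lw=3, color=color, clip_on=False)
    iu = np.triu_indices(n, k=1)
    bx.boxplot(matrix.r[iu])
    bx.set_ylim(-1, 1)
    bx.set_ylabel("pairwise r")
    bx.set_xticks([])
    fig.tight_layout()
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out


def render_boxplot_summary(
    matrices: list[CorrelationMatrix], out: str | os.PathLike
) -> str:
    """One boxplot of off-diagonal R-values per fragment, side by side."""
    out = str(out)
    parent = os.path.dirname(out)
    if parent:
        os.makedirs(parent, exist_ok=True)
    fig, ax = plt.subplots(figsize=(1.2 * len(matrices) + 2, 5))
    data = []
    labels = []
    for m in matrices:
        iu = np.triu_indices(len(m.windows), k=1)
        data.append(m.r[iu])
        labels.append(m.seq_id)
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("pairwise window correlation r")
    ax.set_ylim(-1, 1)
    fig.tight_layout()
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out
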