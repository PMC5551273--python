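"""Optional figures: NMDS ordination with per-type confidence ellipses."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .inference import EllipseSpec, confidence_ellipse

_TYPE_COLORS = {"Fremont": "#1b9e77", "hybrid": "#d95f02", "narrowleaf": "#7570b3"}


def plot_ordination(
    coordinates: pd.DataFrame,
    groups: Sequence[str],
    ellipses: Sequence[EllipseSpec] | None = None,
    title: str = "",
    path=None,
):
    """Scatter the 2-D NMDS coordinates colored by tree type, with 95%
    confidence ellipses; writes to ``path`` if given, returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = np.asarray(list(groups))
    if ellipses is None:
        ellipses = confidence_ellipse(coordinates, groups)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    pts = coordinates.to_numpy()
    for g in pd.unique(groups):
        color = _TYPE_COLORS.get(str(g))
        sel = groups == g
        ax.scatter(pts[sel, 0], pts[sel, 1], s=25, label=str(g), color=color)
    for es in ellipses:
        ring = es.boundary(200)
        ax.plot(ring[:, 0], ring[:, 1], lw=1.2,
                color=_TYPE_COLORS.get(es.group), alpha=0.8)
    ax.axhline(0, lw=0.4, color="0.8")
    ax.axvline(0, lw=0.4, color="0.8")
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
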