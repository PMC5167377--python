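"""Static figures: template topographies and label timelines."""

from __future__ import annotations

import numpy as np

from .microstate import MicrostateTemplates, SegmentationLabels
from .montage import Montage


def plot_templates(templates: MicrostateTemplates, montage: Montage, path=None):
    """Scatter-style topographic maps, one panel per template."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = templates.k
    fig, axes = plt.subplots(1, k, figsize=(2.2 * k, 2.4), squeeze=False)
    xy = montage.positions[:, :2]
    vmax = np.abs(templates.maps).max()
    for j, ax in enumerate(axes[0]):
        ax.scatter(
            xy[:, 0], xy[:, 1], c=templates.maps[j], cmap="RdBu_r",
            vmin=-vmax, vmax=vmax, s=18,
        )
        ax.set_title(f"map {templates.ids[j]}", fontsize=9)
        ax.set_aspect("equal")
        ax.axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_label_timeline(segs: list[SegmentationLabels], path=None):
    """One row per condition; color encodes the assigned map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 0.6 * len(segs) + 1))
    n_maps = max(int(s.labels.max()) for s in segs) + 1
    cmap = plt.get_cmap("tab10", max(n_maps, 1))
    for row, seg in enumerate(segs):
        colors = [
            cmap(l) if l >= 0 else (1, 1, 1, 0) for l in seg.labels
        ]
        ax.scatter(seg.times, np.full_like(seg.times, row), c=colors, marker="s", s=12)
    ax.set_yticks(range(len(segs)), [s.condition for s in segs])
    ax.set_xlabel("time (ms)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
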