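"""Basic plotting plumbing: segmentation overlays and lineage trees."""

from __future__ import annotations

from typing import Sequence

import numpy as np


def overlay_labels(frame: np.ndarray, labels: np.ndarray, ax=None):
    """Show a frame with label boundaries overlaid; returns the axes."""
    import matplotlib.pyplot as plt
    from skimage.segmentation import find_boundaries

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(frame, cmap="gray")
    bounds = find_boundaries(np.asarray(labels), mode="outer")
    rgba = np.zeros(frame.shape + (4,))
    rgba[bounds] = (1.0, 0.2, 0.2, 1.0)
    ax.imshow(rgba)
    ax.set_axis_off()
    return ax


def plot_lineage(records: Sequence, ax=None):
    """Draw a lineage tree (tracks as horizontal bars, divisions as links)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rows = {rec.label: i for i, rec in enumerate(sorted(records,
                                                        key=lambda r: r.label))}
    for rec in records:
        y = rows[rec.label]
        ax.hlines(y, rec.begin_frame, rec.end_frame, lw=2)
        ax.text(rec.end_frame + 0.2, y, str(rec.label), va="center", fontsize=8)
        if rec.parent_label and rec.parent_label in rows:
            ax.plot([rec.begin_frame - 1, rec.begin_frame],
                    [rows[rec.parent_label], y], "k--", lw=0.8)
    ax.set_xlabel("frame")
    ax.set_ylabel("track")
    return ax
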