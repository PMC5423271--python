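"""Minimal orthogonal-slice rendering for volumes and probability maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .volumes import Volume


def plot_slices(
    vol: Volume,
    path: str | Path | None = None,
    title: str = "",
    cmap: str = "gray",
    vmin: float | None = None,
    vmax: float | None = None,
):
    """Mid-volume axial/coronal/sagittal slices side by side."""
    data = vol.data
    cx, cy, cz = (s // 2 for s in data.shape)
    slices = [data[cx, :, :], data[:, cy, :], data[:, :, cz]]
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    for ax, sl in zip(axes, slices):
        im = ax.imshow(np.rot90(sl), cmap=cmap, vmin=vmin, vmax=vmax)
        ax.axis("off")
    fig.colorbar(im, ax=axes, fraction=0.03)
    if title:
        fig.suptitle(title)
    if path is not None:
        fig.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(fig)
        return Path(path)
    return fig
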