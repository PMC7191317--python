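"""Optional figure helpers (requires matplotlib, installed via the
``plot`` extra).  Heatmaps follow the convention of masking small indices
to keep the display readable; the stored tables are never thresholded."""

from __future__ import annotations

import numpy as np


def plot_index_heatmap(frame, threshold: float = 0.05, ax=None, title=""):
    """Outputs x inputs heatmap of (signed) sensitivity indices.

    ``frame`` is a DataFrame as returned by
    ``StageBundle.sensitivity_frames()``; entries with |value| below
    ``threshold`` are masked for display only.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.5 * frame.shape[1] + 2, 0.4 * frame.shape[0] + 2))
    data = frame.values.astype(float)
    masked = np.ma.masked_where(np.abs(data) < threshold, data)
    vmax = np.nanmax(np.abs(data))
    im = ax.imshow(masked, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(frame.shape[1]), frame.columns, rotation=90)
    ax.set_yticks(range(frame.shape[0]), frame.index)
    ax.set_title(title)
    plt.colorbar(im, ax=ax)
    return ax


def plot_main_effects(curves, ax=None, title=""):
    """Overlay main-effect curves (one line per input)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        ax.plot(c.grid, c.expectation, label=c.input)
    ax.set_xlabel("normalized input value")
    ax.set_ylabel("expected output")
    ax.set_title(title)
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_restitution_surface(surface, ax=None, title=""):
    """Mean APD_90 over (DI x second input), colored by the credible band."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    D, G = np.meshgrid(surface["di_grid"], surface["second_grid"], indexing="ij")
    band = surface["band_halfwidth"]
    norm = band / max(band.max(), 1e-12)
    ax.plot_surface(D, G, surface["mean"], facecolors=__import__("matplotlib.cm", fromlist=["cm"]).viridis(norm))
    ax.set_xlabel("DI (normalized)")
    ax.set_ylabel("second input (normalized)")
    ax.set_zlabel("APD90")
    ax.set_title(title)
    return ax
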