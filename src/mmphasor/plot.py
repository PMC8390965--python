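"""Rendering of phasor histograms and parameter maps to image files.

All plotting is headless (Agg backend); functions write files and return
the matplotlib figure for further customization.  The phasor density uses
the red-to-blue colormap convention: red marks the most populated bins,
blue the least.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .phasor import PhasorHistogram

__all__ = ["render_phasor_histogram", "render_map"]


def render_phasor_histogram(hist: PhasorHistogram, path=None, title=None,
                            show_guides: bool = True):
    """Render a 2-D phasor histogram; optionally save to ``path``.

    ``show_guides`` overlays the physical-boundary circle of radius 0.5 and
    the retardance-branch circle of center (0.25, 0) and radius 0.25.
    """
    fig, ax = plt.subplots(figsize=(5, 5))
    counts = np.where(hist.counts > 0, hist.counts, np.nan)
    extent = [hist.g_edges[0], hist.g_edges[-1],
              hist.s_edges[0], hist.s_edges[-1]]
    im = ax.imshow(counts.T, origin="lower", extent=extent,
                   cmap=hist.colormap, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="pixels / bin", shrink=0.8)
    if show_guides:
        t = np.linspace(0, 2 * np.pi, 361)
        ax.plot(0.5 * np.cos(t), 0.5 * np.sin(t), "k--", lw=0.8)
        ax.plot(0.25 + 0.25 * np.cos(t), 0.25 * np.sin(t), "k:", lw=0.8)
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=150)
        plt.close(fig)
    return fig


def render_map(data, path=None, name: str = "map", cmap: str = "viridis",
               vmin=None, vmax=None, mask=None):
    """Render a parameter map as a color image; masked/NaN pixels are black."""
    arr = np.asarray(data, dtype=float)
    if mask is not None:
        arr = np.where(np.asarray(mask, dtype=bool), np.nan, arr)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("black")
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(arr, cmap=cm, vmin=vmin, vmax=vmax, interpolation="nearest")
    fig.colorbar(im, ax=ax, label=name, shrink=0.8)
    ax.set_axis_off()
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=150)
        plt.close(fig)
    return fig
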