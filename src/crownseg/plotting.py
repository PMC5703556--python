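"""Minimal map plotting for classified crowns and fishnet summaries."""

from __future__ import annotations

import matplotlib.pyplot as plt
from matplotlib.patches import Polygon as MplPolygon

CLASS_COLORS = {
    "sapote": "#1b7837",
    "algarrobo_alive": "#7fbf7b",
    "algarrobo_dead": "#8c510a",
    "overo": "#dfc27d",
    None: "#999999",
}


def plot_classified_map(classified, ax=None):
    """Draw crown polygons coloured by class; returns the axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    for crown in classified.crowns:
        poly = crown.polygon
        if poly is None:
            continue
        geoms = poly.geoms if hasattr(poly, "geoms") else [poly]
        for g in geoms:
            ax.add_patch(
                MplPolygon(
                    list(g.exterior.coords),
                    closed=True,
                    facecolor=CLASS_COLORS.get(crown.label, "#999999"),
                    edgecolor="black",
                    linewidth=0.3,
                )
            )
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    handles = [
        plt.Line2D([], [], marker="s", linestyle="", color=c, label=l)
        for l, c in CLASS_COLORS.items()
        if l
    ]
    ax.legend(handles=handles, loc="upper right", fontsize=8)
    return ax
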