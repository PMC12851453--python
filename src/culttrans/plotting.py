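"""Optional matplotlib views of the machine-readable results.

The acceptance surfaces of the analysis are the edge lists and tables;
these plots are conveniences for eyeballing them.
"""

from __future__ import annotations

import numpy as np

from .resemblance import ResemblanceGraph
from .transmission import BiasEstimate, _TRIANGLE_CORNERS, triangle_coordinates

_CATEGORY_COLORS = {
    "direct_vertical": "tab:red",
    "indirect_vertical": "tab:orange",
    "horizontal": "tab:blue",
    "other": "tab:gray",
}


def plot_resemblance_graph(graph: ResemblanceGraph, factor: str, ax=None):
    """Draw one factor's resemblance edges: solid for strong (z > 3.3),
    dashed for weak (z > 1.96), width proportional to z, coloured by
    transmission pathway."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    edges = [e for e in graph.edges if e["factor"] == factor and e["tier"] != "none"]
    roles = sorted({r for e in graph.edges for r in e["role_pair"]})
    angles = np.linspace(0, 2 * np.pi, len(roles), endpoint=False)
    pos = {r: (np.cos(a), np.sin(a)) for r, a in zip(roles, angles)}
    for e in edges:
        a, b = e["role_pair"]
        (x1, y1), (x2, y2) = pos[a], pos[b]
        ax.plot(
            [x1, x2], [y1, y2],
            linestyle="-" if e["tier"] == "strong" else "--",
            linewidth=max(0.5, 0.4 * e["z"]),
            color=_CATEGORY_COLORS.get(e["category"], "tab:gray"),
            alpha=0.8,
        )
    for r, (x, y) in pos.items():
        ax.plot(x, y, "o", color="black", ms=4)
        ax.annotate(r, (x, y), xytext=(1.12 * x, 1.12 * y), ha="center", fontsize=7)
    ax.set_title(factor)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def plot_bias_triangle(estimates: dict[str, BiasEstimate], ax=None):
    """Barycentric triangle of normalised Vertical/Horizontal/Other biases,
    one point per factor and polarity."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    corners = _TRIANGLE_CORNERS
    tri = np.array([corners["vertical"], corners["horizontal"], corners["other"],
                    corners["vertical"]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    for name, (x, y) in (("VertB", corners["vertical"]),
                         ("HorizB", corners["horizontal"]),
                         ("OtherB", corners["other"])):
        ax.annotate(name, (x, y), xytext=(x, y + 0.04 if name == "VertB" else y - 0.08),
                    ha="center")
    for factor, est in estimates.items():
        coords = triangle_coordinates(est)
        for polarity, marker in (("trait", "o"), ("opposite", "s")):
            c = coords[polarity]
            ax.plot(c["x"], c["y"], marker)
            sign = "+" if polarity == "trait" else "-"
            ax.annotate(f"{factor[:6]}{sign}", (c["x"], c["y"]), fontsize=7,
                        xytext=(c["x"] + 0.01, c["y"] + 0.01))
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
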