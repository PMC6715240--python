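"""Optional SVG rendering of layouts — presentation only."""

from __future__ import annotations

from typing import Mapping

from .grid import GridLayout
from .module_layout import ModuleRegion
from .network import ModuleAssignment, Network

__all__ = ["render_svg"]


def render_svg(
    layout: GridLayout,
    network: Network,
    assignment: ModuleAssignment,
    path,
    regions: Mapping[str, ModuleRegion] | None = None,
) -> None:
    """Draw nodes (colored by module), straight gray edges and region boxes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mods = list(dict.fromkeys(assignment.module_of.values()))
    cmap = plt.get_cmap("tab20")
    color = {m: cmap(i % 20) for i, m in enumerate(mods)}

    fig, ax = plt.subplots(figsize=(8, 8))
    for u, v in network.edges:
        (x1, y1), (x2, y2) = layout[u], layout[v]
        ax.plot([x1, x2], [y1, y2], color="0.6", lw=0.8, zorder=1)
    for u in network.nodes:
        x, y = layout[u]
        m = assignment.module_of.get(u)
        ax.scatter([x], [y], s=60, color=color.get(m, "0.3"), zorder=2)
        ax.annotate(u, (x, y), fontsize=6, ha="center", va="center", zorder=3)
    if regions:
        from matplotlib.patches import Rectangle

        for r in regions.values():
            ax.add_patch(
                Rectangle(
                    (r.x0 - 0.5, r.y0 - 0.5), r.side, r.side,
                    fill=False, edgecolor="0.3", ls="--", lw=0.8, zorder=0,
                )
            )
    ax.set_aspect("equal")
    ax.invert_yaxis()  # y grows downward in the grid convention
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
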