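"""Stage 3 — grid optimization of descendant nodes inside module regions.

The node weight matrix W_node is set from shortest-path lengths in the whole
network.  Same-module pairs: adjacent pairs attract strongly, pairs two
steps apart are neutral, and everything further (or disconnected) repels:

    path length 1        ->  +40
    path length 2        ->    0
    path length >= 3     ->  -10

Pairs whose members sit in *different* modules carry an extra +40 when
adjacent (and nothing otherwise, by default), so bridge endpoints are pulled
toward the facing sides of their regions, easing inter-module edge
crossings.  All node positions are
then optimized simultaneously by reoptimization-after-perturbation under a
hard containment constraint: a node never leaves its module's square region.
Because regions are pairwise disjoint, injectivity across modules is free.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

import numpy as np

from .grid import (
    GridLayout,
    OptimizerParams,
    Rect,
    WeightMatrix,
    reoptimize_after_perturbation,
)
from .module_layout import ModuleRegion
from .network import ModuleAssignment, Network

__all__ = ["set_node_weight", "optimize_nodes", "DEFAULT_BASE_WEIGHTS", "DEFAULT_EXTRA_WEIGHT"]

DEFAULT_BASE_WEIGHTS: tuple[float, float, float] = (40.0, 0.0, -10.0)
DEFAULT_EXTRA_WEIGHT: float = 40.0


def set_node_weight(
    network: Network,
    assignment: ModuleAssignment,
    base_weights: tuple[float, float, float] = DEFAULT_BASE_WEIGHTS,
    extra_weight: float = DEFAULT_EXTRA_WEIGHT,
    inter_base: str = "zero",
) -> WeightMatrix:
    """Build W_node from path lengths plus the inter-module adjacency bonus.

    ``base_weights`` = (w at path length 1, at length 2, at length >= 3)
    applies to same-module pairs; unreachable pairs fall in the ">= 3"
    bucket.  Path lengths are measured on the full network via breadth-first
    search truncated at depth 2.

    ``inter_base`` selects how pairs in *different* modules are weighted
    before the extra is added:

    * ``"zero"`` (default): inter-module pairs carry no path-length weight;
      an adjacent pair gets exactly ``extra_weight``.  With this scheme the
      only cross-region force is the bridge attraction, so bridge endpoints
      migrate to the facing sides of their regions.
    * ``"path"``: the path-length weight applies to every pair and the extra
      is accumulated on top (adjacent inter-module pairs get
      ``base + extra``).  The long-range repulsion then acts across regions
      too, which counteracts the bridge pull; kept for comparison.
    """
    if inter_base not in ("zero", "path"):
        raise ValueError("inter_base must be 'zero' or 'path'")
    assignment.validate_total(network)
    w1, w2, w_far = (float(v) for v in base_weights)
    extra = float(extra_weight)
    nodes = network.nodes
    w = WeightMatrix()
    for i, u in enumerate(nodes):
        near = network.neighbors(u)
        two = set()
        for x in near:
            two.update(network.neighbors(x))
        two.discard(u)
        two -= near
        mod_u = assignment.module_of[u]
        for v in nodes[i + 1:]:
            if v in near:
                base = w1
            elif v in two:
                base = w2
            else:
                base = w_far
            if assignment.module_of[v] == mod_u:
                val = base
            elif inter_base == "path":
                val = base + (extra if v in near else 0.0)
            else:
                val = extra if v in near else 0.0
            w.set(u, v, val)
    return w


def optimize_nodes(
    network: Network,
    w_node: WeightMatrix,
    regions: Mapping[str, ModuleRegion],
    assignment: ModuleAssignment,
    params: OptimizerParams,
    neighborhood: str = "moore",
) -> GridLayout:
    """Optimize all node positions inside their module regions.

    Nodes start at seeded-random vacant points of their region; the
    optimizer's moves and perturbations both respect region containment.
    Raises before optimizing if any region lacks capacity for its module.
    """
    assignment.validate_total(network)
    modules = assignment.modules
    for mod, members in modules.items():
        if mod not in regions:
            raise ValueError(f"no region for module {mod!r}")
        if regions[mod].capacity < len(members):
            raise ValueError(
                f"region of module {mod!r} holds {regions[mod].capacity} points"
                f" but the module has {len(members)} nodes"
            )

    rng = np.random.default_rng(params.seed)
    pos: dict[str, tuple[int, int]] = {}
    bounds: dict[str, Rect] = {}
    for mod in sorted(modules):
        members = modules[mod]
        pts = regions[mod].rect.points()
        chosen = rng.choice(len(pts), size=len(members), replace=False)
        for u, i in zip(members, chosen):
            pos[u] = pts[int(i)]
            bounds[u] = regions[mod].rect
    # keep network node order as the optimizer sweep order
    initial = GridLayout({u: pos[u] for u in network.nodes}, bounds=bounds)
    opt_seed = int(rng.integers(2**31))
    return reoptimize_after_perturbation(
        w_node, initial, replace(params, seed=opt_seed), neighborhood
    )
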