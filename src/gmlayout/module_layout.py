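"""Stage 2 — module layout.

Modules are first treated as single points and placed on the grid by
minimizing  C_module = sum w_hk * d_hk,  where the weight w_hk grows with the
number of edges e_hk running between modules h and k (heavily connected
module pairs are pulled together, cutting inter-module edge crossings).
Each module is then expanded into a square region with side

    l_h = ceil(2 * sqrt(n_h))        (n_h = module size, minimum side 2)

anchored at (x_h * l', y_h * l') with l' = max_h l_h + margin, so regions of
distinct modules can never overlap and each region has ample capacity
(l_h^2 >= 4 * n_h) for its descendant nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .grid import (
    GridLayout,
    OptimizerParams,
    Rect,
    WeightMatrix,
    reoptimize_after_perturbation,
)
from .network import ModuleAssignment, Network

__all__ = [
    "ModuleRegion",
    "count_intermodule_edges",
    "set_module_weight",
    "layout_modules",
    "expand_modules",
]


@dataclass(frozen=True)
class ModuleRegion:
    """Square grid region allotted to one module's descendant nodes."""

    module: str
    x0: int
    y0: int
    side: int

    def __post_init__(self):
        if self.side < 1:
            raise ValueError("region side must be positive")

    @property
    def rect(self) -> Rect:
        return Rect(self.x0, self.y0, self.x0 + self.side - 1, self.y0 + self.side - 1)

    @property
    def capacity(self) -> int:
        return self.side * self.side


def count_intermodule_edges(
    network: Network, assignment: ModuleAssignment
) -> dict[tuple[str, str], int]:
    """e_hk: number of edges with one endpoint in module h, the other in k.

    Keys are sorted (h, k) pairs with h != k; intra-module edges are ignored.
    """
    assignment.validate_total(network)
    counts: dict[tuple[str, str], int] = {}
    for u, v in network.edges:
        h, k = assignment.module_of[u], assignment.module_of[v]
        if h == k:
            continue
        key = (h, k) if h <= k else (k, h)
        counts[key] = counts.get(key, 0) + 1
    return counts


def set_module_weight(
    e: Mapping[tuple[str, str], int],
    mapping: Callable[[int], float] = float,
) -> WeightMatrix:
    """W_module from inter-module edge counts.

    ``mapping`` must be non-decreasing and map 0 to 0; the default is the
    identity w_hk = e_hk, the simplest scheme under which module pairs with
    more edges get larger weights.
    """
    w = WeightMatrix()
    for (h, k), count in e.items():
        if count < 0:
            raise ValueError(f"negative edge count for pair ({h!r}, {k!r})")
        w.set(h, k, mapping(count))
    return w


def layout_modules(
    w_module: WeightMatrix,
    params: OptimizerParams,
    module_ids: Sequence[str] | None = None,
    neighborhood: str = "moore",
) -> GridLayout:
    """Place modules on distinct grid points minimizing C_module.

    Starts from a seeded random injective placement on a compact square board
    (side ceil(sqrt(k)) + 1, leaving vacancies to move through) and runs
    reoptimization-after-perturbation with ``params.niter`` rounds.  A single
    module is pinned at the origin.  ``module_ids`` defaults to the entities
    of the weight matrix; pass the full module list to also place modules
    with no inter-module edges.
    """
    ids = list(module_ids) if module_ids is not None else list(w_module.entities())
    for e in w_module.entities():
        if e not in ids:
            raise ValueError(f"weighted module {e!r} missing from module_ids")
    k = len(ids)
    if k == 0:
        return GridLayout({})
    if k == 1:
        return GridLayout({ids[0]: (0, 0)})
    side = int(math.ceil(math.sqrt(k))) + 1
    board = Rect(0, 0, side - 1, side - 1)
    rng = np.random.default_rng(params.seed)
    pts = board.points()
    chosen = rng.choice(len(pts), size=k, replace=False)
    initial = GridLayout({e: pts[int(i)] for e, i in zip(ids, chosen)}, bounds=board)
    opt_seed = int(rng.integers(2**31))
    return reoptimize_after_perturbation(
        w_module, initial, replace(params, seed=opt_seed), neighborhood
    )


def expand_modules(
    r_module: GridLayout,
    assignment: ModuleAssignment,
    margin: int = 2,
) -> dict[str, ModuleRegion]:
    """Expand each placed module into its square region.

    Region side l_h = ceil(2*sqrt(n_h)) floored at 2; the grid of module
    positions is scaled by l' = max l_h + margin, guaranteeing pairwise
    disjoint regions with a vacant corridor of at least ``margin`` cells.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    sizes = {m: len(members) for m, members in assignment.modules.items()}
    regions: dict[str, ModuleRegion] = {}
    sides: dict[str, int] = {}
    for mod in r_module.entities():
        n_h = sizes.get(mod, 0)
        if n_h == 0:
            raise ValueError(f"module {mod!r} has no members")
        sides[mod] = max(2, math.ceil(2.0 * math.sqrt(n_h)))
    if not sides:
        return {}
    l_prime = max(sides.values()) + margin
    for mod in r_module.entities():
        x_h, y_h = r_module[mod]
        regions[mod] = ModuleRegion(mod, x_h * l_prime, y_h * l_prime, sides[mod])
    return regions
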