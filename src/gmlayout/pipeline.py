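"""End-to-end GML pipeline: preprocessing -> module layout -> grid optimization.

One master seed deterministically derives the per-stage seeds, so a whole
run is reproducible from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridLayout, OptimizerParams, WeightMatrix, layout_cost
from .grid_optimization import (
    DEFAULT_BASE_WEIGHTS,
    DEFAULT_EXTRA_WEIGHT,
    optimize_nodes,
    set_node_weight,
)
from .module_layout import (
    ModuleRegion,
    count_intermodule_edges,
    expand_modules,
    layout_modules,
    set_module_weight,
)
from .network import ModuleAssignment, Network
from .preprocessing import partition_residual_nodes

__all__ = ["GMLParams", "LayoutResult", "layout_network"]


@dataclass(frozen=True)
class GMLParams:
    """All pipeline knobs with their defaults.

    ``niter_module`` / ``niter_grid`` are the reoptimization round counts of
    stages 2 and 3; ``perturb_prob`` the per-entity kick probability;
    ``margin`` the vacant corridor (in grid cells) between module regions;
    ``base_weights`` / ``extra_weight`` the stage-3 weight scheme.
    """

    niter_module: int = 200
    niter_grid: int = 500
    perturb_prob: float = 0.2
    neighborhood: str = "moore"
    margin: int = 2
    base_weights: tuple[float, float, float] = DEFAULT_BASE_WEIGHTS
    extra_weight: float = DEFAULT_EXTRA_WEIGHT
    inter_base: str = "zero"
    resolution: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class LayoutResult:
    assignment: ModuleAssignment
    module_positions: GridLayout
    regions: dict[str, ModuleRegion]
    layout: GridLayout
    w_node: WeightMatrix
    module_cost: float
    node_cost: float


def _stage_seeds(master: int) -> tuple[int, int, int]:
    rng = np.random.default_rng(master)
    return tuple(int(s) for s in rng.integers(2**31, size=3))


def layout_network(
    network: Network,
    predefined: ModuleAssignment | None = None,
    params: GMLParams = GMLParams(),
) -> LayoutResult:
    """Run the three GML stages on a network and return every artifact.

    Stage 1 clusters the non-predefined nodes into pseudo modules; stage 2
    places modules and expands them into disjoint square regions; stage 3
    optimizes every node inside its region.
    """
    seed_cluster, seed_module, seed_grid = _stage_seeds(params.seed)

    assignment = partition_residual_nodes(
        network, predefined, seed=seed_cluster, resolution=params.resolution
    )

    e = count_intermodule_edges(network, assignment)
    w_module = set_module_weight(e)
    module_positions = layout_modules(
        w_module,
        OptimizerParams(params.niter_module, params.perturb_prob, seed_module),
        module_ids=assignment.module_ids,
        neighborhood=params.neighborhood,
    )
    regions = expand_modules(module_positions, assignment, margin=params.margin)

    w_node = set_node_weight(
        network, assignment, base_weights=params.base_weights,
        extra_weight=params.extra_weight, inter_base=params.inter_base,
    )
    layout = optimize_nodes(
        network,
        w_node,
        regions,
        assignment,
        OptimizerParams(params.niter_grid, params.perturb_prob, seed_grid),
        neighborhood=params.neighborhood,
    )
    return LayoutResult(
        assignment=assignment,
        module_positions=module_positions,
        regions=regions,
        layout=layout,
        w_node=w_node,
        module_cost=layout_cost(w_module, module_positions),
        node_cost=layout_cost(w_node, layout),
    )
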