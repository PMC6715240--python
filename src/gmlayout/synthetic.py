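"""Synthetic modular networks and the 24-node demonstration fixture.

The planted-partition generator emulates the modular structure typical of
biological interaction networks — groups of densely interconnected molecules
(complexes, pathways) with sparse cross-talk — and carries its ground-truth
partition, so clustering recovery and layout quality can be scored without
external datasets.
"""

from __future__ import annotations

import numpy as np

from .network import ModuleAssignment, Network

__all__ = ["generate_modular_network", "example_network_24"]


def generate_modular_network(
    sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> tuple[Network, ModuleAssignment]:
    """Planted-partition random graph with known module structure.

    Every intra-module node pair becomes an edge with probability ``p_in``,
    every inter-module pair with ``p_out``.  Nodes are named "1".."N" in
    module blocks; modules are "M1".."Mk".  Returns the network and the
    planted (total, non-predefined) assignment.  Same seed, same graph.
    """
    if not sizes:
        raise ValueError("sizes must be non-empty")
    if any(s < 1 for s in sizes):
        raise ValueError("module sizes must be positive")
    for name, p in (("p_in", p_in), ("p_out", p_out)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    nodes = [str(i + 1) for i in range(n)]
    module_of: dict[str, str] = {}
    block = np.empty(n, dtype=np.int64)
    start = 0
    for k, s in enumerate(sizes):
        for i in range(start, start + s):
            module_of[nodes[i]] = f"M{k + 1}"
            block[i] = k
        start += s
    ii, jj = np.triu_indices(n, k=1)
    p_pair = np.where(block[ii] == block[jj], p_in, p_out)
    keep = rng.random(len(ii)) < p_pair
    edges = [(nodes[int(a)], nodes[int(b)]) for a, b in zip(ii[keep], jj[keep])]
    return Network(nodes, edges), ModuleAssignment(module_of)


# 24-node demonstration network: three densely connected residual groups
# ({1..6}, {7..12}, {13..18, 23}) joined by a few bridges, plus a predefined
# module {19, 20, 21, 22, 24} in which node 24 is isolated.  The edge set is
# a repository constant chosen to exhibit these features; it is synthetic.
_EXAMPLE_24_EDGES: tuple[tuple[str, str], ...] = (
    # group 1: nodes 1-6
    ("1", "2"), ("1", "3"), ("1", "4"), ("2", "3"), ("2", "4"), ("3", "4"),
    ("3", "5"), ("4", "5"), ("4", "6"), ("5", "6"), ("3", "6"),
    # group 2: nodes 7-12
    ("7", "8"), ("7", "9"), ("7", "10"), ("8", "9"), ("8", "10"), ("9", "10"),
    ("9", "11"), ("10", "11"), ("10", "12"), ("11", "12"),
    # group 3: nodes 13-18 and 23
    ("13", "14"), ("13", "15"), ("14", "15"), ("14", "16"), ("15", "16"),
    ("15", "17"), ("16", "17"), ("16", "18"), ("17", "18"), ("16", "23"),
    ("18", "23"),
    # bridges between residual groups
    ("6", "7"), ("9", "13"), ("12", "18"),
    # predefined module 19-22 internal wiring (24 stays isolated)
    ("19", "20"), ("19", "21"), ("20", "22"), ("21", "22"),
    # connections from the predefined module into the residual groups
    ("2", "21"), ("8", "19"), ("17", "22"),
)


def example_network_24() -> tuple[Network, ModuleAssignment]:
    """Fixed 24-node fixture with a predefined module {19, 20, 21, 22, 24}.

    Node 24 has no connection to the rest of the network but is retained
    inside its predefined module.  Returns the network and the *partial*
    predefined assignment (residual nodes uncovered).
    """
    nodes = [str(i) for i in range(1, 25)]
    net = Network(nodes, _EXAMPLE_24_EDGES)
    predefined = {u: "P1" for u in ("19", "20", "21", "22", "24")}
    return net, ModuleAssignment(predefined, predefined=frozenset({"P1"}))
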