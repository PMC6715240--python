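"""Stage 1 — network preprocessing.

Nodes belonging to user-predefined modules are set aside; the remaining
("residual") nodes are partitioned into pseudo modules by multilevel
modularity maximization (Louvain).  Clustering sees only the subgraph induced
by residual nodes, mirroring the filter-then-cluster order: edges into
predefined modules do not influence the pseudo modules.
"""

from __future__ import annotations

from networkx.algorithms.community import louvain_communities

from .network import ModuleAssignment, Network

__all__ = ["partition_residual_nodes"]

PSEUDO_PREFIX = "pseudo"


def partition_residual_nodes(
    network: Network,
    predefined: ModuleAssignment | None = None,
    seed: int = 0,
    resolution: float = 1.0,
) -> ModuleAssignment:
    """Complete a partial predefined assignment into a total partition.

    Predefined module contents are preserved verbatim.  Every residual node
    lands in exactly one pseudo module named ``pseudo1``, ``pseudo2``, ...;
    numbering follows the first (in network node order) member of each
    community, so the result is deterministic for a fixed seed.  Residual
    nodes of degree 0 in the residual subgraph come out as singleton
    communities of the clustering.
    """
    if predefined is None:
        predefined = ModuleAssignment.empty()
    for u in predefined.module_of:
        if not network.has_node(u):
            raise ValueError(f"predefined node {u!r} is not in the network")

    module_of: dict[str, str] = dict(predefined.module_of)
    residual = [u for u in network.nodes if u not in module_of]
    if residual:
        sub = network.subgraph(residual).to_networkx()
        communities = louvain_communities(sub, seed=seed, resolution=resolution)
        order = {u: k for k, u in enumerate(network.nodes)}
        communities = sorted(communities, key=lambda c: min(order[u] for u in c))
        used = set(predefined.predefined) | set(predefined.module_of.values())
        idx = 0
        for comm in communities:
            idx += 1
            name = f"{PSEUDO_PREFIX}{idx}"
            while name in used:
                idx += 1
                name = f"{PSEUDO_PREFIX}{idx}"
            used.add(name)
            for u in sorted(comm, key=order.__getitem__):
                module_of[u] = name

    # keep network node order in the mapping for reproducible downstream order
    ordered = {u: module_of[u] for u in network.nodes}
    result = ModuleAssignment(ordered, predefined=predefined.predefined)
    result.validate_total(network)
    return result
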