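"""Core graph containers: undirected simple networks and module partitions.

A biological network is modelled as a simple undirected graph over opaque
string node identifiers.  Modules (either *predefined* by the user from
biological knowledge, or *pseudo* modules found by clustering) partition the
node set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

__all__ = ["Network", "ModuleAssignment"]


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


class Network:
    """Simple undirected graph with ordered string node ids.

    Node order is first-appearance order and is preserved throughout the
    pipeline so layouts and files are deterministic.  Self-loops and duplicate
    edges are rejected at construction; use :func:`gmlayout.io.read_network`
    for forgiving parsing of external files.
    """

    __slots__ = ("_nodes", "_edges", "_adj")

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        self._nodes: list[str] = []
        seen: set[str] = set()
        for u in nodes:
            u = str(u)
            if u not in seen:
                seen.add(u)
                self._nodes.append(u)
        self._adj: dict[str, set[str]] = {u: set() for u in self._nodes}
        self._edges: list[tuple[str, str]] = []
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            for w in (u, v):
                if w not in self._adj:
                    raise ValueError(f"edge endpoint {w!r} is not a declared node")
            if v in self._adj[u]:
                raise ValueError(f"duplicate edge {u!r}-{v!r}")
            self._adj[u].add(v)
            self._adj[v].add(u)
            self._edges.append(_edge_key(u, v))

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        """Edges as sorted (u, v) pairs, in insertion order."""
        return tuple(self._edges)

    @property
    def n(self) -> int:
        return len(self._nodes)

    @property
    def m(self) -> int:
        return len(self._edges)

    def degree(self, u: str) -> int:
        return len(self._adj[u])

    def neighbors(self, u: str) -> frozenset[str]:
        return frozenset(self._adj[u])

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    def has_node(self, u: str) -> bool:
        return u in self._adj

    def __iter__(self) -> Iterator[str]:
        return iter(self._nodes)

    def __contains__(self, u: object) -> bool:
        return u in self._adj

    def __repr__(self) -> str:
        return f"Network(n={self.n}, m={self.m})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self._nodes == other._nodes and set(self._edges) == set(other._edges)

    def __hash__(self):  # mutable-free but keep unhashable like nx.Graph
        raise TypeError("Network is not hashable")

    # -- derived views -----------------------------------------------------
    def subgraph(self, keep: Iterable[str]) -> "Network":
        """Induced subgraph on ``keep``, preserving node order."""
        keep_set = set(keep)
        nodes = [u for u in self._nodes if u in keep_set]
        edges = [(u, v) for u, v in self._edges if u in keep_set and v in keep_set]
        return Network(nodes, edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges)
        return g

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "Network":
        """Build a network from an edge iterable; node order is first appearance."""
        edges = [(str(u), str(v)) for u, v in edges]
        nodes: list[str] = []
        seen: set[str] = set()
        for u, v in edges:
            for w in (u, v):
                if w not in seen:
                    seen.add(w)
                    nodes.append(w)
        for w in extra_nodes:
            w = str(w)
            if w not in seen:
                seen.add(w)
                nodes.append(w)
        return cls(nodes, edges)


@dataclass(frozen=True)
class ModuleAssignment:
    """Partition of (a subset of) nodes into modules.

    ``module_of`` maps each covered node to exactly one module id.
    ``predefined`` flags the modules fixed by the user; the rest are pseudo
    modules produced by clustering.  A *partial* assignment (covering only the
    predefined nodes) is completed by
    :func:`gmlayout.preprocessing.partition_residual_nodes`.
    """

    module_of: Mapping[str, str]
    predefined: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "module_of", dict(self.module_of))
        object.__setattr__(self, "predefined", frozenset(self.predefined))
        unknown = self.predefined - set(self.modules)
        if unknown:
            raise ValueError(f"predefined module ids with no members: {sorted(unknown)}")

    @property
    def modules(self) -> dict[str, list[str]]:
        """Module id -> member nodes (in assignment insertion order)."""
        out: dict[str, list[str]] = {}
        for node, mod in self.module_of.items():
            out.setdefault(mod, []).append(node)
        return out

    @property
    def module_ids(self) -> tuple[str, ...]:
        return tuple(self.modules)

    def members(self, module_id: str) -> tuple[str, ...]:
        return tuple(self.modules[module_id])

    def size(self, module_id: str) -> int:
        return len(self.modules[module_id])

    def covers(self, nodes: Iterable[str]) -> bool:
        return all(u in self.module_of for u in nodes)

    def is_predefined(self, module_id: str) -> bool:
        return module_id in self.predefined

    def validate_total(self, network: Network) -> None:
        """Raise unless this assignment is a partition of the network's nodes."""
        missing = [u for u in network.nodes if u not in self.module_of]
        if missing:
            raise ValueError(f"nodes not assigned to any module: {missing[:5]}")
        extra = [u for u in self.module_of if not network.has_node(u)]
        if extra:
            raise ValueError(f"assigned nodes not in network: {extra[:5]}")

    @classmethod
    def empty(cls) -> "ModuleAssignment":
        return cls({}, frozenset())
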