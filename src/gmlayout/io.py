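"""Reading networks and module files; writing layout tables.

Supported network formats: whitespace-delimited edge lists, SIF (Simple
Interaction Format: ``node  interaction-type  partner [partner ...]``), and
GraphML (ids only; attributes are ignored).  All parsers collapse duplicate
edges and drop self-loops with a warning, so the in-memory graph is always
simple and undirected.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

from .grid import GridLayout
from .network import ModuleAssignment, Network

__all__ = [
    "read_network",
    "read_predefined_modules",
    "write_layout",
    "read_layout",
    "write_regions",
]

logger = logging.getLogger(__name__)

_FORMATS = ("edgelist", "sif", "graphml")


def _build_simple(nodes: list[str], triples: Iterable[tuple[str, str, int]],
                  path) -> Network:
    """Collapse duplicates / drop self-loops from (u, v, lineno) edge triples.

    ``nodes`` lists node ids in first-appearance order (may include isolated
    nodes); edge endpoints not yet listed are appended in edge order.
    """
    seen_nodes = set(nodes)
    nodes = list(nodes)
    edges: list[tuple[str, str]] = []
    seen_edges: set[frozenset[str]] = set()
    for u, v, lineno in triples:
        for w in (u, v):
            if w not in seen_nodes:
                seen_nodes.add(w)
                nodes.append(w)
        if u == v:
            logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
            continue
        key = frozenset((u, v))
        if key in seen_edges:
            logger.warning("%s:%d: dropping duplicate edge %r-%r", path, lineno, u, v)
            continue
        seen_edges.add(key)
        edges.append((u, v))
    if not nodes:
        raise ValueError(f"{path}: empty network file")
    return Network(nodes, edges)


def _parse_edgelist(path: Path) -> Network:
    triples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two whitespace-separated node"
                    f" ids, got {len(fields)} fields"
                )
            triples.append((fields[0], fields[1], lineno))
    return _build_simple([], triples, path)


def _parse_sif(path: Path) -> Network:
    nodes: list[str] = []
    triples: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 1:  # isolated node line is legal SIF
                nodes.append(fields[0])
                continue
            if len(fields) == 2:
                raise ValueError(
                    f"{path}:{lineno}: SIF line needs a source, an interaction"
                    " type and at least one target"
                )
            nodes.append(fields[0])
            for tgt in fields[2:]:
                nodes.append(tgt)
                triples.append((fields[0], tgt, lineno))
    ordered = list(dict.fromkeys(nodes))
    return _build_simple(ordered, triples, path)


def _parse_graphml(path: Path) -> Network:
    import networkx as nx

    g = nx.read_graphml(path)
    nodes = [str(u) for u in g.nodes()]
    triples = [(str(u), str(v), i + 1) for i, (u, v) in enumerate(g.edges())]
    return _build_simple(nodes, triples, path)


def read_network(path, format: str = "edgelist") -> Network:
    """Read a network file into a simple undirected :class:`Network`.

    Duplicate edges are collapsed and self-loops dropped (with warnings);
    node order is first-appearance order in the file.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edgelist":
        return _parse_edgelist(path)
    if format == "sif":
        return _parse_sif(path)
    return _parse_graphml(path)


def read_predefined_modules(path, network: Network) -> ModuleAssignment:
    """Read a two-column TSV (node-id, module-id) of predefined modules.

    Returns a *partial* assignment covering exactly the listed nodes, with
    every listed module flagged predefined.  A node listed under two modules,
    or a node absent from the network, is an error.
    """
    path = Path(path)
    module_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns (node-id, module-id)"
                )
            node, mod = fields
            if not network.has_node(node):
                raise ValueError(
                    f"{path}:{lineno}: node {node!r} is not in the network"
                )
            if node in module_of and module_of[node] != mod:
                raise ValueError(
                    f"{path}:{lineno}: node {node!r} assigned to both"
                    f" {module_of[node]!r} and {mod!r}"
                )
            module_of[node] = mod
    return ModuleAssignment(module_of, predefined=frozenset(module_of.values()))


def write_layout(layout: GridLayout, assignment: ModuleAssignment, path,
                 network: Network | None = None) -> None:
    """Write a layout TSV: node-id, x, y, module-id, predefined flag.

    Rows follow network node order when a network is given, else layout
    insertion order; output is byte-deterministic for a fixed layout.
    """
    order = list(network.nodes) if network is not None else list(layout.entities())
    missing = [u for u in order if u not in layout]
    if missing:
        raise ValueError(f"nodes missing from layout: {missing[:5]}")
    lines = ["node\tx\ty\tmodule\tpredefined"]
    for u in order:
        x, y = layout[u]
        mod = assignment.module_of.get(u, "")
        flag = "true" if assignment.is_predefined(mod) else "false"
        lines.append(f"{u}\t{x}\t{y}\t{mod}\t{flag}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_layout(path) -> tuple[GridLayout, ModuleAssignment]:
    """Read back a layout TSV written by :func:`write_layout`."""
    pos: dict[str, tuple[int, int]] = {}
    module_of: dict[str, str] = {}
    predefined: set[str] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("node\t"):
            raise ValueError(f"{path}: missing layout header")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            node, x, y, mod, flag = fields
            pos[node] = (int(x), int(y))
            if mod:
                module_of[node] = mod
                if flag == "true":
                    predefined.add(mod)
    return GridLayout(pos), ModuleAssignment(module_of, frozenset(predefined))


def write_regions(regions, path) -> None:
    """Write module regions as TSV: module-id, x0, y0, side."""
    lines = ["module\tx0\ty0\tside"]
    for r in regions.values() if isinstance(regions, dict) else regions:
        lines.append(f"{r.module}\t{r.x0}\t{r.y0}\t{r.side}")
    Path(path).write_text("\n".join(lines) + "\n")
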