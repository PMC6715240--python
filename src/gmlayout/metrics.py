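"""Layout-quality metrics.

Four measures summarize a grid layout of a network:

* **connectivity F-measure** — per node i, draw a circle B_i(r_i) around its
  position; precision P_i = fraction of the other nodes inside the circle
  that are neighbors of i, recall R_i = fraction of i's neighbors inside the
  circle.  F_i = 1 / (alpha/P_i + (1-alpha)/R_i) maximized over r_i, and F is
  the mean of F_i over nodes with degree >= 1.  Higher is better: dense
  neighborhoods sit together.
* **relative edge length** — total Manhattan edge length divided by
  (layout area x edge count); lower is more compact.  Area is the node
  bounding box counted in grid cells, (dx+1)*(dy+1).
* **edge-edge crossing ratio** — crossing edge pairs over all C(m,2) pairs.
  A pair crosses iff the *open* segments intersect: a proper interior
  crossing, or a collinear overlap of positive length (counted once).  Pairs
  that merely share an endpoint do not cross.
* **node-edge crossing ratio** — (node, edge) pairs where the node is not an
  endpoint but lies within ``eps`` (default 0.5 grid units) of the segment,
  over all n*m - 2m such pairs.

All geometry uses exact integer arithmetic where possible; circle membership
uses Euclidean distance, while edge lengths stay Manhattan as in the cost
function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridLayout
from .network import Network

__all__ = [
    "LayoutMetrics",
    "precision_recall",
    "connectivity_f_measure",
    "relative_edge_length",
    "edge_edge_crossing_ratio",
    "node_edge_crossing_ratio",
    "evaluate_layout",
]


@dataclass(frozen=True)
class LayoutMetrics:
    connectivity_f: float
    relative_edge_length: float
    edge_edge_ratio: float
    node_edge_ratio: float
    alpha: float = 0.5
    eps: float = 0.5


def _positions(layout: GridLayout, network: Network) -> np.ndarray:
    missing = [u for u in network.nodes if u not in layout]
    if missing:
        raise ValueError(f"nodes missing from layout: {missing[:5]}")
    return np.array([layout[u] for u in network.nodes], dtype=np.int64)


def precision_recall(
    layout: GridLayout, network: Network, i: str, r: float
) -> tuple[float, float]:
    """(P_i(r), R_i(r)) for the circle of Euclidean radius r around node i.

    Requires degree(i) >= 1 (the recall denominator).  If the circle contains
    no other node, precision is reported as 0.
    """
    deg = network.degree(i)
    if deg == 0:
        raise ValueError(f"node {i!r} has degree 0; recall is undefined")
    pts = _positions(layout, network)
    nodes = network.nodes
    idx = nodes.index(i)
    d2 = ((pts - pts[idx]) ** 2).sum(axis=1)
    inside = (d2 <= r * r)
    inside[idx] = False
    adj = np.array([network.has_edge(i, v) for v in nodes])
    hits = int((inside & adj).sum())
    n_inside = int(inside.sum())
    p = hits / n_inside if n_inside else 0.0
    return p, hits / deg


def connectivity_f_measure(
    layout: GridLayout, network: Network, alpha: float = 0.5
) -> float:
    """Mean over degree->=1 nodes of F_i maximized over the circle radius.

    Candidate radii are the distinct distances from i to the other nodes —
    F_i is piecewise-constant between them, so the maximum is exact.
    """
    if network.m == 0:
        raise ValueError("connectivity F-measure needs at least one edge")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    pts = _positions(layout, network)
    nodes = network.nodes
    adj_idx = {u: k for k, u in enumerate(nodes)}
    fs = []
    for k, u in enumerate(nodes):
        deg = network.degree(u)
        if deg == 0:
            continue
        d2 = ((pts - pts[k]) ** 2).sum(axis=1)
        d2 = np.delete(d2, k)
        adj = np.zeros(len(nodes), dtype=bool)
        for v in network.neighbors(u):
            adj[adj_idx[v]] = True
        adj = np.delete(adj, k)
        order = np.argsort(d2, kind="stable")
        d2s = d2[order]
        hits = np.cumsum(adj[order])
        counts = np.arange(1, len(d2s) + 1)
        # evaluate only at the largest index of each distinct radius
        last = np.r_[d2s[1:] != d2s[:-1], True]
        p = hits[last] / counts[last]
        rcl = hits[last] / deg
        with np.errstate(divide="ignore"):
            f = np.where(hits[last] > 0, 1.0 / (alpha / p + (1 - alpha) / rcl), 0.0)
        fs.append(float(f.max()))
    return float(np.mean(fs))


def relative_edge_length(layout: GridLayout, network: Network) -> float:
    """Sum of Manhattan edge lengths / (bounding-box area x edge count)."""
    if network.m == 0:
        raise ValueError("relative edge length needs at least one edge")
    pts = _positions(layout, network)
    idx = {u: k for k, u in enumerate(network.nodes)}
    total = 0
    for u, v in network.edges:
        a, b = pts[idx[u]], pts[idx[v]]
        total += abs(int(a[0]) - int(b[0])) + abs(int(a[1]) - int(b[1]))
    area = (np.ptp(pts[:, 0]) + 1) * (np.ptp(pts[:, 1]) + 1)
    return total / (float(area) * network.m)


def _segment_arrays(layout: GridLayout, network: Network):
    idx = {u: k for k, u in enumerate(network.nodes)}
    pts = _positions(layout, network)
    ends = np.array(
        [(idx[u], idx[v]) for u, v in network.edges], dtype=np.int64
    )
    return pts, ends


def _cross(o, a, b):
    """2D cross product (a-o) x (b-o); int64-exact on grid coordinates."""
    return (a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1]) - (
        a[..., 1] - o[..., 1]
    ) * (b[..., 0] - o[..., 0])


def segments_cross(p1, p2, p3, p4) -> np.ndarray:
    """Vectorized open-segment intersection test on integer endpoints.

    True iff the open segments (p1,p2) and (p3,p4) share a point: either a
    proper interior crossing (strict orientation changes on both sides) or a
    collinear overlap of positive length.  Touching at endpoints — including
    a T-junction where one endpoint lies on the other segment's interior —
    does not count.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=np.int64) for p in (p1, p2, p3, p4))
    d1 = _cross(p3, p4, p1)
    d2 = _cross(p3, p4, p2)
    d3 = _cross(p1, p2, p3)
    d4 = _cross(p1, p2, p4)
    proper = ((d1 > 0) != (d2 > 0)) & (d1 != 0) & (d2 != 0) \
        & ((d3 > 0) != (d4 > 0)) & (d3 != 0) & (d4 != 0)
    collinear = (d1 == 0) & (d2 == 0) & (d3 == 0) & (d4 == 0)
    # open-interval overlap along each axis for collinear pairs
    lo_x = np.maximum(np.minimum(p1[..., 0], p2[..., 0]), np.minimum(p3[..., 0], p4[..., 0]))
    hi_x = np.minimum(np.maximum(p1[..., 0], p2[..., 0]), np.maximum(p3[..., 0], p4[..., 0]))
    lo_y = np.maximum(np.minimum(p1[..., 1], p2[..., 1]), np.minimum(p3[..., 1], p4[..., 1]))
    hi_y = np.minimum(np.maximum(p1[..., 1], p2[..., 1]), np.maximum(p3[..., 1], p4[..., 1]))
    overlap = (hi_x - lo_x > 0) | (hi_y - lo_y > 0)
    return proper | (collinear & overlap)


def edge_edge_crossing_ratio(layout: GridLayout, network: Network) -> float:
    """Crossing edge pairs / C(m, 2)."""
    m = network.m
    if m < 2:
        raise ValueError("edge-edge crossing ratio needs at least two edges")
    pts, ends = _segment_arrays(layout, network)
    ii, jj = np.triu_indices(m, k=1)
    a, b = ends[ii, 0], ends[ii, 1]
    c, d = ends[jj, 0], ends[jj, 1]
    crossing = segments_cross(pts[a], pts[b], pts[c], pts[d])
    # pairs sharing a node can still cross via collinear overlap, which
    # segments_cross already classifies correctly; nothing to mask out
    total_pairs = m * (m - 1) // 2
    return float(crossing.sum()) / total_pairs


def node_edge_crossing_ratio(
    layout: GridLayout, network: Network, eps: float = 0.5
) -> float:
    """(node, edge) incidences within ``eps`` of the segment / (n*m - 2m)."""
    n, m = network.n, network.m
    if n < 1 or m < 1:
        raise ValueError("node-edge crossing ratio needs nodes and edges")
    denom = n * m - 2 * m
    if denom <= 0:
        return 0.0
    pts, ends = _segment_arrays(layout, network)
    P = pts.astype(np.float64)
    A = P[ends[:, 0]]  # (m, 2)
    B = P[ends[:, 1]]
    AB = B - A
    ab2 = (AB ** 2).sum(axis=1)  # positive: injective layout
    # distance from every node to every segment, (n, m)
    AP = P[:, None, :] - A[None, :, :]
    t = np.clip((AP * AB[None, :, :]).sum(axis=2) / ab2[None, :], 0.0, 1.0)
    closest = A[None, :, :] + t[:, :, None] * AB[None, :, :]
    dist = np.sqrt(((P[:, None, :] - closest) ** 2).sum(axis=2))
    near = dist <= eps
    node_idx = np.arange(n)
    is_endpoint = (node_idx[:, None] == ends[None, :, 0]) | (
        node_idx[:, None] == ends[None, :, 1]
    )
    count = int((near & ~is_endpoint).sum())
    return count / denom


def evaluate_layout(
    layout: GridLayout,
    network: Network,
    alpha: float = 0.5,
    eps: float = 0.5,
) -> LayoutMetrics:
    """All four metrics in one pass (requires m >= 2)."""
    return LayoutMetrics(
        connectivity_f=connectivity_f_measure(layout, network, alpha),
        relative_edge_length=relative_edge_length(layout, network),
        edge_edge_ratio=edge_edge_crossing_ratio(layout, network),
        node_edge_ratio=node_edge_crossing_ratio(layout, network, eps),
        alpha=alpha,
        eps=eps,
    )
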