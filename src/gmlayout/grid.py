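"""Grid-layout machinery: cost function and reoptimization-after-perturbation.

All entities (modules in stage 2, nodes in stage 3) live on integer grid
points, at most one entity per point.  The layout quality is the weighted sum
of Manhattan distances over entity pairs,

    C(W, R) = sum_{i<j} w_ij * d_ij,      d_ij = |x_i - x_j| + |y_i - y_j|,

and is minimized by *reoptimization-after-perturbation*: greedy single-entity
descent to a local optimum, then a random kick (each entity moves to a random
vacant neighboring point with some probability), re-descent, and acceptance of
the lower-cost layout, repeated for a fixed number of iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Rect",
    "GridLayout",
    "WeightMatrix",
    "OptimizerParams",
    "manhattan",
    "layout_cost",
    "partial_optimize",
    "perturb",
    "reoptimize_after_perturbation",
    "random_layout",
]

# Scan order N, NE, E, SE, S, SW, W, NW with y pointing down (screen
# convention); ties in the descent are broken by this order.
_OFFSETS_MOORE: tuple[tuple[int, int], ...] = (
    (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1),
)
_OFFSETS_VON_NEUMANN: tuple[tuple[int, int], ...] = ((0, -1), (1, 0), (0, 1), (-1, 0))


def neighborhood_offsets(neighborhood: str) -> tuple[tuple[int, int], ...]:
    if neighborhood == "moore":
        return _OFFSETS_MOORE
    if neighborhood == "von_neumann":
        return _OFFSETS_VON_NEUMANN
    raise ValueError(f"unknown neighborhood {neighborhood!r} (use 'moore' or 'von_neumann')")


@dataclass(frozen=True)
class Rect:
    """Closed rectangle of grid points: x0 <= x <= x1, y0 <= y <= y1."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValueError(f"degenerate rectangle {self}")

    def contains(self, p: tuple[int, int]) -> bool:
        return self.x0 <= p[0] <= self.x1 and self.y0 <= p[1] <= self.y1

    @property
    def capacity(self) -> int:
        return (self.x1 - self.x0 + 1) * (self.y1 - self.y0 + 1)

    def points(self) -> list[tuple[int, int]]:
        """All grid points, row-major (y outer, x inner)."""
        return [
            (x, y)
            for y in range(self.y0, self.y1 + 1)
            for x in range(self.x0, self.x1 + 1)
        ]

    def intersects(self, other: "Rect") -> bool:
        return not (
            self.x1 < other.x0
            or other.x1 < self.x0
            or self.y1 < other.y0
            or other.y1 < self.y0
        )


class GridLayout:
    """Injective mapping entity-id -> integer grid point, with optional bounds.

    ``bounds`` may be a single :class:`Rect` applying to every entity or a
    mapping entity-id -> Rect (used in stage 3, where each node is confined to
    its module's square region).  Injectivity — no two entities on the same
    grid point — is enforced at construction and preserved by every optimizer
    operation.
    """

    __slots__ = ("_pos", "_bounds")

    def __init__(
        self,
        pos: Mapping[str, tuple[int, int]],
        bounds: Rect | Mapping[str, Rect] | None = None,
    ):
        self._pos: dict[str, tuple[int, int]] = {
            str(k): (int(x), int(y)) for k, (x, y) in pos.items()
        }
        occupied = set(self._pos.values())
        if len(occupied) != len(self._pos):
            raise ValueError("layout is not injective: two entities share a grid point")
        self._bounds = dict(bounds) if isinstance(bounds, Mapping) else bounds
        for e, p in self._pos.items():
            b = self.bounds_of(e)
            if b is not None and not b.contains(p):
                raise ValueError(f"entity {e!r} at {p} lies outside its bounds {b}")

    @property
    def pos(self) -> dict[str, tuple[int, int]]:
        return dict(self._pos)

    @property
    def bounds(self):
        return dict(self._bounds) if isinstance(self._bounds, dict) else self._bounds

    def bounds_of(self, entity: str) -> Rect | None:
        if self._bounds is None:
            return None
        if isinstance(self._bounds, dict):
            return self._bounds.get(entity)
        return self._bounds

    def __getitem__(self, entity: str) -> tuple[int, int]:
        return self._pos[entity]

    def __contains__(self, entity: object) -> bool:
        return entity in self._pos

    def __len__(self) -> int:
        return len(self._pos)

    def __iter__(self):
        return iter(self._pos)

    def items(self):
        return self._pos.items()

    def entities(self) -> tuple[str, ...]:
        return tuple(self._pos)

    def occupied(self) -> frozenset[tuple[int, int]]:
        return frozenset(self._pos.values())

    def translate(self, dx: int, dy: int) -> "GridLayout":
        """Translated copy; bounds are dropped (used for invariance checks)."""
        return GridLayout({e: (x + dx, y + dy) for e, (x, y) in self._pos.items()})

    def replace_positions(self, pos: Mapping[str, tuple[int, int]]) -> "GridLayout":
        return GridLayout(pos, self._bounds)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridLayout):
            return NotImplemented
        return self._pos == other._pos

    def __repr__(self) -> str:
        return f"GridLayout({len(self._pos)} entities)"


class WeightMatrix:
    """Symmetric pairwise weights; absent pairs weigh 0, diagonal is ignored."""

    __slots__ = ("_w",)

    def __init__(self, weights: Mapping[tuple[str, str], float] | None = None):
        self._w: dict[tuple[str, str], float] = {}
        if weights:
            for (i, j), v in weights.items():
                self.set(i, j, v)

    @staticmethod
    def _key(i: str, j: str) -> tuple[str, str]:
        if i == j:
            raise ValueError(f"diagonal weight ({i!r},{i!r}) is not defined")
        return (i, j) if i <= j else (j, i)

    def set(self, i: str, j: str, value: float) -> None:
        key = self._key(i, j)
        if value == 0:
            self._w.pop(key, None)
        else:
            self._w[key] = float(value)

    def get(self, i: str, j: str) -> float:
        return self._w.get(self._key(i, j), 0.0)

    def items(self):
        return self._w.items()

    def entities(self) -> tuple[str, ...]:
        """Entities appearing in any nonzero weight, in first-appearance order."""
        seen: dict[str, None] = {}
        for i, j in self._w:
            seen.setdefault(i)
            seen.setdefault(j)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self._w)

    def __repr__(self) -> str:
        return f"WeightMatrix({len(self._w)} nonzero pairs)"


@dataclass(frozen=True)
class OptimizerParams:
    """Knobs of reoptimization-after-perturbation.

    niter
        number of perturb+reoptimize rounds after the initial descent.
    perturb_prob
        per-entity probability of a random kick each round.
    seed
        seeds all randomness; identical inputs and seed give identical output.
    """

    niter: int = 200
    perturb_prob: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.niter < 0:
            raise ValueError("niter must be >= 0")
        if not 0.0 <= self.perturb_prob <= 1.0:
            raise ValueError("perturb_prob must lie in [0, 1]")


def manhattan(a: tuple[int, int], b: tuple[int, int]) -> int:
    """|x_a - x_b| + |y_a - y_b| — the grid distance used in all cost terms."""
    return abs(a[0] - b[0]) + abs(a[1] - b[1])


# ---------------------------------------------------------------------------
# internal array engine


class _Engine:
    """Array-backed state for the optimizer; deterministic given inputs.

    Entities are indexed in layout insertion order; positions are int64
    arrays so candidate-move deltas vectorize over all other entities.
    """

    def __init__(self, w: WeightMatrix, layout: GridLayout, neighborhood: str = "moore"):
        self.ids: list[str] = list(layout.entities())
        index = {e: k for k, e in enumerate(self.ids)}
        for (i, j), _v in w.items():
            for e in (i, j):
                if e not in index:
                    raise ValueError(f"weighted entity {e!r} is missing from the layout")
        n = len(self.ids)
        self.W = np.zeros((n, n), dtype=np.float64)
        for (i, j), v in w.items():
            a, b = index[i], index[j]
            self.W[a, b] = self.W[b, a] = v
        self.X = np.array([layout[e][0] for e in self.ids], dtype=np.int64)
        self.Y = np.array([layout[e][1] for e in self.ids], dtype=np.int64)
        self.bounds: list[Rect | None] = [layout.bounds_of(e) for e in self.ids]
        self._layout_bounds = layout.bounds
        self.occ: dict[tuple[int, int], int] = {
            (int(x), int(y)): k for k, (x, y) in enumerate(zip(self.X, self.Y))
        }
        self.offsets = neighborhood_offsets(neighborhood)

    def cost(self) -> float:
        d = np.abs(self.X[:, None] - self.X[None, :]) + np.abs(
            self.Y[:, None] - self.Y[None, :]
        )
        return float((self.W * d).sum() / 2.0)

    def _candidates(self, k: int) -> list[tuple[int, int]]:
        x, y = int(self.X[k]), int(self.Y[k])
        b = self.bounds[k]
        out = []
        for dx, dy in self.offsets:
            p = (x + dx, y + dy)
            if p in self.occ:
                continue
            if b is not None and not b.contains(p):
                continue
            out.append(p)
        return out

    def sweep(self) -> bool:
        """One pass of steepest single-entity descent; True if any move made."""
        moved = False
        for k in range(len(self.ids)):
            cands = self._candidates(k)
            if not cands:
                continue
            wrow = self.W[k]
            cur = np.abs(self.X - self.X[k]) + np.abs(self.Y - self.Y[k])
            cx = np.array([p[0] for p in cands], dtype=np.int64)
            cy = np.array([p[1] for p in cands], dtype=np.int64)
            cd = np.abs(cx[:, None] - self.X[None, :]) + np.abs(
                cy[:, None] - self.Y[None, :]
            )
            # wrow[k] == 0, so the self-distance column contributes nothing
            deltas = (cd - cur[None, :]) @ wrow
            best = int(np.argmin(deltas))  # first minimum = scan-order tie-break
            if deltas[best] < 0.0:
                old = (int(self.X[k]), int(self.Y[k]))
                new = cands[best]
                del self.occ[old]
                self.occ[new] = k
                self.X[k], self.Y[k] = new
                moved = True
        return moved

    def optimize(self) -> None:
        while self.sweep():
            pass

    def perturb(self, prob: float, rng: np.random.Generator) -> None:
        for k in range(len(self.ids)):
            if rng.random() >= prob:
                continue
            cands = self._candidates(k)
            if not cands:
                continue
            new = cands[int(rng.integers(len(cands)))]
            old = (int(self.X[k]), int(self.Y[k]))
            del self.occ[old]
            self.occ[new] = k
            self.X[k], self.Y[k] = new

    def snapshot(self) -> tuple[np.ndarray, np.ndarray]:
        return self.X.copy(), self.Y.copy()

    def restore(self, state: tuple[np.ndarray, np.ndarray]) -> None:
        self.X, self.Y = state[0].copy(), state[1].copy()
        self.occ = {(int(x), int(y)): k for k, (x, y) in enumerate(zip(self.X, self.Y))}

    def to_layout(self) -> GridLayout:
        pos = {e: (int(self.X[k]), int(self.Y[k])) for k, e in enumerate(self.ids)}
        return GridLayout(pos, self._layout_bounds)


# ---------------------------------------------------------------------------
# public operations


def layout_cost(w: WeightMatrix, layout: GridLayout) -> float:
    """C(W, R): sum over unordered pairs of w_ij times Manhattan distance."""
    return _Engine(w, layout).cost()


def partial_optimize(
    w: WeightMatrix, layout: GridLayout, neighborhood: str = "moore"
) -> GridLayout:
    """Greedy descent: repeatedly move single entities to their best adjacent
    vacant grid point until no single move lowers the cost.

    Entities are swept in insertion order; each commits the strictly
    improving neighbor move with the largest decrease (ties broken by scan
    order N, NE, E, SE, S, SW, W, NW).  The result never costs more than the
    input and occupies distinct grid points.
    """
    eng = _Engine(w, layout, neighborhood)
    eng.optimize()
    return eng.to_layout()


def perturb(
    layout: GridLayout,
    perturb_prob: float,
    rng: np.random.Generator,
    neighborhood: str = "moore",
) -> GridLayout:
    """Random kick: each entity independently moves, with probability
    ``perturb_prob``, to a uniformly chosen vacant neighboring point (staying
    put if every neighbor is occupied or out of bounds)."""
    eng = _Engine(WeightMatrix(), layout, neighborhood)
    eng.perturb(perturb_prob, rng)
    return eng.to_layout()


def reoptimize_after_perturbation(
    w: WeightMatrix,
    initial: GridLayout,
    params: OptimizerParams,
    neighborhood: str = "moore",
) -> GridLayout:
    """Full optimization loop: descend, then ``niter`` rounds of kick +
    re-descent, keeping whichever layout costs less each round."""
    eng = _Engine(w, initial, neighborhood)
    rng = np.random.default_rng(params.seed)
    eng.optimize()
    best = eng.snapshot()
    best_cost = eng.cost()
    for _ in range(params.niter):
        eng.perturb(params.perturb_prob, rng)
        eng.optimize()
        c = eng.cost()
        if c < best_cost:
            best = eng.snapshot()
            best_cost = c
        else:
            eng.restore(best)
    eng.restore(best)
    return eng.to_layout()


def random_layout(
    entities: Sequence[str], seed: int, side: int | None = None
) -> GridLayout:
    """Uniform injective placement of ``entities`` on a square board.

    Default board side is ceil(sqrt(2k)) for k entities, i.e. roughly half
    the grid points occupied — a density comparable to optimized layouts.
    """
    entities = list(entities)
    k = len(entities)
    if k == 0:
        return GridLayout({})
    if side is None:
        side = int(np.ceil(np.sqrt(2.0 * k)))
    if side * side < k:
        raise ValueError(f"board {side}x{side} cannot hold {k} entities")
    rng = np.random.default_rng(seed)
    board = Rect(0, 0, side - 1, side - 1)
    pts = board.points()
    chosen = rng.choice(len(pts), size=k, replace=False)
    return GridLayout({e: pts[int(i)] for e, i in zip(entities, chosen)})
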