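"""Embedding pathway networks into compact 2D lattice grids.

A pathway graph G = (V, E) is placed injectively onto an m x n lattice so
that the total Manhattan distance summed over the edges of G is as small
as possible — adjacent reactions end up on neighboring grid cells wherever
the topology allows it.  The optimum is computed by an exact mixed-integer
program over binary node-to-cell assignment variables (Manhattan distances
linearized through row/column absolute-difference variables); larger
instances fall back to a seeded simulated-annealing heuristic.  A
brute-force enumerator over all injective placements serves as an
independent optimality oracle for small instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .network import PathwayNetwork

__all__ = [
    "LatticeGrid",
    "GridEmbedding",
    "EmbeddingError",
    "choose_grid_dimensions",
    "embed_exact",
    "embed_heuristic",
    "embed",
    "brute_force_oracle",
    "total_length",
    "canonicalize_placement",
]

DEFAULT_EXACT_LIMIT = 16


class EmbeddingError(RuntimeError):
    """Raised when an embedding cannot be produced (infeasible or timed out)."""


@dataclass(frozen=True)
class LatticeGrid:
    """A rows x cols lattice of cells addressed by 0-based (row, col)."""

    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def cells(self) -> list[tuple[int, int]]:
        return [(r, c) for r in range(self.rows) for c in range(self.cols)]


@dataclass
class GridEmbedding:
    """Injective placement of network nodes onto a lattice grid.

    ``total_length`` is the sum over edges of the Manhattan distance of the
    two endpoint cells; ``optimal`` records whether it is a proven global
    minimum (exact solver) or a heuristic value.
    """

    grid: LatticeGrid
    placement: dict[str, tuple[int, int]]
    total_length: int
    optimal: bool

    def __post_init__(self) -> None:
        cells = list(self.placement.values())
        if len(set(cells)) != len(cells):
            raise ValueError("placement is not injective")
        for r, c in cells:
            if not (0 <= r < self.grid.rows and 0 <= c < self.grid.cols):
                raise ValueError(f"cell ({r}, {c}) outside {self.grid.rows}x{self.grid.cols} grid")


def choose_grid_dimensions(n_nodes: int) -> LatticeGrid:
    """Smallest near-square grid holding ``n_nodes``: cols = ceil(sqrt(n))."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    cols = math.isqrt(n_nodes)
    if cols * cols < n_nodes:
        cols += 1
    rows = -(-n_nodes // cols)
    return LatticeGrid(rows=rows, cols=cols)


def total_length(net: PathwayNetwork, placement: dict[str, tuple[int, int]]) -> int:
    """Total Manhattan edge length of a placement."""
    out = 0
    for u, v in net.edges:
        (ru, cu), (rv, cv) = placement[u], placement[v]
        out += abs(ru - rv) + abs(cu - cv)
    return out


def _grid_symmetries(grid: LatticeGrid):
    """The symmetries of the lattice: 4 for rectangles, 8 for squares."""
    R, C = grid.rows, grid.cols
    syms = [
        lambda r, c: (r, c),
        lambda r, c: (R - 1 - r, c),
        lambda r, c: (r, C - 1 - c),
        lambda r, c: (R - 1 - r, C - 1 - c),
    ]
    if R == C:
        syms += [
            lambda r, c: (c, r),
            lambda r, c: (C - 1 - c, r),
            lambda r, c: (c, R - 1 - r),
            lambda r, c: (C - 1 - c, R - 1 - r),
        ]
    return syms


def canonicalize_placement(
    placement: dict[str, tuple[int, int]], grid: LatticeGrid
) -> dict[str, tuple[int, int]]:
    """Pick, among the grid symmetries of a placement, the lexicographically
    smallest placement vector (nodes sorted by id).  Distances are invariant
    under all of these, so the choice is a reproducibility tie-break only."""
    nodes = sorted(placement)
    best = None
    for sym in _grid_symmetries(grid):
        vec = tuple(sym(*placement[v]) for v in nodes)
        if best is None or vec < best:
            best = vec
    return dict(zip(nodes, best))


def embed_exact(
    net: PathwayNetwork,
    grid: LatticeGrid | None = None,
    time_limit: float | None = None,
) -> GridEmbedding:
    """Optimal embedding by mixed-integer programming.

    Minimizes the total Manhattan edge length over all injective placements
    (proven optimum).  Binary variables x[v, c] assign node v to cell c;
    per edge, two continuous variables bound the row and column coordinate
    differences from above and below, so their minimized sum equals the
    Manhattan distance.  One symmetry-breaking restriction confines a
    highest-degree anchor node to the fundamental domain of the grid's
    symmetry group (a quarter, or an eighth for square grids), which
    removes mirror-image duplicates without excluding any optimal length.
    """
    if grid is None:
        grid = choose_grid_dimensions(max(net.n_nodes, 1))
    n = net.n_nodes
    if grid.n_cells < n:
        raise EmbeddingError(f"grid {grid.rows}x{grid.cols} too small for {n} nodes")
    cells = grid.cells()
    nc = grid.n_cells
    nodes = net.nodes

    edges_idx = [(nodes.index(u), nodes.index(v)) for u, v in net.edges]
    if not edges_idx:
        placement = {v: cells[i] for i, v in enumerate(nodes)}
        placement = canonicalize_placement(placement, grid)
        return GridEmbedding(grid=grid, placement=placement, total_length=0, optimal=True)

    ne = len(edges_idx)
    nx_vars = n * nc  # assignment block, then 2*ne distance vars (row, col per edge)
    nvars = nx_vars + 2 * ne

    def xi(v: int, c: int) -> int:
        return v * nc + c

    rows_of_cell = np.array([r for r, _ in cells], dtype=float)
    cols_of_cell = np.array([c for _, c in cells], dtype=float)

    data, ri, ci = [], [], []
    lb, ub = [], []
    row = 0

    # each node on exactly one cell
    for v in range(n):
        for c in range(nc):
            ri.append(row); ci.append(xi(v, c)); data.append(1.0)
        lb.append(1.0); ub.append(1.0)
        row += 1
    # each cell holds at most one node
    for c in range(nc):
        for v in range(n):
            ri.append(row); ci.append(xi(v, c)); data.append(1.0)
        lb.append(0.0); ub.append(1.0)
        row += 1
    # distance linearization: d_e >= +-(pos_u - pos_v) for rows and columns
    for e, (u, v) in enumerate(edges_idx):
        for coord, pos in ((0, rows_of_cell), (1, cols_of_cell)):
            dvar = nx_vars + 2 * e + coord
            for sign in (1.0, -1.0):
                for c in range(nc):
                    if pos[c] != 0.0:
                        ri.append(row); ci.append(xi(u, c)); data.append(sign * pos[c])
                        ri.append(row); ci.append(xi(v, c)); data.append(-sign * pos[c])
                ri.append(row); ci.append(dvar); data.append(-1.0)
                lb.append(-np.inf); ub.append(0.0)
                row += 1

    # valid cuts that tighten the LP relaxation (the position linearization
    # alone lets fractional solutions collapse all distances to zero):
    # (a) endpoints of an edge occupy distinct cells, so d_row + d_col >= 1
    for e in range(ne):
        ri.append(row); ci.append(nx_vars + 2 * e); data.append(1.0)
        ri.append(row); ci.append(nx_vars + 2 * e + 1); data.append(1.0)
        lb.append(1.0); ub.append(np.inf)
        row += 1
    # (b) a node of degree d has at most 4 cells at distance 1, 8 at
    # distance 2, ... around it, so its incident edges sum to at least
    # f(d) = sum of the d smallest available distances (infinite-grid
    # bound, valid a fortiori on a finite grid)
    ring = []
    dist_val = 1
    while len(ring) < n:
        ring.extend([dist_val] * (4 * dist_val))
        dist_val += 1
    for v in range(n):
        incident = [e for e, (u, w) in enumerate(edges_idx) if v in (u, w)]
        if len(incident) < 2:
            continue
        for e in incident:
            ri.append(row); ci.append(nx_vars + 2 * e); data.append(1.0)
            ri.append(row); ci.append(nx_vars + 2 * e + 1); data.append(1.0)
        lb.append(float(sum(ring[: len(incident)]))); ub.append(np.inf)
        row += 1

    # symmetry breaking: anchor node confined to the fundamental domain
    anchor = int(np.argmax(net.adjacency.sum(axis=1)))
    allowed = set()
    for c, (r, cc) in enumerate(cells):
        if 2 * r <= grid.rows - 1 and 2 * cc <= grid.cols - 1:
            if grid.rows != grid.cols or r <= cc:
                allowed.add(c)
    for c in range(nc):
        if c not in allowed:
            ri.append(row); ci.append(xi(anchor, c)); data.append(1.0)
            lb.append(0.0); ub.append(0.0)
            row += 1

    A = sparse.csr_matrix((data, (ri, ci)), shape=(row, nvars))
    cost = np.zeros(nvars)
    cost[nx_vars:] = 1.0
    integrality = np.ones(nvars)  # distance vars are integral at optimum;
    # declaring them so helps the branch-and-bound
    bounds_lb = np.zeros(nvars)
    bounds_ub = np.full(nvars, np.inf)
    bounds_ub[:nx_vars] = 1.0

    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=cost,
        constraints=LinearConstraint(A, lb, ub),
        integrality=integrality,
        bounds=Bounds(bounds_lb, bounds_ub),
        options=options,
    )
    if res.status == 1:  # iteration/time limit
        raise EmbeddingError(
            "exact embedding timed out; rerun with a larger time limit or "
            "use embed_heuristic"
        )
    if not res.success:
        raise EmbeddingError(f"exact embedding failed: {res.message}")

    x = np.asarray(res.x[:nx_vars]).reshape(n, nc)
    placement = {nodes[v]: cells[int(np.argmax(x[v]))] for v in range(n)}
    placement = canonicalize_placement(placement, grid)
    return GridEmbedding(
        grid=grid,
        placement=placement,
        total_length=total_length(net, placement),
        optimal=True,
    )


def embed_heuristic(
    net: PathwayNetwork,
    grid: LatticeGrid | None = None,
    seed: int = 0,
    n_iter: int | None = None,
) -> GridEmbedding:
    """Simulated-annealing embedding for instances too large for the MILP.

    Starts from a breadth-first placement (neighbors placed early end up
    near each other), then anneals with swap/relocate moves between random
    cell pairs under a geometric cooling schedule.  Deterministic for a
    given seed; the result is valid but not certified optimal.
    """
    if grid is None:
        grid = choose_grid_dimensions(max(net.n_nodes, 1))
    n = net.n_nodes
    if grid.n_cells < n:
        raise EmbeddingError(f"grid {grid.rows}x{grid.cols} too small for {n} nodes")
    rng = np.random.default_rng(seed)
    cells = grid.cells()
    nc = grid.n_cells
    nodes = net.nodes
    pos = {v: i for i, v in enumerate(nodes)}

    # BFS order from a highest-degree node, deterministic tie-breaks
    degree = net.adjacency.sum(axis=1).astype(int)
    order: list[int] = []
    seen: set[int] = set()
    remaining = sorted(range(n), key=lambda i: (-degree[i], nodes[i]))
    g = net.graph()
    for start in remaining:
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        while queue:
            u = queue.pop(0)
            order.append(u)
            nbrs = sorted((pos[w] for w in g.neighbors(nodes[u])), key=lambda i: (-degree[i], nodes[i]))
            for w in nbrs:
                if w not in seen:
                    seen.add(w)
                    queue.append(w)

    # snake order over cells keeps consecutive cells adjacent
    snake = []
    for r in range(grid.rows):
        rowcells = list(range(r * grid.cols, (r + 1) * grid.cols))
        snake.extend(rowcells if r % 2 == 0 else rowcells[::-1])

    cell_of_node = np.full(n, -1, dtype=int)
    node_of_cell = np.full(nc, -1, dtype=int)
    for node_i, cell_i in zip(order, snake):
        cell_of_node[node_i] = cell_i
        node_of_cell[cell_i] = node_i

    rpos = np.array([r for r, _ in cells])
    cpos = np.array([c for _, c in cells])
    D = np.abs(rpos[:, None] - rpos[None, :]) + np.abs(cpos[:, None] - cpos[None, :])
    adj_lists = [np.flatnonzero(net.adjacency[i]) for i in range(n)]

    def node_cost(v: int, cell: int) -> int:
        nbr_cells = cell_of_node[adj_lists[v]]
        return int(D[cell, nbr_cells].sum())

    cur = total_length(net, {nodes[v]: cells[cell_of_node[v]] for v in range(n)})
    best = cur
    best_cells = cell_of_node.copy()

    if n_iter is None:
        n_iter = max(3000, 150 * nc * nc)
    temp = 2.0
    cooling = (0.01 / temp) ** (1.0 / max(n_iter, 1))
    for _ in range(n_iter):
        c1, c2 = rng.integers(0, nc, size=2)
        if c1 == c2:
            temp *= cooling
            continue
        v1, v2 = node_of_cell[c1], node_of_cell[c2]
        if v1 < 0 and v2 < 0:
            temp *= cooling
            continue
        delta = 0
        if v1 >= 0:
            delta += node_cost(v1, c2) - node_cost(v1, c1)
        if v2 >= 0:
            delta += node_cost(v2, c1) - node_cost(v2, c2)
        if v1 >= 0 and v2 >= 0 and net.adjacency[v1, v2]:
            # node_cost saw the partner at its stale cell for the shared edge:
            # it charged 0 twice instead of D[c1, c2] twice (swap leaves the
            # shared edge length unchanged)
            delta += 2 * int(D[c1, c2])
        if delta < 0 or rng.random() < math.exp(-delta / max(temp, 1e-12)):
            node_of_cell[c1], node_of_cell[c2] = v2, v1
            if v1 >= 0:
                cell_of_node[v1] = c2
            if v2 >= 0:
                cell_of_node[v2] = c1
            cur += delta
            if cur < best:
                best = cur
                best_cells = cell_of_node.copy()
        temp *= cooling

    placement = {nodes[v]: cells[best_cells[v]] for v in range(n)}
    placement = canonicalize_placement(placement, grid)
    return GridEmbedding(
        grid=grid,
        placement=placement,
        total_length=total_length(net, placement),
        optimal=False,
    )


def embed(
    net: PathwayNetwork,
    grid: LatticeGrid | None = None,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
    seed: int = 0,
    time_limit: float | None = None,
) -> GridEmbedding:
    """Embed a network: exact MILP up to ``exact_limit`` nodes, else annealing."""
    if net.n_nodes <= exact_limit:
        return embed_exact(net, grid, time_limit=time_limit)
    return embed_heuristic(net, grid, seed=seed)


@lru_cache(maxsize=32)
def _placement_array(n_cells: int, n_nodes: int) -> np.ndarray:
    perms = itertools.permutations(range(n_cells), n_nodes)
    return np.array(list(perms), dtype=np.int8)


def brute_force_oracle(net: PathwayNetwork, grid: LatticeGrid) -> int:
    """Exhaustive minimum total Manhattan length over all injective placements.

    Independent of the MILP path; restricted to grids of at most 9 cells
    (enumeration over n_cells! / (n_cells - n)! placements).
    """
    if grid.n_cells > 9:
        raise ValueError("brute-force oracle restricted to grids of <= 9 cells")
    n = net.n_nodes
    if grid.n_cells < n:
        raise EmbeddingError(f"grid {grid.rows}x{grid.cols} too small for {n} nodes")
    if n == 0:
        return 0
    cells = grid.cells()
    rpos = np.array([r for r, _ in cells])
    cpos = np.array([c for _, c in cells])
    D = np.abs(rpos[:, None] - rpos[None, :]) + np.abs(cpos[:, None] - cpos[None, :])
    P = _placement_array(grid.n_cells, n)
    nodes = net.nodes
    cost = np.zeros(len(P), dtype=np.int64)
    for u, v in net.edges:
        iu, iv = nodes.index(u), nodes.index(v)
        cost += D[P[:, iu], P[:, iv]]
    return int(cost.min())
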