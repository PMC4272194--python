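"""Spatial, spatio-temporal and extended adjacency structures and their ICAR precisions.

The spatio-temporal neighbourhood matrix ``W`` couples K areal units over T
consecutive periods: within period t a binary spatial adjacency ``U(t)`` links
areas sharing a border, and between consecutive periods a diagonal binary matrix
``V(t, t+1) <= I`` links each area to itself one period ahead.  In the global
smoothing state every permitted element equals one.  Localised smoothing treats
each permitted element as a binary quantity; to keep every cell's conditional
variance finite when relations are switched off, the adjacency is extended with
a global effect ``phi*`` whose link ``w*[k, t]`` switches on exactly when at
least one of the cell's permitted relations is currently zero.

Cells are vectorised time-major: cell (k, t) maps to index ``t * K + k`` so that
``W`` is block-tridiagonal with the spatial blocks on the diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SpatialGraph",
    "STAdjacency",
    "EdgeSet",
    "ExtendedAdjacency",
    "PrecisionMatrix",
    "build_st_adjacency",
    "icar_precision",
    "extend_with_global",
    "conditional_moments",
    "partial_correlation",
]


@dataclass(frozen=True)
class SpatialGraph:
    """K areal units and their symmetric binary spatial adjacency.

    Parameters
    ----------
    n_areas:
        Number of areal units K.
    edges:
        Unordered pairs ``(k, i)`` of 0-based area indices sharing a border,
        stored sorted with ``k < i``.
    labels:
        Optional area identifiers, position-aligned with indices.
    """

    n_areas: int
    edges: tuple[tuple[int, int], ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_areas < 1:
            raise ValueError("graph must contain at least one area")
        canon = sorted({(min(a, b), max(a, b)) for a, b in self.edges})
        for a, b in canon:
            if a == b:
                raise ValueError(f"self-loop on area {a}")
            if not (0 <= a < self.n_areas and 0 <= b < self.n_areas):
                raise ValueError(f"edge ({a},{b}) references an area >= {self.n_areas}")
        object.__setattr__(self, "edges", tuple(canon))
        if self.labels is not None:
            if len(self.labels) != self.n_areas:
                raise ValueError("labels length must equal n_areas")
            object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        deg = self.degrees()
        if self.n_areas > 1 and np.any(deg == 0):
            isolated = np.flatnonzero(deg == 0).tolist()
            warnings.warn(
                f"areas {isolated} have no spatial neighbours; their cells rely "
                "on temporal links and the global effect",
                stacklevel=2,
            )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_areas, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def adjacency_matrix(self) -> sp.csr_array:
        """The K x K binary matrix U."""
        if not self.edges:
            return sp.csr_array((self.n_areas, self.n_areas))
        rows = [a for a, b in self.edges] + [b for a, b in self.edges]
        cols = [b for a, b in self.edges] + [a for a, b in self.edges]
        data = np.ones(2 * self.n_edges)
        return sp.csr_array((data, (rows, cols)), shape=(self.n_areas, self.n_areas))

    def neighbours(self, k: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == k:
                out.append(b)
            elif b == k:
                out.append(a)
        return sorted(out)


class STAdjacency:
    """The KT x KT block spatio-temporal neighbourhood matrix W, element-mutable.

    ``spatial_state[t, e]`` holds the element of ``U(t)`` for spatial edge ``e``
    (in the order of ``graph.edges``); ``temporal_state[k, t]`` holds the
    diagonal element of ``V(t, t+1)`` for area k.  Both are binary.
    """

    def __init__(self, graph: SpatialGraph, n_periods: int):
        if n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        self.graph = graph
        self.n_periods = int(n_periods)
        self.spatial_state = np.ones((self.n_periods, graph.n_edges), dtype=np.uint8)
        self.temporal_state = np.ones(
            (graph.n_areas, max(self.n_periods - 1, 0)), dtype=np.uint8
        )
        if self.n_periods == 1:
            warnings.warn(
                "T=1 collapses the model to the purely spatial localised CAR",
                stacklevel=2,
            )

    @property
    def n_areas(self) -> int:
        return self.graph.n_areas

    @property
    def n_cells(self) -> int:
        return self.graph.n_areas * self.n_periods

    def cell_index(self, k: int, t: int) -> int:
        """Time-major vectorisation: (k, t) -> t*K + k."""
        return t * self.n_areas + k

    def n_estimable(self) -> int:
        """T*|edges| spatial plus K*(T-1) temporal elements."""
        return self.n_periods * self.graph.n_edges + self.n_areas * (self.n_periods - 1)

    def copy(self) -> "STAdjacency":
        out = STAdjacency.__new__(STAdjacency)
        out.graph = self.graph
        out.n_periods = self.n_periods
        out.spatial_state = self.spatial_state.copy()
        out.temporal_state = self.temporal_state.copy()
        return out

    def matrix(self) -> sp.csr_array:
        """Assemble the KT x KT symmetric binary matrix W."""
        K, T = self.n_areas, self.n_periods
        rows, cols = [], []
        edges = self.graph.edges
        for t in range(T):
            base = t * K
            on = np.flatnonzero(self.spatial_state[t])
            for e in on:
                a, b = edges[e]
                rows += [base + a, base + b]
                cols += [base + b, base + a]
        for t in range(T - 1):
            on = np.flatnonzero(self.temporal_state[:, t])
            for k in on:
                i, j = t * K + k, (t + 1) * K + k
                rows += [i, j]
                cols += [j, i]
        n = K * T
        if not rows:
            return sp.csr_array((n, n))
        data = np.ones(len(rows))
        return sp.csr_array((data, (rows, cols)), shape=(n, n))

    def cell_degree(self, k: int, t: int) -> int:
        """Number of currently-on spatial + temporal relations of cell (k, t)."""
        d = 0
        for e, (a, b) in enumerate(self.graph.edges):
            if k in (a, b):
                d += int(self.spatial_state[t, e])
        if t > 0:
            d += int(self.temporal_state[k, t - 1])
        if t < self.n_periods - 1:
            d += int(self.temporal_state[k, t])
        return d

    # --- EdgeSet round-trip -------------------------------------------------

    def to_edgeset(self) -> "EdgeSet":
        return EdgeSet.from_adjacency(self)

    def set_from_edgeset(self, es: "EdgeSet") -> None:
        T, m, K = self.n_periods, self.graph.n_edges, self.n_areas
        v = np.asarray(es.values, dtype=np.uint8)
        if v.size != self.n_estimable():
            raise ValueError("EdgeSet length does not match adjacency")
        self.spatial_state = v[: T * m].reshape(T, m).copy()
        self.temporal_state = v[T * m :].reshape(T - 1, K).T.copy() if T > 1 else self.temporal_state


@dataclass(frozen=True)
class EdgeSet:
    """Ordered binary vector over all estimable adjacency positions.

    Entry order: spatial elements ``(t, edge)`` for t ascending then edge index
    ascending, followed by temporal elements ``(t, k)`` for t ascending then k
    ascending.
    """

    entries: tuple[tuple, ...]
    values: np.ndarray = field(compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.uint8)
        if v.ndim != 1 or v.size != len(self.entries):
            raise ValueError("values must be a flat vector aligned with entries")
        if v.size and not np.isin(v, (0, 1)).all():
            raise ValueError("values must be binary")
        object.__setattr__(self, "values", v)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EdgeSet)
            and self.entries == other.entries
            and np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash((self.entries, self.values.tobytes()))

    def __len__(self) -> int:
        return len(self.entries)

    @staticmethod
    def from_adjacency(adj: STAdjacency) -> "EdgeSet":
        entries: list[tuple] = []
        for t in range(adj.n_periods):
            for a, b in adj.graph.edges:
                entries.append(("spatial", t, a, b))
        for t in range(adj.n_periods - 1):
            for k in range(adj.n_areas):
                entries.append(("temporal", t, k, k))
        vals = np.concatenate(
            [adj.spatial_state.ravel(), adj.temporal_state.T.ravel()]
        ) if adj.n_periods > 1 else adj.spatial_state.ravel().copy()
        return EdgeSet(tuple(entries), vals.astype(np.uint8))

    def n_zero(self) -> int:
        return int((self.values == 0).sum())


class ExtendedAdjacency:
    """The (KT+1) x (KT+1) matrix adjoining the global-effect links w*.

    ``w_star[c] = 1`` exactly when at least one permitted relation of cell c is
    currently zero; absent temporal terms at t=1 and t=T are skipped, not
    counted as zeros.  ``w_star`` is recomputed from the base state, never free.
    """

    def __init__(self, base: STAdjacency):
        self.base = base
        self.w_star = self._compute_w_star()

    def _compute_w_star(self) -> np.ndarray:
        adj = self.base
        K, T = adj.n_areas, adj.n_periods
        w = np.zeros(K * T, dtype=np.uint8)
        # any off spatial relation in the cell's period
        edge_a = np.array([a for a, b in adj.graph.edges], dtype=int)
        edge_b = np.array([b for a, b in adj.graph.edges], dtype=int)
        for t in range(T):
            off = adj.spatial_state[t] == 0
            if off.any():
                hit = np.unique(np.concatenate([edge_a[off], edge_b[off]]))
                w[t * K + hit] = 1
        # any off temporal relation touching the cell
        for t in range(T - 1):
            off = np.flatnonzero(adj.temporal_state[:, t] == 0)
            w[t * K + off] = 1
            w[(t + 1) * K + off] = 1
        return w

    def refresh(self) -> None:
        self.w_star = self._compute_w_star()

    @property
    def n_cells(self) -> int:
        return self.base.n_cells

    def matrix(self) -> sp.csr_array:
        """The full (KT+1) x (KT+1) symmetric matrix with the global effect last."""
        W = self.base.matrix()
        n = self.base.n_cells
        ws = sp.csr_array(self.w_star.reshape(1, n).astype(float))
        top = sp.hstack([W, ws.T])
        bottom = sp.hstack([ws, sp.csr_array((1, 1))])
        return sp.csr_array(sp.vstack([top, bottom]))

    def cell_degree(self, k: int, t: int) -> int:
        c = self.base.cell_index(k, t)
        return self.base.cell_degree(k, t) + int(self.w_star[c])


@dataclass(frozen=True)
class PrecisionMatrix:
    """An ICAR precision Q = diag(W 1) - W with scale multiplier tau."""

    Q: sp.csr_array
    scale: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    def rank(self) -> int:
        """n minus the number of connected components of the source graph.

        Isolated nodes count as their own components, so an all-zero row
        contributes nothing to the rank.
        """
        ncomp = sp.csgraph.connected_components(self.Q, directed=False)[0]
        return self.n - ncomp

    def quadratic_form(self, x: np.ndarray) -> float:
        return float(x @ (self.Q @ x))


def build_st_adjacency(graph: SpatialGraph, T: int) -> STAdjacency:
    """Global-smoothing spatio-temporal adjacency: every permitted element 1."""
    if not isinstance(T, (int, np.integer)) or T < 1:
        raise ValueError("T must be a positive integer")
    if graph.n_areas < 1:
        raise ValueError("graph is empty")
    return STAdjacency(graph, T)


def icar_precision(adjacency, tau: float = 1.0) -> PrecisionMatrix:
    """Q = diag(row sums) - W for a spatial, spatio-temporal or extended adjacency."""
    if isinstance(adjacency, SpatialGraph):
        W = adjacency.adjacency_matrix()
    elif isinstance(adjacency, STAdjacency):
        W = adjacency.matrix()
    elif isinstance(adjacency, ExtendedAdjacency):
        W = adjacency.matrix()
    elif sp.issparse(adjacency):
        W = sp.csr_array(adjacency)
    else:
        raise TypeError(f"unsupported adjacency type {type(adjacency)!r}")
    deg = np.asarray(W.sum(axis=1)).ravel()
    Q = sp.diags_array(deg) - W
    return PrecisionMatrix(sp.csr_array(Q), scale=tau)


def extend_with_global(adjacency: STAdjacency) -> ExtendedAdjacency:
    return ExtendedAdjacency(adjacency)


def conditional_moments(
    adjacency: ExtendedAdjacency,
    phi: np.ndarray,
    tau: float,
    cell: tuple[int, int],
) -> tuple[float, float]:
    """Full-conditional mean and variance of one cell under the extended ICAR prior.

    ``phi`` has length KT + 1 with the global effect last.  The mean is the
    equally-weighted average of the cell's currently-linked neighbours
    (including the global effect when linked); the variance is 1/(tau * degree).
    """
    phi = np.asarray(phi, dtype=float)
    base = adjacency.base
    if phi.size != base.n_cells + 1:
        raise ValueError("phi must have length KT+1 (global effect last)")
    k, t = cell
    c = base.cell_index(k, t)
    total = 0.0
    deg = 0
    for e, (a, b) in enumerate(base.graph.edges):
        if k in (a, b) and base.spatial_state[t, e]:
            other = b if a == k else a
            total += phi[base.cell_index(other, t)]
            deg += 1
    if t > 0 and base.temporal_state[k, t - 1]:
        total += phi[base.cell_index(k, t - 1)]
        deg += 1
    if t < base.n_periods - 1 and base.temporal_state[k, t]:
        total += phi[base.cell_index(k, t + 1)]
        deg += 1
    if adjacency.w_star[c]:
        total += phi[-1]
        deg += 1
    if deg == 0:
        raise RuntimeError(
            f"cell {cell} has degree 0 — the extended adjacency invariant is violated"
        )
    return total / deg, 1.0 / (tau * deg)


def partial_correlation(
    adjacency: STAdjacency, cellA: tuple[int, int], cellB: tuple[int, int]
) -> float:
    """Partial autocorrelation between two cells under the ICAR prior on W.

    Equals ``w / sqrt(deg_A * deg_B)`` where w is the adjacency element linking
    the two cells (0 when unlinked) and the degrees count each cell's currently
    active spatial and temporal relations.
    """
    if cellA == cellB:
        raise ValueError("cells must be distinct")
    (k, t), (j, r) = cellA, cellB
    dA = adjacency.cell_degree(k, t)
    dB = adjacency.cell_degree(j, r)
    if dA == 0 or dB == 0:
        raise ValueError("partial correlation undefined for a degree-0 cell")
    w = 0
    if t == r:
        pair = (min(k, j), max(k, j))
        for e, edge in enumerate(adjacency.graph.edges):
            if edge == pair:
                w = int(adjacency.spatial_state[t, e])
                break
    elif k == j and abs(t - r) == 1:
        w = int(adjacency.temporal_state[k, min(t, r)])
    return w / np.sqrt(dA * dB)
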