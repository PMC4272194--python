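"""Residual autocorrelation and separability diagnostics.

Moran's I is the classical binary-weight statistic

    I = (K / S0) * sum_{k~i} (x_k - xbar)(x_i - xbar) / sum_k (x_k - xbar)^2

with S0 twice the edge count; under random permutation of the values over the
areas its expectation is -1/(K-1).  Significance is assessed by a two-sided
permutation test.  Space-time separability of a residual panel is probed by
correlating the yearly residual surfaces with each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stgraph import SpatialGraph

__all__ = [
    "MoranResult",
    "morans_i",
    "moran_permutation_test",
    "separability_correlations",
    "overdispersion",
]


@dataclass(frozen=True)
class MoranResult:
    statistic: float
    p_value: float
    n_permutations: int
    period: int | str = "pooled"

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")


def _cross_sum(values: np.ndarray, graph: SpatialGraph) -> float:
    a = np.array([e[0] for e in graph.edges])
    b = np.array([e[1] for e in graph.edges])
    return 2.0 * float(np.sum(values[a] * values[b]))


def morans_i(values: np.ndarray, graph: SpatialGraph) -> float:
    """Classical Moran's I with binary weights (no row standardisation)."""
    values = np.asarray(values, dtype=float)
    if values.size != graph.n_areas:
        raise ValueError("values length must equal the number of areas")
    if graph.n_areas < 2 or graph.n_edges < 1:
        raise ValueError("Moran's I needs at least 2 areas and 1 edge")
    centred = values - values.mean()
    denom = float(centred @ centred)
    if denom == 0.0:
        raise ValueError("Moran's I undefined for zero-variance input")
    s0 = 2.0 * graph.n_edges
    return (graph.n_areas / s0) * _cross_sum(centred, graph) / denom


def moran_permutation_test(
    values: np.ndarray,
    graph: SpatialGraph,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    period: int | str = "pooled",
) -> MoranResult:
    """Two-sided Moran's I permutation test; p = (1 + #{|I_perm| >= |I_obs|}) / (1 + n_perm)."""
    if n_perm < 1:
        raise ValueError("n_perm must be a positive integer")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = morans_i(values, graph)
    values = np.asarray(values, dtype=float)
    centred = values - values.mean()
    denom = float(centred @ centred)
    s0 = 2.0 * graph.n_edges
    scale = graph.n_areas / (s0 * denom)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(centred)
        stat = scale * _cross_sum(perm, graph)
        if abs(stat) >= abs(obs):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MoranResult(statistic=obs, p_value=p, n_permutations=n_perm, period=period)


def separability_correlations(residuals: np.ndarray) -> np.ndarray:
    """Pearson correlations between the yearly residual spatial surfaces.

    Returns a T x T matrix with unit diagonal; a zero-variance year yields NaN
    in its row and column.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2 or residuals.shape[1] < 2:
        raise ValueError("residuals must be K x T with T >= 2")
    T = residuals.shape[1]
    out = np.eye(T)
    sd = residuals.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(residuals.T)
    for i in range(T):
        for j in range(T):
            if i != j:
                out[i, j] = corr[i, j] if sd[i] > 0 and sd[j] > 0 else np.nan
    return out


def overdispersion(data, fitted: np.ndarray, p: int) -> float:
    """Pearson X^2 / (n - p) overdispersion estimate against fitted Poisson means."""
    fitted = np.asarray(fitted, dtype=float)
    Y = np.asarray(data.Y, dtype=float)
    if np.any(fitted <= 0):
        raise ValueError("fitted means must be positive")
    x2 = float(np.sum((Y - fitted) ** 2 / fitted))
    return x2 / (Y.size - p)
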