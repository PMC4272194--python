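"""Model family definitions: Poisson GLM, separable/non-separable BYM, localised variants.

All models share the first level ``Y_kt ~ Poisson(E_kt * R_kt)`` with
``ln R_kt = x_kt' beta + phi_kt``; they differ in how the random effect surface
``phi`` is decomposed and which Gaussian Markov random field priors it carries:

* ``glm`` — no random effects.
* ``bym_separable`` — a common spatial surface (ICAR + iid, precisions tau1,
  tau2) plus a common temporal trend (first-order random walk + iid, tau3,
  tau4).
* ``bym_nonseparable`` — a spatio-temporal ICAR component on the block matrix W
  (tau1) plus an iid component (tau2), so the spatial pattern may evolve.
* ``localised_nonseparable`` — a single random-effect vector with an extended
  ICAR prior on (phi, phi*) whose adjacency elements are estimable.
* ``localised_separable`` — spatial extended-LCAR on the shared spatial
  adjacency U plus the separable temporal terms (RW1 + iid).

Vague priors throughout: ``beta ~ N(0, 1000)`` (variance 1000) and every
precision ``tau ~ Gamma(shape=1, rate=0.0005)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import gammaln

from .stgraph import (
    ExtendedAdjacency,
    PrecisionMatrix,
    STAdjacency,
    SpatialGraph,
    build_st_adjacency,
    icar_precision,
)

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "STDataset",
    "log_likelihood",
    "log_prior_random_effects",
    "build_localised_separable_spec",
    "rw1_precision",
]

FAMILIES = (
    "glm",
    "bym_separable",
    "bym_nonseparable",
    "localised_separable",
    "localised_nonseparable",
)


def rw1_precision(T: int) -> PrecisionMatrix:
    """First-order random-walk precision: the ICAR Q of the path graph on T nodes."""
    path = SpatialGraph(T, tuple((t, t + 1) for t in range(T - 1)))
    return icar_precision(path)


@dataclass
class STDataset:
    """Areal counts over a K x T panel with expected counts and covariates.

    ``Y`` and ``E`` are K x T; ``X`` is K x T x p and includes an intercept
    column.  ``E`` enters the Poisson mean as an offset.
    """

    Y: np.ndarray
    E: np.ndarray
    X: np.ndarray
    covariate_names: tuple[str, ...] = ()
    area_labels: tuple[str, ...] | None = None
    time_labels: tuple[int, ...] | None = None

    def __post_init__(self):
        self.Y = np.asarray(self.Y)
        self.E = np.asarray(self.E, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.Y.ndim != 2 or self.E.shape != self.Y.shape:
            raise ValueError("Y and E must be K x T arrays of matching shape")
        if self.X.ndim != 3 or self.X.shape[:2] != self.Y.shape:
            raise ValueError("X must be K x T x p aligned with Y")
        if np.any(self.Y < 0) or not np.issubdtype(self.Y.dtype, np.integer):
            if not np.allclose(self.Y, np.round(self.Y)) or np.any(self.Y < 0):
                raise ValueError("Y must contain non-negative integer counts")
            self.Y = self.Y.astype(int)
        if np.any(self.E <= 0):
            raise ValueError("expected counts E must be strictly positive")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        if not self.covariate_names:
            self.covariate_names = tuple(f"x{j}" for j in range(self.X.shape[2]))

    @property
    def n_areas(self) -> int:
        return self.Y.shape[0]

    @property
    def n_periods(self) -> int:
        return self.Y.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[2]

    @property
    def n_obs(self) -> int:
        return self.Y.size

    def flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (y, e, x) flattened time-major: cell (k, t) at row t*K + k."""
        K, T, p = self.X.shape
        y = self.Y.T.ravel()
        e = self.E.T.ravel()
        x = self.X.transpose(1, 0, 2).reshape(K * T, p)
        return y, e, x


@dataclass
class ModelSpec:
    """A model family plus its priors and (where needed) adjacency structure."""

    family: str
    adjacency: STAdjacency | ExtendedAdjacency | None = None
    beta_prior_variance: float = 1000.0
    tau_prior: tuple[float, float] = (1.0, 0.0005)  # shape, rate
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.family == "glm":
            return
        if self.adjacency is None:
            raise ValueError(f"family {self.family!r} requires an adjacency")
        if self.family == "localised_nonseparable" and not isinstance(
            self.adjacency, ExtendedAdjacency
        ):
            if isinstance(self.adjacency, STAdjacency):
                self.adjacency = ExtendedAdjacency(self.adjacency)
            else:
                raise ValueError("localised_nonseparable requires an extended adjacency")

    @property
    def base_adjacency(self) -> STAdjacency | None:
        if isinstance(self.adjacency, ExtendedAdjacency):
            return self.adjacency.base
        return self.adjacency

    def component_names(self) -> tuple[str, ...]:
        return {
            "glm": (),
            "bym_separable": ("spatial_icar", "spatial_iid", "temporal_rw1", "temporal_iid"),
            "bym_nonseparable": ("st_icar", "st_iid"),
            "localised_nonseparable": ("phi_tilde",),
            "localised_separable": ("spatial_lcar", "temporal_rw1", "temporal_iid"),
        }[self.family]

    def to_yaml(self, graph_path: str | None = None) -> str:
        doc = {
            "family": self.family,
            "beta_prior_variance": float(self.beta_prior_variance),
            "tau_prior": {"shape": self.tau_prior[0], "rate": self.tau_prior[1]},
        }
        if graph_path is not None:
            doc["adjacency_file"] = graph_path
        if self.base_adjacency is not None:
            doc["n_periods"] = self.base_adjacency.n_periods
        doc.update({k: v for k, v in self.meta.items() if isinstance(v, (str, int, float, bool))})
        return yaml.safe_dump(doc, sort_keys=False)

    @staticmethod
    def from_yaml(text: str, graph: SpatialGraph | None = None) -> "ModelSpec":
        doc = yaml.safe_load(text)
        family = doc["family"]
        adjacency = None
        if family != "glm":
            if graph is None:
                raise ValueError("a SpatialGraph is required to rebuild this spec")
            adjacency = build_st_adjacency(graph, int(doc.get("n_periods", 1)))
        tp = doc.get("tau_prior", {"shape": 1.0, "rate": 0.0005})
        return ModelSpec(
            family=family,
            adjacency=adjacency,
            beta_prior_variance=float(doc.get("beta_prior_variance", 1000.0)),
            tau_prior=(float(tp["shape"]), float(tp["rate"])),
        )


def log_likelihood(data: STDataset, beta: np.ndarray, phi=0.0) -> float:
    """Poisson log-likelihood with mean ``E * exp(X beta + phi)`` summed over cells."""
    y, e, x = data.flat()
    beta = np.asarray(beta, dtype=float)
    if beta.size != data.n_covariates:
        raise ValueError("beta length does not match the covariate dimension")
    eta = x @ beta + np.log(e) + np.asarray(phi, dtype=float).ravel()
    bad = ~np.isfinite(eta)
    if bad.any():
        c = int(np.flatnonzero(bad)[0])
        K = data.n_areas
        raise ValueError(f"non-finite linear predictor at cell (area {c % K}, period {c // K})")
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


def _icar_term(tau: float, phi: np.ndarray, prec: PrecisionMatrix) -> float:
    r = prec.rank()
    q = prec.quadratic_form(phi)
    return 0.5 * r * math.log(tau) - 0.5 * tau * q


def _iid_term(tau: float, phi: np.ndarray) -> float:
    n = phi.size
    return 0.5 * n * math.log(tau) - 0.5 * tau * float(phi @ phi)


def log_prior_random_effects(spec: ModelSpec, components: dict, taus: dict) -> float:
    """Joint GMRF log-density of all random-effect components, up to constants.

    ICAR-type terms use the pseudo-normalising constant ``(rank(Q)/2) ln tau``;
    the temporal random walk is the ICAR of the path graph; iid terms are
    proper Gaussians.
    """
    names = spec.component_names()
    if set(components) != set(names) or set(taus) != set(names):
        raise ValueError(f"components/taus must be exactly {names}")
    total = 0.0
    if spec.family == "bym_separable":
        g = spec.base_adjacency.graph
        T = spec.base_adjacency.n_periods
        total += _icar_term(taus["spatial_icar"], components["spatial_icar"], icar_precision(g))
        total += _iid_term(taus["spatial_iid"], components["spatial_iid"])
        total += _icar_term(taus["temporal_rw1"], components["temporal_rw1"], rw1_precision(T))
        total += _iid_term(taus["temporal_iid"], components["temporal_iid"])
    elif spec.family == "bym_nonseparable":
        total += _icar_term(
            taus["st_icar"], components["st_icar"], icar_precision(spec.base_adjacency)
        )
        total += _iid_term(taus["st_iid"], components["st_iid"])
    elif spec.family == "localised_nonseparable":
        total += _icar_term(
            taus["phi_tilde"], components["phi_tilde"], icar_precision(spec.adjacency)
        )
    elif spec.family == "localised_separable":
        ext = spec.meta["spatial_extended"]
        total += _icar_term(
            taus["spatial_lcar"], components["spatial_lcar"], icar_precision(ext)
        )
        T = spec.base_adjacency.n_periods
        total += _icar_term(taus["temporal_rw1"], components["temporal_rw1"], rw1_precision(T))
        total += _iid_term(taus["temporal_iid"], components["temporal_iid"])
    return total


def build_localised_separable_spec(graph: SpatialGraph, T: int) -> ModelSpec:
    """Localised separable model: extended-LCAR spatial surface + RW1 + iid trend.

    The estimable elements live in a single spatial adjacency U shared across
    periods; a global spatial effect is appended so cells stay proper when
    relations are switched off.  The temporal part keeps the separable
    random-walk-plus-noise trend.
    """
    adjacency = build_st_adjacency(graph, T)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        spatial = build_st_adjacency(graph, 1)  # single-period carrier of U's state
    ext = ExtendedAdjacency(spatial)
    return ModelSpec(
        family="localised_separable",
        adjacency=adjacency,
        meta={"spatial_extended": ext},
    )
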