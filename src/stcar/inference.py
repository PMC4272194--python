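"""Posterior computation for all model families, plus DIC, CPO and residuals.

The Bayesian backend is a blocked Metropolis-within-Gibbs sampler:

* each precision parameter has a conjugate Gamma full conditional given its
  component's quadratic form;
* random-effect vectors are updated with chromatic single-site Metropolis —
  the component's conditional-independence graph is coloured once, and every
  cell in a colour class is proposed and accepted simultaneously (valid because
  same-colour cells are conditionally independent given the rest);
* the global effect of an extended (LCAR-style) component has a Gaussian full
  conditional and is Gibbs-updated exactly (it never enters the likelihood);
* the regression coefficients use a joint random-walk proposal preconditioned
  by the quasi-Poisson GLM covariance, with Robbins-Monro scale adaptation
  during burn-in.

Identifiability: every intrinsic component is recentred each sweep and the
removed level absorbed into the intercept, the standard resolution of the
ICAR-intercept confounding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .models import ModelSpec, STDataset, rw1_precision
from .stgraph import ExtendedAdjacency

__all__ = [
    "SamplerControl",
    "Samples",
    "PosteriorSummary",
    "FitResult",
    "fit_glm",
    "fit_bayes",
    "dic",
    "cpo",
    "residuals",
    "tau_full_conditional",
]


@dataclass
class SamplerControl:
    """MCMC run settings; ``fast()`` is the profile for iterative inner fits."""

    n_chains: int = 3
    n_iter: int = 20000
    n_burn: int = 10000
    thin: int = 10
    seed: int = 0

    @classmethod
    def fast(cls, seed: int = 0) -> "SamplerControl":
        return cls(n_chains=1, n_iter=5000, n_burn=2500, thin=5, seed=seed)

    @property
    def n_keep(self) -> int:
        return self.n_chains * ((self.n_iter - self.n_burn) // self.thin)


@dataclass
class Samples:
    """Retained posterior draws (chains pooled; chain id kept for diagnostics)."""

    beta: np.ndarray                      # (S, p)
    taus: dict[str, np.ndarray]           # name -> (S,)
    phi_eff: np.ndarray                   # (S, KT) random-effect sum per cell
    components: dict[str, np.ndarray]     # name -> (S, size)
    chain_id: np.ndarray                  # (S,)

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]


@dataclass
class PosteriorSummary:
    """Marginal posterior summaries for beta, taus and every random-effect cell."""

    table: pd.DataFrame                   # rows: beta_*, tau_*; cols mean, sd, q2.5, q97.5, ess, rhat
    components: dict[str, dict[str, np.ndarray]]  # name -> {mean, sd, lo, hi}
    phi_eff_mean: np.ndarray | None = None

    def intervals(self, component: str) -> tuple[np.ndarray, np.ndarray]:
        c = self.components[component]
        return c["lo"], c["hi"]


@dataclass
class FitResult:
    spec: ModelSpec
    posterior: PosteriorSummary
    dic: float
    pD: float
    cpo: np.ndarray | None
    residuals: np.ndarray
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    samples: Samples | None = None

    @property
    def mean_cpo(self) -> float:
        return float(np.mean(self.cpo)) if self.cpo is not None else float("nan")

    def beta_summary(self) -> pd.DataFrame:
        return self.table_rows("beta_")

    def table_rows(self, prefix: str) -> pd.DataFrame:
        t = self.posterior.table
        return t[t.index.str.startswith(prefix)]

    def save(self, outdir) -> None:
        """Write posterior_summary.csv, cpo.csv, residuals.csv and metrics.json."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.posterior.table.to_csv(out / "posterior_summary.csv")
        if self.cpo is not None:
            pd.DataFrame({"cpo": self.cpo}).to_csv(out / "cpo.csv", index=False)
        pd.DataFrame(self.residuals).to_csv(out / "residuals.csv", index=False)
        metrics = {
            "dic": None if not np.isfinite(self.dic) else float(self.dic),
            "pD": None if not np.isfinite(self.pD) else float(self.pD),
            "mean_cpo": None if not np.isfinite(self.mean_cpo) else float(self.mean_cpo),
            "converged": bool(self.converged),
            **{k: v for k, v in self.diagnostics.items() if isinstance(v, (int, float, str, bool))},
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        (out / "config.yaml").write_text(self.spec.to_yaml())


# --------------------------------------------------------------------------
# quasi-Poisson GLM baseline
# --------------------------------------------------------------------------

def fit_glm(data: STDataset) -> FitResult:
    """Overdispersed (quasi-likelihood) Poisson GLM with offset ln E.

    Dispersion is estimated as Pearson X^2 / (n - p) and Wald 95% intervals
    are scaled by its square root.  Residuals are raw (Y - fitted mean).
    """
    import statsmodels.api as sm

    y, e, x = data.flat()
    model = sm.GLM(y, x, family=sm.families.Poisson(), offset=np.log(e))
    try:
        res = model.fit()
    except Exception as err:  # pragma: no cover - separation is data-dependent
        raise RuntimeError(f"GLM failed to converge: {err}") from err
    if not res.converged:
        raise RuntimeError(f"GLM failed to converge after {res.fit_history['iteration']} iterations")
    mu = res.fittedvalues
    p = x.shape[1]
    dispersion = float(np.sum((y - mu) ** 2 / mu) / (y.size - p))
    se = res.bse * math.sqrt(max(dispersion, np.finfo(float).tiny))
    z = norm.ppf(0.975)
    names = [f"beta_{n}" for n in data.covariate_names]
    table = pd.DataFrame(
        {
            "mean": res.params,
            "sd": se,
            "q2.5": res.params - z * se,
            "q97.5": res.params + z * se,
            "ess": np.nan,
            "rhat": np.nan,
        },
        index=names,
    )
    K, T = data.n_areas, data.n_periods
    resid = (y - mu).reshape(T, K).T
    posterior = PosteriorSummary(table=table, components={}, phi_eff_mean=None)
    return FitResult(
        spec=ModelSpec(family="glm"),
        posterior=posterior,
        dic=float("nan"),
        pD=float("nan"),
        cpo=None,
        residuals=resid,
        converged=True,
        diagnostics={"dispersion": dispersion, "backend": "quasi-glm"},
    )


# --------------------------------------------------------------------------
# sampler machinery
# --------------------------------------------------------------------------

@dataclass
class _Component:
    name: str
    size: int
    mapping: str            # identity | spatial | temporal
    kind: str               # icar | iid | extended
    A: sp.csr_array | None  # neighbour matrix (includes global links if extended)
    degrees: np.ndarray | None
    colors: list[np.ndarray]
    rank: int
    centre: bool
    has_global: bool


def _color_classes(A: sp.csr_array, n_color_nodes: int) -> list[np.ndarray]:
    """Greedy colouring of the conditional-dependence graph on the first nodes."""
    sub = A[:n_color_nodes, :n_color_nodes]
    G = nx.from_scipy_sparse_array(sp.csr_matrix(sub))
    coloring = nx.coloring.greedy_color(G, strategy="largest_first")
    ncol = max(coloring.values()) + 1 if coloring else 1
    classes = [[] for _ in range(ncol)]
    for node in range(n_color_nodes):
        classes[coloring.get(node, 0)].append(node)
    return [np.asarray(c, dtype=int) for c in classes if len(c)]


def _make_gmrf_component(name, mapping, A, size, has_global, centre=True) -> _Component:
    deg = np.asarray(A.sum(axis=1)).ravel()
    ncomp = sp.csgraph.connected_components(A, directed=False)[0]
    colors = _color_classes(A, size - 1 if has_global else size)
    return _Component(
        name=name,
        size=size,
        mapping=mapping,
        kind="extended" if has_global else "icar",
        A=sp.csr_array(A),
        degrees=deg,
        colors=colors,
        rank=size - ncomp,
        centre=centre,
        has_global=has_global,
    )


def _make_iid_component(name, mapping, size) -> _Component:
    return _Component(
        name=name,
        size=size,
        mapping=mapping,
        kind="iid",
        A=None,
        degrees=None,
        colors=[np.arange(size)],
        rank=size,
        centre=False,
        has_global=False,
    )


def _build_components(spec: ModelSpec, K: int, T: int) -> list[_Component]:
    fam = spec.family
    if fam == "glm":
        return []
    if fam == "bym_separable":
        U = spec.base_adjacency.graph.adjacency_matrix()
        P = rw1_precision(T)
        path = sp.csr_array(sp.diags_array(np.asarray(P.Q.diagonal())) - P.Q)
        return [
            _make_gmrf_component("spatial_icar", "spatial", U, K, has_global=False),
            _make_iid_component("spatial_iid", "spatial", K),
            _make_gmrf_component("temporal_rw1", "temporal", path, T, has_global=False),
            _make_iid_component("temporal_iid", "temporal", T),
        ]
    if fam == "bym_nonseparable":
        W = spec.base_adjacency.matrix()
        return [
            _make_gmrf_component("st_icar", "identity", W, K * T, has_global=False),
            _make_iid_component("st_iid", "identity", K * T),
        ]
    if fam == "localised_nonseparable":
        Wt = spec.adjacency.matrix()
        return [
            _make_gmrf_component("phi_tilde", "identity", Wt, K * T + 1, has_global=True)
        ]
    if fam == "localised_separable":
        ext: ExtendedAdjacency = spec.meta["spatial_extended"]
        Ut = ext.matrix()
        P = rw1_precision(T)
        path = sp.csr_array(sp.diags_array(np.asarray(P.Q.diagonal())) - P.Q)
        return [
            _make_gmrf_component("spatial_lcar", "spatial", Ut, K + 1, has_global=True),
            _make_gmrf_component("temporal_rw1", "temporal", path, T, has_global=False),
            _make_iid_component("temporal_iid", "temporal", T),
        ]
    raise ValueError(fam)


def tau_full_conditional(
    prior: tuple[float, float], rank: int, quad_form: float
) -> tuple[float, float]:
    """Shape and rate of the conjugate Gamma full conditional for a precision."""
    a, b = prior
    return a + 0.5 * rank, b + 0.5 * quad_form


def _pack_components(comps):
    """Flatten the component list into the arrays the sweep kernel consumes."""
    nc = len(comps)
    comp_kind = np.zeros(nc, dtype=np.int8)
    comp_map = np.zeros(nc, dtype=np.int8)
    comp_size = np.zeros(nc, dtype=np.int64)
    comp_has_global = np.zeros(nc, dtype=np.int8)
    comp_centre = np.zeros(nc, dtype=np.int8)
    comp_u_off = np.zeros(nc + 1, dtype=np.int64)
    comp_n_colors = np.zeros(nc, dtype=np.int64)
    comp_color_off = np.zeros(nc, dtype=np.int64)
    ap_parts, ai_parts, deg_parts = [], [], []
    comp_ap_off = np.zeros(nc, dtype=np.int64)
    comp_ai_off = np.zeros(nc, dtype=np.int64)
    nodes_parts = []
    bounds = [0]
    map_code = {"identity": 0, "spatial": 1, "temporal": 2}
    ap_c = ai_c = col_c = 0
    for ci, c in enumerate(comps):
        comp_kind[ci] = 0 if c.kind == "iid" else 1
        comp_map[ci] = map_code[c.mapping]
        comp_size[ci] = c.size
        comp_has_global[ci] = 1 if c.has_global else 0
        comp_centre[ci] = 1 if c.centre else 0
        comp_u_off[ci + 1] = comp_u_off[ci] + c.size
        comp_ap_off[ci] = ap_c
        comp_ai_off[ci] = ai_c
        if c.A is not None:
            csr = sp.csr_array(c.A)
            ap_parts.append(csr.indptr.astype(np.int64))
            ai_parts.append(csr.indices.astype(np.int64))
            deg_parts.append(np.asarray(c.degrees, dtype=float))
            ap_c += c.size + 1
            ai_c += csr.indices.size
        else:
            ap_parts.append(np.zeros(c.size + 1, dtype=np.int64))
            deg_parts.append(np.zeros(c.size))
            ap_c += c.size + 1
        comp_color_off[ci] = col_c
        comp_n_colors[ci] = len(c.colors)
        for C in c.colors:
            nodes_parts.append(np.asarray(C, dtype=np.int64))
            bounds.append(bounds[-1] + C.size)
        col_c += len(c.colors)
    ap_all = np.concatenate(ap_parts) if ap_parts else np.zeros(1, dtype=np.int64)
    ai_all = (
        np.concatenate(ai_parts) if ai_parts else np.zeros(0, dtype=np.int64)
    )
    deg_all = np.concatenate(deg_parts) if deg_parts else np.zeros(0)
    color_nodes = (
        np.concatenate(nodes_parts) if nodes_parts else np.zeros(0, dtype=np.int64)
    )
    color_bounds = np.asarray(bounds, dtype=np.int64)
    return dict(
        comp_kind=comp_kind,
        comp_map=comp_map,
        comp_size=comp_size,
        comp_has_global=comp_has_global,
        comp_centre=comp_centre,
        comp_u_off=comp_u_off,
        ap_all=ap_all,
        comp_ap_off=comp_ap_off,
        ai_all=ai_all,
        comp_ai_off=comp_ai_off,
        deg_all=deg_all,
        color_nodes=color_nodes,
        color_bounds=color_bounds,
        comp_color_off=comp_color_off,
        comp_n_colors=comp_n_colors,
    )


def _build_ridges(comps, x, K, T, p, intercept_col):
    """Translation-move directions: which components absorb each covariate."""

    def qvec(comp, v):
        return comp.degrees * v - comp.A @ v

    ident = next(
        (i for i, c in enumerate(comps) if c.mapping == "identity" and c.kind != "iid"),
        None,
    )
    spat = next(
        (i for i, c in enumerate(comps) if c.mapping == "spatial" and c.kind != "iid"),
        None,
    )
    temp = next(
        (i for i, c in enumerate(comps) if c.mapping == "temporal" and c.kind != "iid"),
        None,
    )
    ridges = []
    if comps and intercept_col is not None:
        for j in range(p):
            if j == intercept_col:
                continue
            xj = x[:, j]
            if ident is not None:
                c = comps[ident]
                proj = np.zeros(c.size)
                proj[: K * T] = xj
                ridges.append(
                    {"j": j, "m": 0.0, "terms": [(ident, proj, qvec(c, proj))], "resid": None}
                )
            elif spat is not None or temp is not None:
                xM = xj.reshape(T, K)
                m = float(xM.mean())
                a = xM.mean(axis=0) - m
                b = xM.mean(axis=1) - m
                resid = xj - (m + np.tile(a, T) + np.repeat(b, K))
                terms = []
                if spat is not None:
                    c = comps[spat]
                    pa = np.zeros(c.size)
                    pa[:K] = a
                    terms.append((spat, pa, qvec(c, pa)))
                if temp is not None:
                    c = comps[temp]
                    pb = np.zeros(c.size)
                    pb[:T] = b
                    terms.append((temp, pb, qvec(c, pb)))
                ridges.append(
                    {
                        "j": j,
                        "m": m,
                        "terms": terms,
                        "resid": resid if np.abs(resid).max() > 1e-12 else None,
                    }
                )
    return ridges


def _pack_ridges(ridges, comps, n):
    nr = len(ridges)
    ridge_j = np.zeros(nr, dtype=np.int64)
    ridge_m = np.zeros(nr)
    rt_off = np.zeros(nr + 1, dtype=np.int64)
    rt_comp_l, proj_parts, qproj_parts, pqp_l, proj_offs = [], [], [], [], []
    ridge_has_resid = np.zeros(nr, dtype=np.int8)
    resid_all = np.zeros((max(nr, 1), n))
    off = 0
    for r, rd in enumerate(ridges):
        ridge_j[r] = rd["j"]
        ridge_m[r] = rd["m"]
        rt_off[r + 1] = rt_off[r] + len(rd["terms"])
        for ci, proj, qproj in rd["terms"]:
            rt_comp_l.append(ci)
            proj_parts.append(proj)
            qproj_parts.append(qproj)
            pqp_l.append(float(proj @ qproj))
            proj_offs.append(off)
            off += proj.size
        if rd["resid"] is not None:
            ridge_has_resid[r] = 1
            resid_all[r] = rd["resid"]
    return dict(
        ridge_j=ridge_j,
        ridge_m=ridge_m,
        rt_off=rt_off,
        rt_comp=np.asarray(rt_comp_l, dtype=np.int64),
        proj_all=np.concatenate(proj_parts) if proj_parts else np.zeros(0),
        rt_proj_off=np.asarray(proj_offs, dtype=np.int64),
        qproj_all=np.concatenate(qproj_parts) if qproj_parts else np.zeros(0),
        rt_pqp=np.asarray(pqp_l),
        ridge_has_resid=ridge_has_resid,
        resid_all=resid_all,
    )


def _phi_contrib_packed(comps, pk, u_all, K, T):
    phi = np.zeros(K * T)
    for ci, c in enumerate(comps):
        seg = u_all[pk["comp_u_off"][ci] : pk["comp_u_off"][ci + 1]]
        if c.mapping == "identity":
            phi += seg[: K * T]
        elif c.mapping == "spatial":
            phi += np.tile(seg[:K], T)
        else:
            phi += np.repeat(seg[:T], K)
    return phi


def _run_chain(spec, data, control, comps, rng, init, beta_prec_chol, engine="auto"):
    from ._kernel import sweep, sweep_py

    kernel = sweep_py if engine == "python" else sweep
    y, e, x = data.flat()
    y = y.astype(float)
    K, T, p = data.n_areas, data.n_periods, data.n_covariates
    log_e = np.log(e)
    intercept_col = None
    for j in range(p):
        if np.allclose(x[:, j], 1.0):
            intercept_col = j
            break
    if intercept_col is None and comps:
        warnings.warn("no intercept column found; intrinsic components left uncentred")

    beta = np.zeros(p)
    u_all = np.zeros(int(sum(c.size for c in comps)))
    taus = np.ones(len(comps))
    pk = _pack_components(comps)
    if init:
        if "beta" in init:
            beta = np.asarray(init["beta"], dtype=float).copy()
        for name, vec in init.get("components", {}).items():
            for ci, c in enumerate(comps):
                if c.name == name and np.size(vec) == c.size:
                    u_all[pk["comp_u_off"][ci] : pk["comp_u_off"][ci + 1]] = np.asarray(
                        vec, dtype=float
                    )
        for name, t in init.get("taus", {}).items():
            for ci, c in enumerate(comps):
                if c.name == name:
                    taus[ci] = float(t)

    ridges = _build_ridges(comps, x, K, T, p, intercept_col)
    rk = _pack_ridges(ridges, comps, K * T)

    def full_eta():
        return log_e + x @ beta + _phi_contrib_packed(comps, pk, u_all, K, T)

    eta = full_eta()
    a0, b0 = spec.tau_prior
    beta_var = float(spec.beta_prior_variance)
    log_scale_beta = np.array([math.log(0.5)])
    log_scales = np.full(len(comps), math.log(0.1))
    ridge_log_scales = np.full(len(ridges), math.log(0.05))
    quads = np.zeros(len(comps))
    acc_out = np.zeros(1)
    icol = -1 if intercept_col is None else intercept_col

    colorable = int(sum(c.size - (1 if c.has_global else 0) for c in comps))
    n_globals = int(sum(1 for c in comps if c.has_global))
    NZ = p + len(ridges) + colorable + n_globals
    NU = 1 + len(ridges) + colorable
    CHUNK = 512

    n_keep = (control.n_iter - control.n_burn) // control.thin
    keep_beta = np.empty((n_keep, p))
    keep_tau = {c.name: np.empty(n_keep) for c in comps}
    keep_phi = np.empty((n_keep, K * T))
    keep_u = {c.name: np.empty((n_keep, c.size)) for c in comps}
    kept = 0
    acc_beta = 0.0
    ranks = np.array([c.rank for c in comps], dtype=float)

    Z_chunk = U_chunk = None
    for it in range(control.n_iter):
        s = it % CHUNK
        if s == 0:
            Z_chunk = rng.standard_normal((CHUNK, NZ))
            U_chunk = rng.random((CHUNK, NU))
        kernel(
            it,
            control.n_burn,
            y,
            x,
            eta,
            K,
            T,
            icol,
            beta,
            u_all,
            taus,
            pk["comp_kind"],
            pk["comp_map"],
            pk["comp_size"],
            pk["comp_has_global"],
            pk["comp_centre"],
            pk["comp_u_off"],
            pk["ap_all"],
            pk["comp_ap_off"],
            pk["ai_all"],
            pk["comp_ai_off"],
            pk["deg_all"],
            pk["color_nodes"],
            pk["color_bounds"],
            pk["comp_color_off"],
            pk["comp_n_colors"],
            rk["ridge_j"],
            rk["ridge_m"],
            rk["rt_off"],
            rk["rt_comp"],
            rk["proj_all"],
            rk["rt_proj_off"],
            rk["qproj_all"],
            rk["rt_pqp"],
            rk["ridge_has_resid"],
            rk["resid_all"],
            log_scale_beta,
            log_scales,
            ridge_log_scales,
            beta_prec_chol,
            beta_var,
            Z_chunk[s],
            U_chunk[s],
            quads,
            acc_out,
        )
        acc_beta += acc_out[0]
        for ci in range(len(comps)):
            shape, rate = tau_full_conditional((a0, b0), ranks[ci], quads[ci])
            taus[ci] = rng.gamma(shape, 1.0 / rate)
        if (it + 1) % 200 == 0:
            eta = full_eta()  # guard against incremental drift
        if it >= control.n_burn and (it - control.n_burn) % control.thin == 0 and kept < n_keep:
            keep_beta[kept] = beta
            for ci, c in enumerate(comps):
                keep_tau[c.name][kept] = taus[ci]
                keep_u[c.name][kept] = u_all[
                    pk["comp_u_off"][ci] : pk["comp_u_off"][ci + 1]
                ]
            keep_phi[kept] = _phi_contrib_packed(comps, pk, u_all, K, T)
            kept += 1

    return keep_beta[:kept], {k: v[:kept] for k, v in keep_tau.items()}, keep_phi[:kept], {
        k: v[:kept] for k, v in keep_u.items()
    }, acc_beta / control.n_iter


def _split_rhat(chains: list[np.ndarray]) -> float:
    """Split-R-hat for a scalar parameter from per-chain sample vectors."""
    halves = []
    for c in chains:
        h = len(c) // 2
        if h >= 2:
            halves += [c[:h], c[h : 2 * h]]
    if len(halves) < 2:
        return float("nan")
    n = min(len(h) for h in halves)
    arr = np.stack([h[:n] for h in halves])
    W = arr.var(axis=1, ddof=1).mean()
    B = n * arr.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    return float(math.sqrt((n - 1) / n + B / (n * W)))


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence autocorrelation sum."""
    n = x.size
    if n < 10 or x.var() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (xc @ xc)
    s = 0.0
    for k in range(1, min(n // 2, 200)):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def glm_preconditioner(data: STDataset) -> tuple[np.ndarray, np.ndarray]:
    """Cholesky of a diagonal proposal covariance for beta, plus starting values,
    from the quasi-Poisson GLM; reusable across repeated fits of one dataset."""
    p = data.n_covariates
    try:
        glm = fit_glm(data)
        sds = glm.posterior.table["sd"].to_numpy()
        cov = np.diag(np.maximum(sds, 1e-6) ** 2)
        return np.linalg.cholesky(cov), glm.posterior.table["mean"].to_numpy()
    except Exception:
        return 0.05 * np.eye(p), np.zeros(p)


def fit_bayes(
    spec: ModelSpec,
    data: STDataset,
    control: SamplerControl | None = None,
    init: dict | None = None,
    keep_samples: bool = False,
    precond: tuple[np.ndarray, np.ndarray] | None = None,
    engine: str = "auto",
) -> FitResult:
    """MCMC fit of any model family; satisfies the marginal-interval contract.

    Returns marginal 95% intervals for every random-effect cell, summaries for
    beta and each tau, DIC/pD, the CPO vector and raw residuals.  Runs are
    reproducible given ``control.seed``.
    """
    if control is None:
        control = SamplerControl()
    K, T, p = data.n_areas, data.n_periods, data.n_covariates
    comps = _build_components(spec, K, T)
    y, e, x = data.flat()

    # preconditioner for the beta proposal from the quasi-GLM covariance
    if precond is None:
        precond = glm_preconditioner(data)
    beta_prec_chol, beta_init = precond
    if init is None:
        init = {}
    init.setdefault("beta", beta_init)

    ss = np.random.SeedSequence(control.seed)
    child = ss.spawn(control.n_chains)
    per_chain = []
    acc_rates = []
    for ci in range(control.n_chains):
        rng = np.random.default_rng(child[ci])
        out = _run_chain(spec, data, control, comps, rng, init, beta_prec_chol, engine=engine)
        per_chain.append(out[:4])
        acc_rates.append(out[4])

    beta_s = np.concatenate([pc[0] for pc in per_chain])
    tau_s = {
        c.name: np.concatenate([pc[1][c.name] for pc in per_chain]) for c in comps
    }
    phi_s = np.concatenate([pc[2] for pc in per_chain])
    u_s = {c.name: np.concatenate([pc[3][c.name] for pc in per_chain]) for c in comps}
    chain_id = np.concatenate(
        [np.full(len(pc[0]), i) for i, pc in enumerate(per_chain)]
    )
    samples = Samples(beta=beta_s, taus=tau_s, phi_eff=phi_s, components=u_s, chain_id=chain_id)

    # ---- summaries -------------------------------------------------------
    rows, idx = [], []
    rhat_bad = False
    for j, name in enumerate(data.covariate_names):
        col = beta_s[:, j]
        chains = [pc[0][:, j] for pc in per_chain]
        rh = _split_rhat(chains) if control.n_chains > 1 else float("nan")
        if control.n_chains > 1 and np.isfinite(rh) and rh > 1.1:
            rhat_bad = True
        rows.append(
            [col.mean(), col.std(ddof=1), *np.quantile(col, [0.025, 0.975]), _ess(col), rh]
        )
        idx.append(f"beta_{name}")
    for c in comps:
        col = tau_s[c.name]
        chains = [pc[1][c.name] for pc in per_chain]
        rh = _split_rhat(chains) if control.n_chains > 1 else float("nan")
        if control.n_chains > 1 and np.isfinite(rh) and rh > 1.1:
            rhat_bad = True
        rows.append(
            [col.mean(), col.std(ddof=1), *np.quantile(col, [0.025, 0.975]), _ess(col), rh]
        )
        idx.append(f"tau_{c.name}")
    table = pd.DataFrame(
        rows, index=idx, columns=["mean", "sd", "q2.5", "q97.5", "ess", "rhat"]
    )
    comp_summ = {}
    for c in comps:
        us = u_s[c.name]
        lo, hi = np.quantile(us, [0.025, 0.975], axis=0)
        comp_summ[c.name] = {
            "mean": us.mean(axis=0),
            "sd": us.std(axis=0, ddof=1),
            "lo": lo,
            "hi": hi,
        }
    posterior = PosteriorSummary(
        table=table, components=comp_summ, phi_eff_mean=phi_s.mean(axis=0)
    )

    dic_val, pd_val = dic(samples, data)
    cpo_vec = cpo(samples, data)
    eta_bar = np.log(e) + x @ beta_s.mean(axis=0) + phi_s.mean(axis=0)
    resid = (y - e * np.exp(eta_bar - np.log(e))).reshape(T, K).T
    return FitResult(
        spec=spec,
        posterior=posterior,
        dic=dic_val,
        pD=pd_val,
        cpo=cpo_vec,
        residuals=resid,
        converged=not rhat_bad,
        diagnostics={
            "backend": "metropolis-within-gibbs",
            "accept_beta": float(np.mean(acc_rates)),
            "n_samples": samples.n_samples,
        },
        samples=samples if keep_samples else None,
    )


def _eta_samples(samples: Samples, data: STDataset) -> np.ndarray:
    y, e, x = data.flat()
    return np.log(e)[None, :] + samples.beta @ x.T + samples.phi_eff


def dic(samples: Samples, data: STDataset) -> tuple[float, float]:
    """Deviance information criterion: DIC = Dbar + pD, pD = Dbar - D(theta_bar)."""
    if samples.n_samples < 100:
        warnings.warn(f"DIC computed from only {samples.n_samples} retained samples")
    y, e, x = data.flat()
    eta_s = _eta_samples(samples, data)
    ll = y[None, :] * eta_s - np.exp(eta_s) - gammaln(y + 1.0)[None, :]
    dev = -2.0 * ll.sum(axis=1)
    dbar = float(dev.mean())
    eta_bar = np.log(e) + x @ samples.beta.mean(axis=0) + samples.phi_eff.mean(axis=0)
    ll_bar = float(np.sum(y * eta_bar - np.exp(eta_bar) - gammaln(y + 1.0)))
    d_hat = -2.0 * ll_bar
    pD = dbar - d_hat
    return dbar + pD, pD


def cpo(samples: Samples, data: STDataset) -> np.ndarray:
    """Harmonic-mean estimator of the conditional predictive ordinate per cell.

    ``CPO_kt = [S^-1 sum_s 1/f(Y_kt | theta_s)]^-1``, evaluated in log space
    with a log-sum-exp guard.
    """
    y, e, _ = data.flat()
    eta_s = _eta_samples(samples, data)
    ll = y[None, :] * eta_s - np.exp(eta_s) - gammaln(y + 1.0)[None, :]
    S = ll.shape[0]
    log_cpo = -(logsumexp(-ll, axis=0) - math.log(S))
    return np.exp(log_cpo)


def residuals(fit: FitResult, data: STDataset) -> np.ndarray:
    """Raw residuals Y - E*exp(x'beta_hat + phi_hat) with posterior-mean plug-ins."""
    y, e, x = data.flat()
    beta_hat = fit.posterior.table.loc[
        [f"beta_{n}" for n in data.covariate_names], "mean"
    ].to_numpy()
    phi_hat = fit.posterior.phi_eff_mean
    eta = x @ beta_hat + (phi_hat if phi_hat is not None else 0.0)
    K, T = data.n_areas, data.n_periods
    return (y - e * np.exp(eta)).reshape(T, K).T
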