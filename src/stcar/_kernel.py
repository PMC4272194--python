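"""One full MCMC sweep over (beta, random effects) as a single compiled kernel.

The kernel mutates the chain state in place and consumes pre-generated
standard-normal and uniform draws laid out in a fixed per-sweep order, so the
compiled path and the pure-Python twin (used when numba is unavailable, and in
parity tests) produce bit-identical trajectories.  Precision parameters are
conjugate and drawn outside the kernel from the quadratic forms it returns.

Within a colour class the cells are conditionally independent given the rest
(that is what the colouring guarantees), so the sequential scan inside a class
is equivalent to the block update.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sweep", "sweep_py"]


def _sweep_impl(
    it,
    n_burn,
    # data
    y,
    x,
    eta,
    K,
    T,
    intercept_col,
    # state
    beta,
    u_all,
    taus,
    # packed components
    comp_kind,      # 0 iid, 1 gmrf (icar/extended)
    comp_map,       # 0 identity, 1 spatial, 2 temporal
    comp_size,
    comp_has_global,
    comp_centre,
    comp_u_off,
    ap_all,         # concatenated CSR indptr
    comp_ap_off,
    ai_all,         # concatenated CSR indices (component-local)
    comp_ai_off,
    deg_all,
    color_nodes,    # concatenated node lists, grouped by colour
    color_bounds,   # start offsets of each colour class
    comp_color_off, # per-component first colour index
    comp_n_colors,
    # ridge moves
    ridge_j,
    ridge_m,
    rt_off,
    rt_comp,
    proj_all,
    rt_proj_off,
    qproj_all,
    rt_pqp,         # proj' Q proj per term
    ridge_has_resid,
    resid_all,      # (n_ridge, n) residual directions (zeros when unused)
    # adaptive scales (length-1 / per-comp / per-ridge arrays, mutated)
    log_scale_beta,
    log_scales,
    ridge_log_scales,
    beta_chol,
    beta_var,
    # randoms for this sweep
    Z,
    U,
    # outputs
    quads,
    acc_out,
):
    p = beta.shape[0]
    n = y.shape[0]
    zi = 0
    ui = 0
    adapt = 1.0 / np.sqrt(1.0 + it / 10.0) if it < n_burn else 0.0

    # ---- beta: joint preconditioned random walk --------------------------
    step = np.exp(log_scale_beta[0])
    dlik = 0.0
    prop = np.empty(p)
    for i in range(p):
        s = 0.0
        for j in range(i + 1):
            s += beta_chol[i, j] * Z[zi + j]
        prop[i] = step * s
    zi += p
    dprior = 0.0
    for i in range(p):
        b_new = beta[i] + prop[i]
        dprior -= 0.5 * (b_new * b_new - beta[i] * beta[i]) / beta_var
    for c in range(n):
        de = 0.0
        for i in range(p):
            de += x[c, i] * prop[i]
        en = eta[c] + de
        dlik += y[c] * de - (np.exp(en) - np.exp(eta[c]))
    acc = 0.0
    if np.log(U[ui]) < dlik + dprior:
        for i in range(p):
            beta[i] += prop[i]
        for c in range(n):
            de = 0.0
            for i in range(p):
                de += x[c, i] * prop[i]
            eta[c] += de
        acc = 1.0
    ui += 1
    log_scale_beta[0] += (acc - 0.3) * adapt
    acc_out[0] = acc

    # ---- ridge (translation) moves ---------------------------------------
    n_ridge = ridge_j.shape[0]
    for r in range(n_ridge):
        delta = np.exp(ridge_log_scales[r]) * Z[zi]
        zi += 1
        j = ridge_j[r]
        bj = beta[j]
        logr = -0.5 * ((bj + delta) ** 2 - bj * bj) / beta_var
        if ridge_m[r] != 0.0:
            b0 = beta[intercept_col]
            b0n = b0 - delta * ridge_m[r]
            logr += -0.5 * (b0n * b0n - b0 * b0) / beta_var
        for ti in range(rt_off[r], rt_off[r + 1]):
            ci = rt_comp[ti]
            tau_c = taus[ci]
            off = comp_u_off[ci]
            po = rt_proj_off[ti]
            qdotu = 0.0
            for k in range(comp_size[ci]):
                qdotu += qproj_all[po + k] * u_all[off + k]
            logr += -0.5 * tau_c * (delta * delta * rt_pqp[ti] - 2.0 * delta * qdotu)
        if ridge_has_resid[r] == 1:
            for c in range(n):
                de = delta * resid_all[r, c]
                logr += y[c] * de - (np.exp(eta[c] + de) - np.exp(eta[c]))
        racc = 0.0
        if np.log(U[ui]) < logr:
            beta[j] = bj + delta
            if ridge_m[r] != 0.0:
                beta[intercept_col] -= delta * ridge_m[r]
            for ti in range(rt_off[r], rt_off[r + 1]):
                ci = rt_comp[ti]
                off = comp_u_off[ci]
                po = rt_proj_off[ti]
                for k in range(comp_size[ci]):
                    u_all[off + k] -= delta * proj_all[po + k]
            if ridge_has_resid[r] == 1:
                for c in range(n):
                    eta[c] += delta * resid_all[r, c]
            racc = 1.0
        ui += 1
        ridge_log_scales[r] += (racc - 0.44) * adapt

    # ---- random-effect components ----------------------------------------
    n_comp = comp_kind.shape[0]
    for ci in range(n_comp):
        kind = comp_kind[ci]
        mp = comp_map[ci]
        size = comp_size[ci]
        off = comp_u_off[ci]
        apo = comp_ap_off[ci]
        aio = comp_ai_off[ci]
        tau = taus[ci]
        sigma = np.exp(log_scales[ci])
        acc_sum = 0.0
        acc_n = 0
        c0 = comp_color_off[ci]
        for col in range(comp_n_colors[ci]):
            lo = color_bounds[c0 + col]
            hi = color_bounds[c0 + col + 1]
            for q in range(lo, hi):
                idx = color_nodes[q]
                gu = off + idx
                uo = u_all[gu]
                prop_s = sigma * Z[zi]
                zi += 1
                if kind == 0:
                    dp = -0.5 * tau * ((uo + prop_s) ** 2 - uo * uo)
                else:
                    s = 0.0
                    for ptr in range(ap_all[apo + idx], ap_all[apo + idx + 1]):
                        s += u_all[off + ai_all[aio + ptr]]
                    d = deg_all[gu]
                    dp = -0.5 * tau * d * ((uo + prop_s) ** 2 - uo * uo) + tau * prop_s * s
                dl = 0.0
                if mp == 0:
                    c = idx
                    dl = y[c] * prop_s - (np.exp(eta[c] + prop_s) - np.exp(eta[c]))
                elif mp == 1:
                    for t in range(T):
                        c = t * K + idx
                        dl += y[c] * prop_s - (np.exp(eta[c] + prop_s) - np.exp(eta[c]))
                else:
                    for k in range(K):
                        c = idx * K + k
                        dl += y[c] * prop_s - (np.exp(eta[c] + prop_s) - np.exp(eta[c]))
                if np.log(U[ui]) < dp + dl:
                    u_all[gu] = uo + prop_s
                    if mp == 0:
                        eta[idx] += prop_s
                    elif mp == 1:
                        for t in range(T):
                            eta[t * K + idx] += prop_s
                    else:
                        for k in range(K):
                            eta[idx * K + k] += prop_s
                    acc_sum += 1.0
                ui += 1
                acc_n += 1
        if comp_has_global[ci] == 1:
            g = size - 1
            dg = deg_all[off + g]
            zg = Z[zi]
            zi += 1
            if dg > 0:
                sg = 0.0
                for ptr in range(ap_all[apo + g], ap_all[apo + g + 1]):
                    sg += u_all[off + ai_all[aio + ptr]]
                u_all[off + g] = sg / dg + zg / np.sqrt(tau * dg)
            else:
                u_all[off + g] = 0.0
        if acc_n > 0:
            log_scales[ci] += (acc_sum / acc_n - 0.45) * adapt

        # recentre intrinsic components, absorbing the level into the intercept
        if comp_centre[ci] == 1 and intercept_col >= 0:
            m = K * T if mp == 0 else (K if mp == 1 else T)
            shift = 0.0
            for k in range(m):
                shift += u_all[off + k]
            shift /= m
            if shift != 0.0:
                for k in range(size):
                    u_all[off + k] -= shift
                beta[intercept_col] += shift

        # quadratic form for the conjugate tau draw (done by the caller)
        qf = 0.0
        if kind == 0:
            for k in range(size):
                qf += u_all[off + k] * u_all[off + k]
        else:
            for k in range(size):
                uk = u_all[off + k]
                s = 0.0
                for ptr in range(ap_all[apo + k], ap_all[apo + k + 1]):
                    s += u_all[off + ai_all[aio + ptr]]
                qf += uk * (deg_all[off + k] * uk - s)
        quads[ci] = qf


sweep_py = _sweep_impl

try:  # compiled path; the pure-Python twin stays available for parity checks
    from numba import njit

    sweep = njit(cache=True, fastmath=False)(_sweep_impl)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    sweep = _sweep_impl
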