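"""Numba kernel for the IRLS-ADMM iteration.

The solver is run tens of thousands of times on 8x4 submatrices during
heterogeneity clustering; the loop is compiled to keep that tractable.
Block matrices are passed in (n, n, 2) block form.  The kernel mirrors
the reference update equations in :mod:`commonlines.denoise` exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["admm_core"]


@njit(cache=True)
def _to_mat(Bb):
    n = Bb.shape[0]
    M = np.empty((2 * n, n))
    for i in range(n):
        for j in range(n):
            M[2 * i, j] = Bb[i, j, 0]
            M[2 * i + 1, j] = Bb[i, j, 1]
    return M


@njit(cache=True)
def _to_blocks(M):
    n = M.shape[1]
    B = np.empty((n, n, 2))
    for i in range(n):
        for j in range(n):
            B[i, j, 0] = M[2 * i, j]
            B[i, j, 1] = M[2 * i + 1, j]
    return B


@njit(cache=True)
def _rank3(Bb):
    M = _to_mat(Bb)
    U, s, Vt = np.linalg.svd(M)
    r = min(3, s.shape[0])
    Z = np.ascontiguousarray(U[:, :r] * s[:r]) @ np.ascontiguousarray(Vt[:r])
    return _to_blocks(Z)


@njit(cache=True)
def _update_T(Ab, Xb, gauge):
    n = Ab.shape[0]
    T = np.zeros((n, n))
    fro2 = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                t = Ab[i, j, 0] * Xb[i, j, 0] + Ab[i, j, 1] * Xb[i, j, 1]
                T[i, j] = t
                fro2 += t * t
    if fro2 > 0.0:
        c = gauge / np.sqrt(fro2)
        for i in range(n):
            for j in range(n):
                T[i, j] *= c
    return T


@njit(cache=True)
def _objective(Ab, T, Xb):
    n = Ab.shape[0]
    obj = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                r0 = T[i, j] * Ab[i, j, 0] - Xb[i, j, 0]
                r1 = T[i, j] * Ab[i, j, 1] - Xb[i, j, 1]
                obj += np.sqrt(r0 * r0 + r1 * r1)
    return obj


@njit(cache=True)
def admm_core(
    Ab, T0, rho, delta, outer_iters, admm_iters, inner_iters, tol, cap, norm_w
):
    """Full IRLS-ADMM loop on unit blocks ``Ab`` ((n, n, 2), zero diagonal).

    ``T0`` is the initial scale matrix (normally the measured block
    norms, so that an already-consistent input is a fixed point).
    Returns (Xb, T, trace, n_trace, converged, diverged).
    """
    n = Ab.shape[0]
    gauge = np.sqrt(n * (n - 1.0))

    T = T0.copy()
    for i in range(n):
        T[i, i] = 0.0
    T *= gauge / np.linalg.norm(T)

    TA = np.empty_like(Ab)
    for i in range(n):
        for j in range(n):
            TA[i, j, 0] = T[i, j] * Ab[i, j, 0]
            TA[i, j, 1] = T[i, j] * Ab[i, j, 1]
    Zb = _rank3(TA)
    Xb = Zb.copy()
    for i in range(n):
        Xb[i, i, 0] = 0.0
        Xb[i, i, 1] = 0.0
    Gb = np.zeros_like(Zb)

    # IRLS weights; optionally normalized to unit mean so the ADMM
    # penalty rho stays commensurate with the data term (the robust
    # averaging regime: the rank-3 consensus out-pulls the fit on
    # downweighted blocks).  Unnormalized weights give the
    # interpolating regime used for exact scale recovery.
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                r0 = T[i, j] * Ab[i, j, 0] - Zb[i, j, 0]
                r1 = T[i, j] * Ab[i, j, 1] - Zb[i, j, 1]
                W[i, j] = 1.0 / np.sqrt(r0 * r0 + r1 * r1 + delta * delta)
    if norm_w:
        W *= n * (n - 1.0) / W.sum()

    trace = np.empty(outer_iters)
    n_trace = 0
    converged = False
    diverged = False

    for outer in range(outer_iters):
        prev_obj = -1.0
        for k in range(admm_iters):
            for _ in range(inner_iters):
                max_delta = 0.0
                max_x = 0.0
                for i in range(n):
                    for j in range(n):
                        if i == j:
                            continue
                        w2 = W[i, j] * W[i, j]
                        d = w2 + rho
                        x0 = (
                            w2 * T[i, j] * Ab[i, j, 0]
                            + rho * Zb[i, j, 0]
                            - Gb[i, j, 0]
                        ) / d
                        x1 = (
                            w2 * T[i, j] * Ab[i, j, 1]
                            + rho * Zb[i, j, 1]
                            - Gb[i, j, 1]
                        ) / d
                        c0 = abs(x0 - Xb[i, j, 0])
                        c1 = abs(x1 - Xb[i, j, 1])
                        if c0 > max_delta:
                            max_delta = c0
                        if c1 > max_delta:
                            max_delta = c1
                        Xb[i, j, 0] = x0
                        Xb[i, j, 1] = x1
                        a0 = abs(x0)
                        a1 = abs(x1)
                        if a0 > max_x:
                            max_x = a0
                        if a1 > max_x:
                            max_x = a1
                T = _update_T(Ab, Xb, gauge)
                if max_delta <= tol * (1.0 + max_x):
                    break
            Zb = _rank3(Xb + Gb / rho)
            for i in range(n):
                for j in range(n):
                    Gb[i, j, 0] += rho * (Xb[i, j, 0] - Zb[i, j, 0])
                    Gb[i, j, 1] += rho * (Xb[i, j, 1] - Zb[i, j, 1])

            bad = False
            mx = 0.0
            for i in range(n):
                for j in range(n):
                    v0 = Xb[i, j, 0]
                    v1 = Xb[i, j, 1]
                    if not (np.isfinite(v0) and np.isfinite(v1)):
                        bad = True
                    if abs(v0) > mx:
                        mx = abs(v0)
                    if abs(v1) > mx:
                        mx = abs(v1)
            if bad or mx > cap:
                diverged = True
                break

            obj = _objective(Ab, T, Xb)
            if prev_obj >= 0.0 and abs(obj - prev_obj) <= tol * max(prev_obj, 1.0):
                # primal consensus residual
                pnum = 0.0
                pden = 0.0
                for i in range(n):
                    for j in range(n):
                        pnum += (Xb[i, j, 0] - Zb[i, j, 0]) ** 2 + (
                            Xb[i, j, 1] - Zb[i, j, 1]
                        ) ** 2
                        pden += Xb[i, j, 0] ** 2 + Xb[i, j, 1] ** 2
                if pden > 0 and np.sqrt(pnum / pden) <= np.sqrt(tol):
                    break
                if abs(obj - prev_obj) <= 0.1 * tol * max(prev_obj, 1.0):
                    break
            prev_obj = obj
        if diverged:
            break
        obj = _objective(Ab, T, Xb)
        trace[n_trace] = obj
        n_trace += 1
        if n_trace >= 2 and abs(trace[n_trace - 1] - trace[n_trace - 2]) <= tol * max(
            abs(trace[n_trace - 2]), 1.0
        ):
            converged = True
            break
        for i in range(n):
            for j in range(n):
                if i != j:
                    r0 = T[i, j] * Ab[i, j, 0] - Zb[i, j, 0]
                    r1 = T[i, j] * Ab[i, j, 1] - Zb[i, j, 1]
                    W[i, j] = 1.0 / np.sqrt(r0 * r0 + r1 * r1 + delta * delta)
        if norm_w:
            W *= n * (n - 1.0) / W.sum()

    for i in range(n):
        Xb[i, i, 0] = 0.0
        Xb[i, i, 1] = 0.0
    return Xb, T, trace, n_trace, converged, diverged


@njit(cache=True)
def ap_polish(Ab, Xb, iters, tol):
    """Alternating projections between {tau o A_unit} and the rank-3 set.

    Exact local refinement of an approximate ADMM solution: project onto
    the per-block scale-consistent set (x_ij <- <a_ij, x_ij> a_ij), then
    onto rank-3 matrices, until the iterates stop moving.  Returns the
    polished blocks and the final scales.
    """
    n = Ab.shape[0]
    T = np.zeros((n, n))
    for _ in range(iters):
        for i in range(n):
            for j in range(n):
                if i == j:
                    T[i, j] = 0.0
                else:
                    T[i, j] = Ab[i, j, 0] * Xb[i, j, 0] + Ab[i, j, 1] * Xb[i, j, 1]
        Xs = np.empty_like(Xb)
        for i in range(n):
            for j in range(n):
                Xs[i, j, 0] = T[i, j] * Ab[i, j, 0]
                Xs[i, j, 1] = T[i, j] * Ab[i, j, 1]
        Xn = _rank3(Xs)
        for i in range(n):
            Xn[i, i, 0] = 0.0
            Xn[i, i, 1] = 0.0
        num = 0.0
        den = 0.0
        for i in range(n):
            for j in range(n):
                num += (Xn[i, j, 0] - Xb[i, j, 0]) ** 2 + (
                    Xn[i, j, 1] - Xb[i, j, 1]
                ) ** 2
                den += Xn[i, j, 0] ** 2 + Xn[i, j, 1] ** 2
        Xb = Xn
        if den == 0.0 or num <= tol * tol * den:
            break
    for i in range(n):
        for j in range(n):
            if i == j:
                T[i, j] = 0.0
            else:
                T[i, j] = Ab[i, j, 0] * Xb[i, j, 0] + Ab[i, j, 1] * Xb[i, j, 1]
    return Xb, T
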