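"""Joint scale estimation and rank-3 denoising of common-lines matrices.

A measured common-lines matrix carries one unknown nonzero scalar per
off-diagonal block (representatives are only defined up to scale and
sign).  After unit-normalizing the blocks, we look for per-block scales
``tau_ij`` and a rank-3 matrix ``X`` with zero diagonal blocks such that
``tau_ij a_ij ~= x_ij``, minimizing a robust mixed L1/Frobenius misfit

    sum_ij || tau_ij a_ij - x_ij ||_2 .

The robust norm is handled by iteratively reweighted least squares
(IRLS): each outer iteration minimizes a weighted Frobenius surrogate
with weights w_ij = 1 / sqrt(||tau_ij a_ij - z_ij||^2 + delta^2).  The
weighted problem is bilinear in (X, tau) with a rank constraint, solved
by ADMM with a consensus split X = Z where Z carries the rank-3
constraint via truncated SVD:

    1a. x_ij <- (w_ij^2 tau_ij a_ij + rho z_ij - gamma_ij) / (w_ij^2 + rho),
        then zero the diagonal blocks;
    1b. tau_ij <- <a_ij, x_ij>, then renormalize ||T||_F (gauge fixing);
    2.  Z <- best rank-3 approximation of X + Gamma/rho;
    3.  Gamma <- Gamma + rho (X - Z).

The scale matrix T is renormalized to Frobenius norm sqrt(n(n-1)) after
every update: the objective is invariant to a global scale, and without a
gauge T -> 0, X -> 0 is a vacuous minimizer.  Scales may be negative
(sign ambiguity of representatives / chirality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CommonLinesMatrix

__all__ = [
    "AdmmParams",
    "AdmmState",
    "DenoiseResult",
    "admm_round",
    "irls_admm",
    "irls_weights",
    "normalize_blocks",
    "update_scales",
]


@dataclass
class AdmmParams:
    """Tuning knobs of the IRLS-ADMM solver (all dimensionless).

    rho : ADMM penalty weight on the consensus term ||X - Z||^2.
    delta : IRLS regularizer; if None, set at runtime to 1e-2 times the
        mean block residual at initialization.
    outer_iters / admm_iters / inner_iters : caps on the IRLS, ADMM, and
        (X, tau) alternation loops.
    tol : relative-change stopping tolerance.
    divergence_cap : any entry beyond this magnitude flags divergence.
    """

    rho: float = 1.0
    delta: float | None = None
    outer_iters: int = 20
    admm_iters: int = 100
    inner_iters: int = 10
    tol: float = 1e-8
    divergence_cap: float = 1e9
    polish_iters: int = 300
    polish_tol: float = 1e-15
    init: str = "norms"  # initial scales: "norms" (measured) or "ones"
    normalize_weights: bool = True  # robust averaging vs interpolating regime

    def __post_init__(self):
        if self.init not in ("norms", "ones"):
            raise ValueError("init must be 'norms' or 'ones'")
        if self.rho <= 0 or self.tol <= 0 or self.divergence_cap <= 0:
            raise ValueError("rho, tol and divergence_cap must be positive")
        if self.delta is not None and self.delta <= 0:
            raise ValueError("delta must be positive")
        if min(self.outer_iters, self.admm_iters, self.inner_iters) < 1:
            raise ValueError("iteration counts must be positive")


@dataclass
class AdmmState:
    """Internal variables of one IRLS-ADMM run, in block form (n, n, 2)."""

    Xb: np.ndarray  # denoised estimate
    T: np.ndarray  # per-block scales, zero diagonal
    Zb: np.ndarray  # rank-3 consensus surrogate
    Gb: np.ndarray  # dual multipliers
    W: np.ndarray  # IRLS weights, zero diagonal
    diverged: bool = False

    @property
    def X(self) -> np.ndarray:
        return _blocks_to_matrix(self.Xb)

    @property
    def Z(self) -> np.ndarray:
        return _blocks_to_matrix(self.Zb)

    @property
    def Gamma(self) -> np.ndarray:
        return _blocks_to_matrix(self.Gb)


@dataclass
class DenoiseResult:
    """Output of :func:`irls_admm`."""

    X: CommonLinesMatrix
    T: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    diverged: bool
    n_outer: int = 0


def _blocks_to_matrix(Bb: np.ndarray) -> np.ndarray:
    n = Bb.shape[0]
    return Bb.transpose(0, 2, 1).reshape(2 * n, n)


def _rank3_blocks(Xb: np.ndarray) -> np.ndarray:
    """Best rank-3 approximation, computed on the 2n x n layout."""
    M = _blocks_to_matrix(Xb)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    Z = (U[:, :3] * s[:3]) @ Vt[:3]
    n = Xb.shape[0]
    return Z.reshape(n, 2, n).transpose(0, 2, 1)


def normalize_blocks(A: CommonLinesMatrix) -> CommonLinesMatrix:
    """Rescale every off-diagonal block to unit Euclidean norm."""
    blocks = A.blocks().copy()
    norms = np.linalg.norm(blocks, axis=2)
    off = ~np.eye(A.n, dtype=bool)
    bad = off & (norms == 0.0)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"off-diagonal block ({i},{j}) is zero; cannot normalize")
    norms[~off] = 1.0
    blocks /= norms[:, :, None]
    return CommonLinesMatrix.from_blocks(blocks, check=False)


def irls_weights(
    A_unit: CommonLinesMatrix | np.ndarray,
    T: np.ndarray,
    Z: CommonLinesMatrix | np.ndarray,
    delta: float,
) -> np.ndarray:
    """IRLS weights w_ij = 1 / sqrt(||tau_ij a_ij - z_ij||^2 + delta^2)."""
    Ab = A_unit.blocks() if isinstance(A_unit, CommonLinesMatrix) else np.asarray(A_unit)
    Zb = Z.blocks() if isinstance(Z, CommonLinesMatrix) else np.asarray(Z)
    res2 = np.sum((T[:, :, None] * Ab - Zb) ** 2, axis=2)
    W = 1.0 / np.sqrt(res2 + delta**2)
    np.fill_diagonal(W, 0.0)
    return W


def update_scales(Ab: np.ndarray, Xb: np.ndarray, n: int) -> np.ndarray:
    """Closed-form scale update tau_ij = <a_ij, x_ij>, gauge-renormalized.

    For unit-norm a_ij the inner product is the exact minimizer of
    ||tau a_ij - x_ij||^2; T is then rescaled to Frobenius norm
    sqrt(n(n-1)) to pin the global scale.
    """
    T = np.sum(Ab * Xb, axis=2)
    np.fill_diagonal(T, 0.0)
    fro = np.linalg.norm(T)
    if fro == 0.0:
        return T  # degenerate: all-zero X; caller flags it
    return T * (np.sqrt(n * (n - 1)) / fro)


def admm_round(A_unit: CommonLinesMatrix, state: AdmmState, params: AdmmParams) -> AdmmState:
    """One full ADMM round: (X, tau) alternation, rank-3 Z-update, dual ascent."""
    Ab = A_unit.blocks() if isinstance(A_unit, CommonLinesMatrix) else A_unit
    n = Ab.shape[0]
    rho = params.rho
    W2 = state.W**2
    Xb, T = state.Xb, state.T
    diag = np.eye(n, dtype=bool)
    for _ in range(params.inner_iters):
        X_new = (W2[:, :, None] * T[:, :, None] * Ab + rho * state.Zb - state.Gb) / (
            W2[:, :, None] + rho
        )
        X_new[diag] = 0.0
        T = update_scales(Ab, X_new, n)
        delta = np.max(np.abs(X_new - Xb))
        Xb = X_new
        if delta <= params.tol * (1.0 + np.max(np.abs(Xb))):
            break
    Zb = _rank3_blocks(Xb + state.Gb / rho)
    Gb = state.Gb + rho * (Xb - Zb)
    diverged = not np.all(np.isfinite(Xb)) or np.max(np.abs(Xb)) > params.divergence_cap
    return AdmmState(Xb=Xb, T=T, Zb=Zb, Gb=Gb, W=state.W, diverged=diverged)


def _objective(Ab: np.ndarray, T: np.ndarray, Xb: np.ndarray) -> float:
    """Mixed L1/Frobenius misfit sum_ij ||tau_ij a_ij - x_ij||."""
    res = np.linalg.norm(T[:, :, None] * Ab - Xb, axis=2)
    return float(np.sum(res))


def irls_admm(A: CommonLinesMatrix, params: AdmmParams | None = None) -> DenoiseResult:
    """Denoise a common-lines matrix by joint scale / rank-3 estimation.

    The input blocks are unit-normalized first; see the module docstring
    for the algorithm.  Returns the denoised matrix X (zero diagonal
    blocks, numerically rank 3 on success), the block scales, the robust
    objective trace over outer iterations, and convergence flags.
    """
    if params is None:
        params = AdmmParams()
    if A.n < 3:
        raise ValueError("need n >= 3")
    A_unit = normalize_blocks(A)
    Ab = A_unit.blocks()
    n = A.n

    # initial scales: the measured block norms (gauge-renormalized), so a
    # matrix that is already consistent is a fixed point of the iteration;
    # "ones" starts agnostic to the measured magnitudes
    if params.init == "norms":
        T0 = np.linalg.norm(A.blocks(), axis=2)
    else:
        T0 = np.ones((n, n))
    np.fill_diagonal(T0, 0.0)
    T0 *= np.sqrt(n * (n - 1)) / np.linalg.norm(T0)

    delta = params.delta
    if delta is None:
        # 1e-2 of the mean block residual at initialization
        Zb0 = _rank3_blocks(T0[:, :, None] * Ab)
        init_res = np.linalg.norm(T0[:, :, None] * Ab - Zb0, axis=2)
        off = ~np.eye(n, dtype=bool)
        delta = max(1e-2 * float(np.mean(init_res[off])), 1e-8)

    from ._admm_kernel import admm_core

    Xb, T, trace_arr, n_trace, converged, diverged = admm_core(
        np.ascontiguousarray(Ab),
        np.ascontiguousarray(T0),
        float(params.rho),
        float(delta),
        params.outer_iters,
        params.admm_iters,
        params.inner_iters,
        float(params.tol),
        float(params.divergence_cap),
        bool(params.normalize_weights),
    )
    trace = trace_arr[:n_trace]
    if not diverged and not converged and len(trace) >= 2:
        # ran out of outer iterations; treat a flat tail as converged
        converged = abs(trace[-1] - trace[-2]) <= 1e-4 * max(abs(trace[-2]), 1.0)

    if not diverged and params.polish_iters > 0:
        # exact local refinement: ADMM selects the basin, alternating
        # projections drive the scale/rank-3 consistency to precision.
        # The polish interpolates every block direction exactly, which
        # is only right when the data admits a consistent scaling; it is
        # kept only when it does not worsen the aggregate constraint
        # error (on outlier-laden data exact interpolation is harmful).
        from ._admm_kernel import ap_polish
        from .constraints import quadratic_error

        Xp, Tp = ap_polish(
            np.ascontiguousarray(Ab),
            np.ascontiguousarray(Xb),
            params.polish_iters,
            float(params.polish_tol),
        )
        if np.linalg.norm(Xp) > 1e-3 * np.linalg.norm(Xb):
            try:
                q_raw = quadratic_error(CommonLinesMatrix.from_blocks(Xb, check=False))
                q_pol = quadratic_error(CommonLinesMatrix.from_blocks(Xp, check=False))
            except ValueError:
                q_raw, q_pol = 0.0, np.inf
            if q_pol <= q_raw:
                Xb, T = Xp, Tp

    return DenoiseResult(
        X=CommonLinesMatrix.from_blocks(Xb, check=False),
        T=T,
        objective_trace=trace,
        converged=bool(converged),
        diverged=bool(diverged),
        n_outer=n_trace if n_trace else 1,
    )
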