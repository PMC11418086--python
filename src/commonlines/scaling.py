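"""Sinkhorn-style row/column scaling to enforce the quadratic constraints.

Rank-3 denoising leaves one global family of scale errors of the form
``tau_ij = lambda_i mu_j``.  Scaling block-row ``i`` by ``lambda_i``
multiplies ``||a_ij||`` by ``lambda_i`` and the triple determinant
``d_i = det[a_ij a_ik]`` by ``lambda_i^2``; scaling column ``j`` by
``mu_j`` multiplies ``||a_ij||`` by ``mu_j`` and ``d_i`` by
``mu_j mu_k``.  Each half-step therefore solves a homogeneous linear
least-squares system for the scales:

* row step — norm rows ``lambda_i ||a_ij|| - lambda_j ||a_ji|| = 0`` and,
  after taking signed square roots ``sr(x) = sign(x) sqrt(|x|)`` of the
  determinant identities ``d_i lambda_i^2 + d_j lambda_j^2 = 0``, the
  linear rows ``sr(d_i) lambda_i + sr(d_j) lambda_j = 0`` and
  ``sr(d_j) lambda_j + sr(d_k) lambda_k = 0``;
* column step — norm rows ``mu_j ||a_ij|| - mu_i ||a_ji|| = 0`` and,
  dividing the determinant identities by the common column scale, the
  linear rows ``d_i mu_j + d_j mu_i = 0`` and ``d_j mu_k + d_k mu_j = 0``.

Each system is solved by the right singular vector of smallest singular
value (sign-fixed so the entry sum is nonnegative), and the scales are
applied in place.  Alternation continues until the aggregate quadratic
error stops changing.  Nonzero scaling never changes the rank, so the
rank-3 property of the input is preserved.  The irreducible global sign
of the result is the chirality ambiguity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np

from .constraints import _pairs, _triple_dets, _triples, quadratic_error
from .geometry import CommonLinesMatrix

__all__ = [
    "SinkhornState",
    "col_scale_step",
    "row_scale_step",
    "sinkhorn",
    "sync_column_signs",
]

_SCALE_FLOOR = 1e-12


@dataclass
class SinkhornState:
    """Latest row/column scales and the residual history of one run."""

    lambda_row: np.ndarray
    mu_col: np.ndarray
    residual_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    diverged: bool = False
    converged: bool = False


def _signed_root(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.sqrt(np.abs(x))


def _smallest_right_singular(M: np.ndarray) -> np.ndarray:
    _, s, Vt = np.linalg.svd(M, full_matrices=False)
    if len(s) >= 2 and s[-1] > 0 and s[-2] / max(s[0], 1e-300) < 1e-8:
        warnings.warn("scale system is nearly rank-deficient; scales ambiguous")
    v = Vt[-1]
    if v.sum() < 0:
        v = -v
    return v


def _norms_and_dets(A: CommonLinesMatrix):
    blocks = A.blocks()
    norms = np.linalg.norm(blocks, axis=2)
    triples = _triples(A.n)
    dets = _triple_dets(blocks, triples)
    return norms, triples, dets


def row_scale_step(A: CommonLinesMatrix) -> np.ndarray:
    """Block-row scales (unit norm) from one homogeneous least-squares solve."""
    n = A.n
    if n < 3:
        raise ValueError("need n >= 3")
    norms, triples, dets = _norms_and_dets(A)
    iu, ju = _pairs(n)
    n_pairs, n_triples = len(iu), len(triples)
    M = np.zeros((n_pairs + 2 * n_triples, n))
    rows = np.arange(n_pairs)
    M[rows, iu] = norms[iu, ju]
    M[rows, ju] = -norms[ju, iu]
    sr = _signed_root(dets)
    r0 = n_pairs + np.arange(n_triples)
    M[r0, triples[:, 0]] = sr[:, 0]
    M[r0, triples[:, 1]] = sr[:, 1]
    r1 = r0 + n_triples
    M[r1, triples[:, 1]] = sr[:, 1]
    M[r1, triples[:, 2]] = sr[:, 2]
    return _smallest_right_singular(M)


def _col_det_system(n: int, triples: np.ndarray, dets: np.ndarray) -> np.ndarray:
    M = np.zeros((2 * len(triples), n))
    r0 = np.arange(len(triples))
    M[r0, triples[:, 1]] = dets[:, 0]
    M[r0, triples[:, 0]] = dets[:, 1]
    r1 = r0 + len(triples)
    M[r1, triples[:, 2]] = dets[:, 1]
    M[r1, triples[:, 1]] = dets[:, 2]
    return M


def col_scale_step(A: CommonLinesMatrix) -> np.ndarray:
    """Column scales (unit norm) from one homogeneous least-squares solve."""
    n = A.n
    if n < 3:
        raise ValueError("need n >= 3")
    norms, triples, dets = _norms_and_dets(A)
    iu, ju = _pairs(n)
    n_pairs = len(iu)
    M = np.zeros((n_pairs, n))
    rows = np.arange(n_pairs)
    M[rows, ju] = norms[iu, ju]
    M[rows, iu] = -norms[ju, iu]
    M = np.vstack([M, _col_det_system(n, triples, dets)])
    return _smallest_right_singular(M)


def sync_column_signs(A: CommonLinesMatrix) -> np.ndarray:
    """Column scales from the determinant rows alone.

    The norm constraints are sign-blind and, solved jointly, push all
    scales toward one sign; the determinant constraints are linear in
    the signed column scales and on clean rank-1-scaled input their
    system is solved exactly by the true (possibly mixed-sign) scales.
    Used to synchronize column signs before the norm+det alternation.
    (Block-row signs are invisible to every constraint — flipping a
    block-row maps pure matrices to pure matrices — so no analogous row
    step exists.)
    """
    norms, triples, dets = _norms_and_dets(A)
    return _smallest_right_singular(_col_det_system(A.n, triples, dets))


def _apply_row_scales(A: CommonLinesMatrix, lam: np.ndarray) -> None:
    A.data *= np.repeat(lam, 2)[:, None]


def _apply_col_scales(A: CommonLinesMatrix, mu: np.ndarray) -> None:
    A.data *= mu[None, :]


def sinkhorn(
    A: CommonLinesMatrix, max_iters: int = 200, tol: float = 1e-10
) -> tuple[CommonLinesMatrix, SinkhornState]:
    """Alternate row and column scaling until the quadratic constraints hold.

    Returns the scaled matrix (global scale arbitrary) and the final
    state.  Sets ``diverged`` when a scale entry collapses below 1e-12 in
    magnitude or the residual grows tenfold over its best value; the
    partial result is still returned.
    """
    if A.n < 3:
        raise ValueError("need n >= 3")
    Ahat = A.copy()
    # keep the two residual families commensurate across iterations
    Ahat.data *= np.sqrt(A.n * (A.n - 1)) / np.linalg.norm(Ahat.data)
    lam = np.ones(A.n) / np.sqrt(A.n)
    # column-sign synchronization: det-only solve, exact on clean input.
    # Only the signs are applied; the solve's magnitudes can be badly
    # conditioned (they scale like squared row scales) and the norm rows
    # of the alternation recover magnitudes reliably on their own.
    mu = sync_column_signs(Ahat)
    if np.min(np.abs(mu)) >= _SCALE_FLOOR:
        _apply_col_scales(Ahat, np.sign(mu))
    trace = [quadratic_error(Ahat)]
    best = trace[0]
    diverged = False
    converged = False
    for _ in range(max_iters):
        lam = row_scale_step(Ahat)
        if np.min(np.abs(lam)) < max(_SCALE_FLOOR, 1e-6 * np.max(np.abs(lam))):
            diverged = True
            break
        _apply_row_scales(Ahat, lam)
        mu = col_scale_step(Ahat)
        if np.min(np.abs(mu)) < max(_SCALE_FLOOR, 1e-6 * np.max(np.abs(mu))):
            diverged = True
            break
        _apply_col_scales(Ahat, mu)
        Ahat.data *= np.sqrt(A.n * (A.n - 1)) / np.linalg.norm(Ahat.data)
        err = quadratic_error(Ahat)
        trace.append(err)
        if err > 10.0 * max(best, 1e-14):
            diverged = True
            break
        best = min(best, err)
        if abs(trace[-1] - trace[-2]) < tol or err < tol:
            converged = True
            break
    state = SinkhornState(
        lambda_row=lam,
        mu_col=mu,
        residual_trace=np.asarray(trace),
        diverged=diverged,
        converged=converged,
    )
    return Ahat, state
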