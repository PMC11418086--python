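"""Rotation recovery from an estimated pure common-lines matrix.

A pure common-lines matrix factors as ``A = B C`` with ``B_i = Jt R_i``.
An SVD rank-3 factorization ``A = U V`` determines ``B`` only up to an
invertible 3x3 gauge ``Q``: ``B = U Q``.  Because the rows of each
``B_i`` are orthonormal, ``U_i Q Q^T U_i^T = I_2`` for all ``i``; setting
``H = Q Q^T`` this is an affine-linear least-squares problem in the six
entries of the symmetric matrix ``H``, solved through its 6x6 normal
equations.  An eigendecomposition ``H = P D P^T`` then gives
``Q = P sqrt(D)`` (the remaining orthogonal freedom in ``Q`` is exactly
the global-rotation ambiguity), and each block of ``B_hat = U Q``
determines two rows of a rotation, the third being their cross product.
Negating the matrix gives the second, mirror-handed candidate tuple —
the chirality ambiguity, which common lines cannot resolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CommonLinesMatrix

__all__ = [
    "GramSolution",
    "nearest_rotation",
    "rank3_factor",
    "recover_rotations",
    "rotations_from_factors",
    "solve_gram",
]

# index pairs of the 6 free entries of a symmetric 3x3 matrix
_SYM_IDX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


@dataclass
class GramSolution:
    """Rank-3 factors and the symmetric Gram candidate ``H ~ Q Q^T``."""

    U: np.ndarray  # 2n x 3
    V: np.ndarray | None  # 3 x n
    H: np.ndarray  # 3 x 3 symmetric
    eigvals: np.ndarray  # descending
    residual: float


def rank3_factor(A: CommonLinesMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Best rank-3 factorization ``A ~ U V`` via truncated SVD."""
    Um, s, Vt = np.linalg.svd(A.data, full_matrices=False)
    if s[2] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("matrix is numerically rank-deficient (sigma3 ~ 0)")
    return Um[:, :3] * s[:3], Vt[:3]


def solve_gram(U: np.ndarray) -> GramSolution:
    """Least-squares symmetric ``H`` with ``U_i H U_i^T = I_2`` per block."""
    U = np.asarray(U, dtype=float)
    n2 = U.shape[0]
    if n2 % 2 or n2 < 6 or U.shape[1] != 3:
        raise ValueError("U must be 2n x 3 with n >= 3")
    n = n2 // 2
    Ub = U.reshape(n, 2, 3)
    # design matrix: 4 equations per image, 6 symmetric unknowns
    cols = []
    for a, b in _SYM_IDX:
        E = np.zeros((3, 3))
        E[a, b] = 1.0
        E[b, a] = 1.0
        cols.append(np.einsum("nij,jk,nlk->nil", Ub, E, Ub).reshape(-1))
    D = np.stack(cols, axis=1)  # 4n x 6
    b = np.tile(np.eye(2).reshape(-1), n)
    N = D.T @ D
    sv = np.linalg.svd(N, compute_uv=False)
    if sv[-1] <= 1e-10 * max(sv[0], 1e-300):
        raise ValueError("normal equations are singular: non-generic input")
    h = np.linalg.solve(N, D.T @ b)
    H = np.zeros((3, 3))
    for val, (a, bb) in zip(h, _SYM_IDX):
        H[a, bb] = val
        H[bb, a] = val
    residual = float(np.sum((D @ h - b) ** 2))
    eigvals = np.sort(np.linalg.eigvalsh(H))[::-1]
    return GramSolution(U=U, V=None, H=H, eigvals=eigvals, residual=residual)


def nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Orthogonal polar factor of ``M`` with determinant forced to +1."""
    Um, _, Vt = np.linalg.svd(M)
    R = Um @ Vt
    if np.linalg.det(R) < 0:
        R = Um @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return R


def rotations_from_factors(U: np.ndarray, H: np.ndarray) -> list[np.ndarray]:
    """Rotations from the gauge-corrected factor ``B_hat = U P sqrt(D)``.

    If ``H`` has two or more negative eigenvalues the global sign is
    flipped (the +-A ambiguity); residual tiny negatives are clamped.
    Each recovered matrix is projected to the nearest rotation.
    """
    H = 0.5 * (np.asarray(H, dtype=float) + np.asarray(H, dtype=float).T)
    w, P = np.linalg.eigh(H)
    if np.sum(w < 0) >= 2:
        H = -H
        w, P = np.linalg.eigh(H)
    w = np.clip(w, 1e-12, None)
    Q = P * np.sqrt(w)
    Bhat = np.asarray(U, dtype=float) @ Q
    n = Bhat.shape[0] // 2
    rots = []
    for i in range(n):
        b1, b2 = Bhat[2 * i], Bhat[2 * i + 1]
        row1, row2 = b2, -b1
        R = np.vstack([row1, row2, np.cross(row1, row2)])
        rots.append(nearest_rotation(R))
    return rots


def recover_rotations(
    Ahat: CommonLinesMatrix,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Both chirality candidates for the rotations behind ``Ahat``.

    Runs the recovery on ``+A`` and ``-A``; exactly one candidate matches
    the ground-truth hand.  The two tuples are related by conjugation
    with the reflection ``J = diag(1, 1, -1)`` up to a global rotation.
    """
    U, V = rank3_factor(Ahat)
    sol = solve_gram(U)
    sol.V = V
    rots_plus = rotations_from_factors(U, sol.H)
    rots_minus = rotations_from_factors(-U, sol.H)
    return rots_plus, rots_minus
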