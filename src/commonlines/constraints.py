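"""Algebraic constraints satisfied by pure common-lines matrices.

Beyond the rank-3 condition, a pure common-lines matrix satisfies one
norm-equality per unordered pair of images,

    ||a_ij|| = ||a_ji||,

and two determinant-equalities per unordered triple {i<j<k}.  With
d_i = det[a_ij a_ik], d_j = det[a_ji a_jk], d_k = det[a_ki a_kj], purity
forces d_i = -d_j = d_k (each equals the scalar triple product of the
three viewing axes), i.e. the residuals |d_i + d_j| and |d_j + d_k|
vanish.  The sign pattern (+,-,+) over the cyclic base images is frozen
by oracle tests on pure fixtures.

These quadratic residuals, evaluated on a matrix normalized to a fixed
Frobenius norm, aggregate into a scale-invariant consistency score used
to decide whether a set of common lines is consistent with one molecule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .geometry import CommonLinesMatrix

__all__ = [
    "ConstraintReport",
    "constraint_report",
    "count_quadratic_constraints",
    "det_residuals",
    "norm_residuals",
    "quadratic_error",
    "rank3_gap",
]


@dataclass
class ConstraintReport:
    """Residuals of all quadratic constraints plus the spectral-gap data."""

    norm_residuals: np.ndarray
    det_residuals: np.ndarray
    sigma3: float
    sigma4: float
    aggregate_error: float

    def to_dict(self) -> dict:
        return {
            "norm_residuals": self.norm_residuals.tolist(),
            "det_residuals": self.det_residuals.tolist(),
            "sigma3": self.sigma3,
            "sigma4": self.sigma4,
            "aggregate_error": self.aggregate_error,
        }


_TRIPLES_CACHE: dict[int, np.ndarray] = {}
_PAIRS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triples(n: int) -> np.ndarray:
    """Cached array of all unordered index triples {i<j<k}."""
    if n not in _TRIPLES_CACHE:
        _TRIPLES_CACHE[n] = np.array(list(combinations(range(n), 3)))
    return _TRIPLES_CACHE[n]


def _pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached upper-triangular index pair arrays."""
    if n not in _PAIRS_CACHE:
        _PAIRS_CACHE[n] = np.triu_indices(n, k=1)
    return _PAIRS_CACHE[n]


def norm_residuals(A: CommonLinesMatrix) -> np.ndarray:
    """| ||a_ij|| - ||a_ji|| | for every unordered pair, lexicographic order."""
    norms = np.linalg.norm(A.blocks(), axis=2)  # n x n
    iu, ju = _pairs(A.n)
    return np.abs(norms[iu, ju] - norms[ju, iu])


def _triple_dets(blocks: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """d_i, d_j, d_k for each triple: columns of the 2x2 dets per base image."""
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]

    def det2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        return u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]

    di = det2(blocks[i, j], blocks[i, k])
    dj = det2(blocks[j, i], blocks[j, k])
    dk = det2(blocks[k, i], blocks[k, j])
    return np.stack([di, dj, dk], axis=1)


def det_residuals(A: CommonLinesMatrix) -> np.ndarray:
    """Two residuals |d_i + d_j|, |d_j + d_k| per unordered triple {i<j<k}."""
    if A.n < 3:
        raise ValueError("determinant constraints need n >= 3")
    d = _triple_dets(A.blocks(), _triples(A.n))
    res = np.stack([np.abs(d[:, 0] + d[:, 1]), np.abs(d[:, 1] + d[:, 2])], axis=1)
    return res.reshape(-1)


def count_quadratic_constraints(n: int) -> int:
    """Number of quadratic constraints: C(n,2) norm + 2*C(n,3) determinant."""
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    return n * (n - 1) // 2 + 2 * (n * (n - 1) * (n - 2) // 6)


def rank3_gap(A: CommonLinesMatrix) -> tuple[float, float]:
    """Third and fourth singular values of the matrix (sigma4 := 0 if n < 4)."""
    s = np.linalg.svd(A.data, compute_uv=False)
    sigma3 = float(s[2]) if len(s) >= 3 else 0.0
    sigma4 = float(s[3]) if len(s) >= 4 else 0.0
    return sigma3, sigma4


def quadratic_error(A: CommonLinesMatrix) -> float:
    """Scale-invariant RMS of all quadratic-constraint residuals.

    The matrix is first rescaled to Frobenius norm sqrt(n(n-1)) (the norm a
    unit-block matrix would have), so scores are comparable across samples
    and invariant to a global scale.
    """
    fro = np.linalg.norm(A.data)
    if fro == 0.0:
        raise ValueError("quadratic_error undefined for the zero matrix")
    scale = np.sqrt(A.n * (A.n - 1)) / fro
    B = CommonLinesMatrix(A.data * scale, check=False)
    res = np.concatenate([norm_residuals(B), det_residuals(B)])
    return float(np.sqrt(np.mean(res**2)))


def constraint_report(A: CommonLinesMatrix, tol: float = 1e-10) -> ConstraintReport:
    """Full constraint evaluation of a common-lines matrix."""
    nr = norm_residuals(A)
    dr = det_residuals(A)
    s3, s4 = rank3_gap(A)
    return ConstraintReport(
        norm_residuals=nr,
        det_residuals=dr,
        sigma3=s3,
        sigma4=s4,
        aggregate_error=quadratic_error(A),
    )
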