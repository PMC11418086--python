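"""Rotations, common-line directions, and pure common-lines matrices.

A projection image taken at rotation ``R_i`` has a Fourier transform equal
to a central slice of the 3-D transform (Fourier slice theorem).  Two slices
intersect in a single 3-D line with direction ``d = r_i x r_j``, where
``r_m`` is the third row of ``R_m`` (the viewing axis).  Expressed in the
coordinates of image ``i``, the in-plane direction of that line is the first
two coordinates of ``R_i d`` — the canonical *representative* ``a_ij``.

Stacking the representatives as 2x1 blocks yields the 2n x n common-lines
matrix; with the canonical (scale-1) representatives it factors as
``A = B C`` with ``B_i = Jt R_i`` (2x3) and ``c_j = R_j^T e3``, hence has
rank 3 for generic rotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "JTILDE",
    "CommonLinesMatrix",
    "RankFactors",
    "assemble_matrix",
    "common_line_direction",
    "factor_pure",
    "pure_block",
    "pure_matrix",
    "random_rotations",
    "validate_rotation",
]

#: 2x3 projector-rotator: Jt @ R keeps (-row2, +row1) of R.
JTILDE = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0]])

_E3 = np.array([0.0, 0.0, 1.0])

#: Two viewing axes closer than this (in |sin|) are treated as parallel.
DEGENERATE_TOL = 1e-10


class DegeneratePairError(ValueError):
    """The two viewing directions are parallel: no unique common line."""


def validate_rotation(m: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Check that ``m`` is a 3x3 special-orthogonal matrix.

    Returns the validated array (as float ndarray); raises ``ValueError``
    if orthogonality or det(m)=+1 fail beyond ``tol``.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {m.shape}")
    if not np.allclose(m @ m.T, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthogonal")
    if abs(np.linalg.det(m) - 1.0) > max(tol, 1e-9):
        raise ValueError("matrix determinant is not +1")
    return m


class CommonLinesMatrix:
    """A 2n x n real matrix of stacked 2x1 common-line representatives.

    Block ``(i, j)`` occupies rows ``2i, 2i+1`` (0-based) of column ``j``
    and holds a representative for the common line of images ``i`` and
    ``j``; diagonal blocks are identically zero.
    """

    def __init__(self, data: np.ndarray, *, check: bool = True):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[0] != 2 * data.shape[1]:
            raise ValueError(f"expected a 2n x n matrix, got shape {data.shape}")
        self.data = data
        self.n = data.shape[1]
        if check:
            for i in range(self.n):
                if np.any(self.data[2 * i : 2 * i + 2, i] != 0.0):
                    raise ValueError(f"diagonal block ({i},{i}) is not zero")

    def block(self, i: int, j: int) -> np.ndarray:
        """The 2-vector representative ``a_ij``."""
        return self.data[2 * i : 2 * i + 2, j]

    def set_block(self, i: int, j: int, value: np.ndarray) -> None:
        self.data[2 * i : 2 * i + 2, j] = value

    def blocks(self) -> np.ndarray:
        """All blocks as an (n, n, 2) array, ``out[i, j] = a_ij``."""
        return self.data.reshape(self.n, 2, self.n).transpose(0, 2, 1)

    @classmethod
    def from_blocks(cls, blocks: np.ndarray, *, check: bool = True) -> "CommonLinesMatrix":
        blocks = np.asarray(blocks, dtype=float)
        n = blocks.shape[0]
        data = blocks.transpose(0, 2, 1).reshape(2 * n, n)
        return cls(data, check=check)

    def copy(self) -> "CommonLinesMatrix":
        return CommonLinesMatrix(self.data.copy(), check=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CommonLinesMatrix(n={self.n})"


@dataclass
class RankFactors:
    """Rank-3 factors of a pure common-lines matrix: ``A = B @ C``."""

    B: np.ndarray  # 2n x 3, stacked 2x3 blocks Jt R_i
    C: np.ndarray  # 3 x n, columns R_j^T e3 (third rows of R_j)

    @property
    def matrix(self) -> np.ndarray:
        return self.B @ self.C


def random_rotations(n: int, seed: int) -> list[np.ndarray]:
    """Draw ``n`` rotations from the Haar (uniform) distribution on SO(3).

    Sampling goes through unit quaternions, which is bias-free (unlike
    uniform Euler angles); reproducible for a given ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    mats = _ScipyRotation.from_quat(quats).as_matrix()
    return [mats[i] for i in range(n)]


def common_line_direction(Ri: np.ndarray, Rj: np.ndarray) -> np.ndarray:
    """Direction of the common 3-D line of images ``i`` and ``j``.

    Returns ``r_i x r_j`` (third rows of the rotations), unnormalized:
    its length is |sin| of the angle between the two viewing axes.
    """
    ri = np.asarray(Ri, dtype=float)[2]
    rj = np.asarray(Rj, dtype=float)[2]
    d = np.cross(ri, rj)
    if np.linalg.norm(d) < DEGENERATE_TOL:
        raise DegeneratePairError(
            "viewing axes are parallel; the common line is undefined"
        )
    return d


def pure_block(Ri: np.ndarray, Rj: np.ndarray) -> np.ndarray:
    """Canonical representative ``a_ij = Jt R_i R_j^T e3``.

    Equals the first two coordinates of ``R_i (r_i x r_j)``; the third
    coordinate vanishes identically.  Raises on parallel viewing axes.
    """
    common_line_direction(Ri, Rj)  # degenerate-pair check
    return JTILDE @ (np.asarray(Ri, dtype=float) @ np.asarray(Rj, dtype=float).T) @ _E3


def pure_matrix(rots: list[np.ndarray]) -> CommonLinesMatrix:
    """Pure common-lines matrix of an n-tuple of rotations.

    Block ``(i, j)`` is ``pure_block(R_i, R_j)`` for ``i != j``, zero on the
    diagonal.  For generic rotations the result has rank exactly 3.
    """
    n = len(rots)
    if n < 2:
        raise ValueError("need at least 2 rotations")
    mats = np.asarray(rots, dtype=float)
    # a_ij = Jt R_i R_j^T e3; R_j^T e3 is the third row r_j.
    third_rows = mats[:, 2, :]  # n x 3
    blocks = np.einsum("ab,ibc,jc->ija", JTILDE, mats, third_rows)
    sin2 = 1.0 - (third_rows @ third_rows.T) ** 2
    for i in range(n):
        blocks[i, i] = 0.0
        for j in range(i + 1, n):
            if sin2[i, j] < DEGENERATE_TOL**2:
                raise DegeneratePairError(
                    f"rotations ({i},{j}) share a viewing axis; common line undefined"
                )
    return CommonLinesMatrix.from_blocks(blocks, check=False)


def factor_pure(rots: list[np.ndarray]) -> RankFactors:
    """Explicit rank-3 factorization ``A = B C`` of the pure matrix.

    ``B_i = Jt R_i`` (rows are an orthonormal pair), ``c_j = R_j^T e3``.
    """
    if len(rots) < 2:
        raise ValueError("need at least 2 rotations")
    mats = np.asarray(rots, dtype=float)
    B = (JTILDE[None] @ mats).reshape(2 * len(rots), 3)
    C = mats[:, 2, :].T
    return RankFactors(B=B, C=C)


def assemble_matrix(blocks: dict[tuple[int, int], np.ndarray], n: int) -> CommonLinesMatrix:
    """Assemble a common-lines matrix from per-pair representatives.

    ``blocks`` must contain an entry for every ordered pair ``(i, j)`` with
    ``i != j``; diagonal blocks are filled with zeros.
    """
    out = np.zeros((n, n, 2))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (i, j) not in blocks:
                raise ValueError(f"missing block ({i},{j})")
            out[i, j] = np.asarray(blocks[(i, j)], dtype=float)
    return CommonLinesMatrix.from_blocks(out, check=False)
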