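import numpy as np
import pytest

from commonlines import pure_matrix, random_rotations


def rot_x90():
    return np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])


def rot_y90():
    return np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])


@pytest.fixture
def fixture_rotations():
    """The I / rot_x(90) / rot_y(90) triple with known pure blocks."""
    return [np.eye(3), rot_x90(), rot_y90()]


@pytest.fixture
def fixture_pure(fixture_rotations):
    return pure_matrix(fixture_rotations)


@pytest.fixture
def haar_pure():
    """Generic pure matrix from Haar rotations, n=6."""
    return pure_matrix(random_rotations(6, 42))


def corr(A, B):
    """Normalized absolute correlation of two matrices."""
    a = A.data if hasattr(A, "data") else A
    b = B.data if hasattr(B, "data") else B
    return abs(float(np.sum(a * b))) / (np.linalg.norm(a) * np.linalg.norm(b))


def rowflip_corr(A, B):
    """Correlation after optimal per-block-row sign alignment.

    Flipping a block-row of a pure matrix yields the pure matrix of the
    rotations with R_i replaced by diag(-1,-1,1) R_i, so the row-sign
    gauge is unidentifiable from scale-corrupted data; this metric
    quotients exactly that orbit.
    """
    a = A.data if hasattr(A, "data") else A
    b = B.data if hasattr(B, "data") else B
    n = a.shape[1]
    num = sum(abs(float(np.sum(a[2 * i : 2 * i + 2] * b[2 * i : 2 * i + 2]))) for i in range(n))
    return num / (np.linalg.norm(a) * np.linalg.norm(b))
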