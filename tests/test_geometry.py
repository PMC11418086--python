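import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commonlines import (
    CommonLinesMatrix,
    assemble_matrix,
    common_line_direction,
    factor_pure,
    pure_block,
    pure_matrix,
    random_rotations,
)
from commonlines.geometry import DegeneratePairError, validate_rotation


class TestRandomRotations:
    def test_rotation_invariants(self):
        for R in random_rotations(5, 0):
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert abs(np.linalg.det(R) - 1.0) < 1e-12

    def test_deterministic_per_seed(self):
        a = random_rotations(5, 0)
        b = random_rotations(5, 0)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        c = random_rotations(5, 1)
        assert not np.allclose(a[0], c[0])

    def test_haar_trace_expectation(self):
        # E[tr R] = 0 under the Haar measure on SO(3): the standard
        # 3-dim representation contains no trivial component (angle
        # density (1-cos)/pi gives E[1 + 2 cos] = 0)
        traces = [np.trace(R) for R in random_rotations(10000, 1)]
        assert abs(np.mean(traces)) < 0.05

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            random_rotations(0, 0)


class TestCommonLineDirection:
    def test_identical_rotations_degenerate(self):
        with pytest.raises(DegeneratePairError):
            common_line_direction(np.eye(3), np.eye(3))

    def test_cross_product_oracle(self, fixture_rotations):
        I, Rx, _ = fixture_rotations
        d = common_line_direction(I, Rx)
        assert np.allclose(d, np.cross([0, 0, 1], [0, 1, 0]))
        assert np.allclose(d, [-1, 0, 0])

    def test_symmetric_in_arguments(self):
        R1, R2 = random_rotations(2, 3)
        assert np.allclose(
            common_line_direction(R1, R2), common_line_direction(R2, R1) * -1
        ) or np.allclose(common_line_direction(R1, R2), common_line_direction(R2, R1))

    def test_norm_is_sine_of_axis_angle(self):
        R1, R2 = random_rotations(2, 5)
        d = common_line_direction(R1, R2)
        cosang = np.dot(R1[2], R2[2])
        assert np.isclose(np.linalg.norm(d), np.sqrt(1 - cosang**2), atol=1e-12)


class TestPureBlock:
    @pytest.mark.parametrize(
        "i,j,expected",
        [
            (0, 1, (-1, 0)),
            (1, 0, (1, 0)),
            (0, 2, (0, -1)),
            (2, 0, (0, 1)),
        ],
    )
    def test_fixture_blocks(self, fixture_rotations, i, j, expected):
        assert np.allclose(pure_block(fixture_rotations[i], fixture_rotations[j]), expected)

    def test_pair_norm_equality(self):
        for seed in range(5):
            Ri, Rj = random_rotations(2, seed + 10)
            assert np.isclose(
                np.linalg.norm(pure_block(Ri, Rj)),
                np.linalg.norm(pure_block(Rj, Ri)),
                atol=1e-12,
            )

    def test_projection_identity(self):
        # a_ij equals the first two coordinates of R_i (r_i x r_j)
        Ri, Rj = random_rotations(2, 8)
        d = common_line_direction(Ri, Rj)
        lifted = Ri @ d
        assert abs(lifted[2]) < 1e-12
        assert np.allclose(pure_block(Ri, Rj), lifted[:2], atol=1e-12)


class TestPureMatrix:
    def test_fixture_matrix(self, fixture_pure):
        expected = np.array(
            [
                [0, -1, 0],
                [0, 0, -1],
                [1, 0, 0],
                [0, 0, -1],
                [0, -1, 0],
                [1, 0, 0],
            ],
            dtype=float,
        )
        assert np.allclose(fixture_pure.data, expected, atol=1e-12)

    def test_rank_exactly_three(self, fixture_pure):
        assert np.linalg.matrix_rank(fixture_pure.data, tol=1e-10) == 3

    def test_zero_diagonal_blocks(self, haar_pure):
        for i in range(haar_pure.n):
            assert np.all(haar_pure.block(i, i) == 0.0)

    def test_matches_factorization(self, haar_pure):
        F = factor_pure(random_rotations(6, 42))
        assert np.allclose(haar_pure.data, F.matrix, atol=1e-12)

    @pytest.mark.parametrize("n", [3, 10, 25, 50])
    def test_factorization_identity_many_sizes(self, n):
        rots = random_rotations(n, n)
        assert np.allclose(pure_matrix(rots).data, factor_pure(rots).matrix, atol=1e-12)

    def test_right_rotation_invariance(self):
        # pure_matrix([R_i O]) = pure_matrix([R_i]): the fiber of the map
        rots = random_rotations(5, 2)
        O = random_rotations(1, 99)[0]
        A = pure_matrix(rots)
        B = pure_matrix([R @ O for R in rots])
        assert np.allclose(A.data, B.data, atol=1e-12)

    def test_degenerate_pair_raises(self):
        R = random_rotations(1, 0)[0]
        with pytest.raises(DegeneratePairError):
            pure_matrix([R, R, np.eye(3)])


class TestFactorPure:
    def test_c_columns_are_third_rows(self, fixture_rotations):
        F = factor_pure(fixture_rotations)
        assert np.allclose(F.C.T, [r[2] for r in fixture_rotations])

    def test_b_blocks_orthonormal_rows(self):
        F = factor_pure(random_rotations(7, 1))
        for i in range(7):
            Bi = F.B[2 * i : 2 * i + 2]
            assert np.allclose(Bi @ Bi.T, np.eye(2), atol=1e-12)

    def test_rank3_singular_gap(self):
        F = factor_pure(random_rotations(6, 4))
        s = np.linalg.svd(F.matrix, compute_uv=False)
        assert s[3] / s[0] < 1e-12


class TestAssembleMatrix:
    def test_round_trip(self, haar_pure):
        blocks = {
            (i, j): haar_pure.block(i, j)
            for i in range(6)
            for j in range(6)
            if i != j
        }
        assert np.allclose(assemble_matrix(blocks, 6).data, haar_pure.data)

    def test_unit_blocks_frobenius(self):
        blocks = {(i, j): np.array([1.0, 0.0]) for i in range(2) for j in range(2) if i != j}
        A = assemble_matrix(blocks, 2)
        assert A.data.shape == (4, 2)
        assert np.isclose(np.linalg.norm(A.data), np.sqrt(2))

    def test_missing_block_raises(self):
        with pytest.raises(ValueError, match="missing"):
            assemble_matrix({(0, 1): np.ones(2)}, 3)


class TestCommonLinesMatrixType:
    def test_rejects_bad_shape(self):
        with pytest.raises(ValueError):
            CommonLinesMatrix(np.zeros((5, 3)))

    def test_rejects_nonzero_diagonal(self):
        data = np.ones((6, 3))
        with pytest.raises(ValueError, match="diagonal"):
            CommonLinesMatrix(data)

    def test_blocks_view_layout(self, fixture_pure):
        blocks = fixture_pure.blocks()
        for i in range(3):
            for j in range(3):
                assert np.array_equal(blocks[i, j], fixture_pure.block(i, j))

    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=100))
    @settings(max_examples=20, deadline=None)
    def test_from_blocks_round_trip(self, n, seed):
        rng = np.random.default_rng(seed)
        blocks = rng.normal(size=(n, n, 2))
        for i in range(n):
            blocks[i, i] = 0.0
        A = CommonLinesMatrix.from_blocks(blocks)
        assert np.array_equal(A.blocks(), blocks)


def test_validate_rotation_rejects_reflection():
    m = np.diag([1.0, 1.0, -1.0])
    with pytest.raises(ValueError):
        validate_rotation(m)
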