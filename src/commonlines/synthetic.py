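"""Synthetic common-lines matrices: block-scale corruption, detection-style
angular noise and outliers, and discretely heterogeneous mixtures.

``corrupt_matrix`` emulates what a detection pipeline hands downstream:
each representative carries an unknown scale and sign, its angle is
perturbed (detection errors are line-angle errors, so noise is an
in-plane rotation that preserves the norm), and a fraction of lines are
outright misdetections replaced by random directions.

``heterogeneous_matrix`` emulates a dataset holding several distinct
molecules: within-population blocks come from a consistent pure matrix,
cross-population blocks carry no geometric information and are i.i.d.
random unit lines, and one global permutation hides the populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .denoise import normalize_blocks
from .geometry import CommonLinesMatrix, pure_matrix

__all__ = ["NoiseSpec", "corrupt_matrix", "heterogeneous_matrix", "unit_normalize"]


@dataclass
class NoiseSpec:
    """Corruption model for measured common-lines matrices.

    scale_low, scale_high : range of |tau| for the per-block scales.
    sign_flip_prob : probability of flipping a block's sign.
    angle_sigma_deg : std dev of in-plane angular noise, degrees.
    outlier_frac : fraction of blocks replaced by random directions.

    The default is the identity corruption; each experiment opts into
    the corruption dimensions it studies (e.g. ``scaled(seed)`` for the
    scale-recovery conditions, ``angle_sigma_deg=2`` for detection-style
    angular noise).
    """

    scale_low: float = 1.0
    scale_high: float = 1.0
    sign_flip_prob: float = 0.0
    angle_sigma_deg: float = 0.0
    outlier_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.scale_low <= self.scale_high):
            raise ValueError("need 0 < scale_low <= scale_high")
        for p in (self.sign_flip_prob, self.outlier_frac):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.angle_sigma_deg < 0:
            raise ValueError("angle_sigma_deg must be >= 0")

    @classmethod
    def neutral(cls, seed: int = 0) -> "NoiseSpec":
        """Identity corruption: scales 1, no flips, no noise, no outliers."""
        return cls(seed=seed)

    @classmethod
    def scaled(cls, seed: int = 0, signs: bool = True) -> "NoiseSpec":
        """Arbitrary per-block scales in [0.5, 2], optionally signed."""
        return cls(
            scale_low=0.5,
            scale_high=2.0,
            sign_flip_prob=0.5 if signs else 0.0,
            seed=seed,
        )


def _rotate_blocks(blocks: np.ndarray, angles_rad: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles_rad), np.sin(angles_rad)
    x, y = blocks[..., 0], blocks[..., 1]
    return np.stack([c * x - s * y, s * x + c * y], axis=-1)


def corrupt_matrix(A_pure: CommonLinesMatrix, spec: NoiseSpec) -> CommonLinesMatrix:
    """Apply per-block scales/signs, angular noise and outliers to a matrix."""
    rng = np.random.default_rng(spec.seed)
    n = A_pure.n
    blocks = A_pure.blocks().copy()
    off = ~np.eye(n, dtype=bool)

    tau = rng.uniform(spec.scale_low, spec.scale_high, size=(n, n))
    flips = rng.random(size=(n, n)) < spec.sign_flip_prob
    tau[flips] *= -1.0
    angles = np.deg2rad(rng.normal(0.0, spec.angle_sigma_deg, size=(n, n)))
    outliers = rng.random(size=(n, n)) < spec.outlier_frac
    out_theta = rng.uniform(0.0, 2 * np.pi, size=(n, n))

    if spec.angle_sigma_deg > 0:
        blocks = _rotate_blocks(blocks, angles)
    if spec.outlier_frac > 0:
        norms = np.linalg.norm(blocks, axis=2)
        repl = norms[..., None] * np.stack(
            [np.cos(out_theta), np.sin(out_theta)], axis=-1
        )
        blocks = np.where(outliers[..., None], repl, blocks)
    blocks[off] *= tau[off, None]
    blocks[~off] = 0.0
    return CommonLinesMatrix.from_blocks(blocks, check=False)


def heterogeneous_matrix(
    rotation_sets: list[list[np.ndarray]], spec: NoiseSpec
) -> tuple[CommonLinesMatrix, np.ndarray]:
    """Mixture matrix for several molecules plus ground-truth labels.

    Within-population blocks are the (corrupted) pure common lines of
    that population's rotations; cross-population blocks are i.i.d.
    uniform unit 2-vectors; a single random permutation is applied
    consistently to block-rows and columns.
    """
    if len(rotation_sets) < 1:
        raise ValueError("need at least one population")
    sizes = [len(rs) for rs in rotation_sets]
    if min(sizes) < 3:
        raise ValueError("each population needs at least 3 rotations")
    n = sum(sizes)
    rng = np.random.default_rng(spec.seed)

    theta = rng.uniform(0.0, 2 * np.pi, size=(n, n))
    blocks = np.stack([np.cos(theta), np.sin(theta)], axis=-1)

    labels = np.empty(n, dtype=int)
    start = 0
    for p, rots in enumerate(rotation_sets):
        m = len(rots)
        sub_spec = NoiseSpec(
            scale_low=spec.scale_low,
            scale_high=spec.scale_high,
            sign_flip_prob=spec.sign_flip_prob,
            angle_sigma_deg=spec.angle_sigma_deg,
            outlier_frac=spec.outlier_frac,
            seed=int(rng.integers(2**31)),
        )
        sub = corrupt_matrix(pure_matrix(rots), sub_spec)
        blocks[start : start + m, start : start + m] = sub.blocks()
        labels[start : start + m] = p
        start += m

    perm = rng.permutation(n)
    blocks = blocks[np.ix_(perm, perm)]
    labels = labels[perm]
    for i in range(n):
        blocks[i, i] = 0.0
    return CommonLinesMatrix.from_blocks(blocks, check=False), labels


def unit_normalize(A: CommonLinesMatrix) -> CommonLinesMatrix:
    """Rescale all off-diagonal blocks to unit norm (detection emulation)."""
    return normalize_blocks(A)
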