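"""Evaluation metrics: Procrustes rotation error, denoising error, ARI.

Recovered rotations are only defined up to one global right rotation, so
rotation accuracy is measured after solving the orthogonal Procrustes
problem  min_{O in SO(3)} sum_i ||R_i O - Rhat_i||_F^2 .  Per-image
errors convert to angles through  ||R - Rhat||_F^2 = 4 (1 - cos theta).
Recovered pure common-lines matrices carry a global scale (and sign)
ambiguity, measured away by a closed-form least-squares scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .geometry import CommonLinesMatrix

__all__ = [
    "ProcrustesResult",
    "adjusted_rand_index",
    "angular_error",
    "denoising_error",
    "procrustes_align",
]


@dataclass
class ProcrustesResult:
    O: np.ndarray  # aligning rotation
    total_error: float  # sum of squared per-image Frobenius errors
    per_image_error: np.ndarray  # squared Frobenius errors
    per_image_angle_deg: np.ndarray

    @property
    def mean_error(self) -> float:
        """Procrustes error divided by the number of images."""
        return self.total_error / len(self.per_image_error)


def angular_error(Ri: np.ndarray, Rhat: np.ndarray) -> float:
    """Rotation angle (degrees) of ``Ri^T Rhat``."""
    c = (np.trace(np.asarray(Ri).T @ np.asarray(Rhat)) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def procrustes_align(
    truth: list[np.ndarray], estimate: list[np.ndarray]
) -> ProcrustesResult:
    """Optimal global right rotation aligning ``truth`` onto ``estimate``."""
    if len(truth) != len(estimate):
        raise ValueError("rotation lists must have equal length")
    if len(truth) == 0:
        raise ValueError("need at least one rotation")
    M = sum(np.asarray(R).T @ np.asarray(Rh) for R, Rh in zip(truth, estimate))
    U, _, Vt = np.linalg.svd(M)
    O = U @ Vt
    if np.linalg.det(O) < 0:
        O = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    per = np.array(
        [
            np.sum((np.asarray(R) @ O - np.asarray(Rh)) ** 2)
            for R, Rh in zip(truth, estimate)
        ]
    )
    angles = np.array(
        [angular_error(np.asarray(R) @ O, Rh) for R, Rh in zip(truth, estimate)]
    )
    return ProcrustesResult(
        O=O,
        total_error=float(per.sum()),
        per_image_error=per,
        per_image_angle_deg=angles,
    )


def denoising_error(
    Ahat: CommonLinesMatrix | np.ndarray, Atruth: CommonLinesMatrix | np.ndarray
) -> float:
    """Scale-invariant relative error min_s ||Ahat - s Atruth||_F / ||Atruth||_F."""
    X = Ahat.data if isinstance(Ahat, CommonLinesMatrix) else np.asarray(Ahat)
    A = Atruth.data if isinstance(Atruth, CommonLinesMatrix) else np.asarray(Atruth)
    if X.shape != A.shape:
        raise ValueError("shape mismatch")
    denom = np.linalg.norm(A)
    if denom == 0.0:
        raise ValueError("truth matrix is zero")
    s = float(np.sum(X * A)) / denom**2
    return float(np.linalg.norm(X - s * A) / denom)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement; 1 iff identical up to relabeling."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))
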