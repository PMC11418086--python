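"""Phantom projections and correlation-based common-line detection.

A molecule is emulated as a sum of isotropic 3-D Gaussian blobs in
generic position (no point-group symmetry).  Its tomographic projection
at rotation ``R`` is available in closed form: each blob projects to a
2-D Gaussian centered at the first two coordinates of ``R c``, with mass
``amplitude * sigma * sqrt(2 pi)``.  By the Fourier slice theorem, the
2-D transforms of two projections agree along their common line, so the
line is detected by sampling both transforms along central rays
(cubic-spline interpolation on the FFT grid) and maximizing the
normalized real correlation over all ray pairs and both relative
orientations.

Image arrays are indexed ``[x, y]`` so that detected ray angles live in
the same planar coordinates as the common-line representatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import CommonLinesMatrix, pure_block

__all__ = [
    "DetectionParams",
    "DetectionResult",
    "Phantom",
    "ProjectionImage",
    "add_noise_snr",
    "detect_common_line",
    "detected_matrix",
    "fourier_line_profiles",
    "project_phantom",
    "random_phantom",
]


@dataclass
class Phantom:
    """Sum of isotropic Gaussian blobs; units are pixels."""

    centers: np.ndarray  # (k, 3)
    amplitudes: np.ndarray  # (k,)
    widths: np.ndarray  # (k,) Gaussian sigmas

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if np.any(self.amplitudes <= 0) or np.any(self.widths <= 0):
            raise ValueError("amplitudes and widths must be positive")


@dataclass
class ProjectionImage:
    pixels: np.ndarray  # (L, L), indexed [x, y]
    pixel_size: float  # Angstrom
    rotation: np.ndarray | None = None


@dataclass
class DetectionParams:
    n_theta: int = 180
    r_min: float = 3.0
    r_max: float | None = None  # default L/2 - 2
    window: bool = True


@dataclass
class DetectionResult:
    theta_i: float  # degrees in [0, 180)
    theta_j: float
    correlation: float
    rep_i: np.ndarray  # unit 2-vector
    rep_j: np.ndarray


def random_phantom(
    seed: int, n_blobs: int = 8, L: int = 64
) -> Phantom:
    """Generic asymmetric phantom: blob centers uniform in a half-radius ball."""
    if n_blobs < 5:
        raise ValueError("need at least 5 blobs for generic asymmetry")
    rng = np.random.default_rng(seed)
    radius = L / 4.0
    centers = []
    while len(centers) < n_blobs:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) <= radius:
            centers.append(p)
    return Phantom(
        centers=np.array(centers),
        amplitudes=rng.uniform(0.5, 1.5, size=n_blobs),
        widths=rng.uniform(2.0, 4.0, size=n_blobs),
    )


def project_phantom(
    ph: Phantom, R: np.ndarray, L: int = 64, pixel_size: float = 3.0
) -> ProjectionImage:
    """Analytic tomographic projection of the phantom at rotation ``R``."""
    if L < 16:
        raise ValueError("grid too small; need L >= 16")
    R = np.asarray(R, dtype=float)
    coords = np.arange(L) - L // 2
    x = coords[:, None]
    y = coords[None, :]
    img = np.zeros((L, L))
    proj_centers = ph.centers @ R.T  # rows R c_k
    for (px, py, _), amp, sig in zip(proj_centers, ph.amplitudes, ph.widths):
        img += (
            amp
            * sig
            * np.sqrt(2 * np.pi)
            * np.exp(-((x - px) ** 2 + (y - py) ** 2) / (2 * sig**2))
        )
    return ProjectionImage(pixels=img, pixel_size=pixel_size, rotation=R)


def add_noise_snr(img: ProjectionImage, snr: float, seed: int) -> ProjectionImage:
    """Add white Gaussian noise with variance mean(clean^2) / snr."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    var = float(np.mean(img.pixels**2)) / snr
    noisy = img.pixels + rng.normal(0.0, np.sqrt(var), size=img.pixels.shape)
    return ProjectionImage(pixels=noisy, pixel_size=img.pixel_size, rotation=img.rotation)


def _radial_window(L: int, inner: float = 0.75) -> np.ndarray:
    """Raised-cosine edge taper in real space."""
    coords = np.arange(L) - L // 2
    r = np.hypot(coords[:, None], coords[None, :]) / (L / 2)
    w = np.ones((L, L))
    band = (r > inner) & (r < 1.0)
    w[band] = 0.5 * (1 + np.cos(np.pi * (r[band] - inner) / (1 - inner)))
    w[r >= 1.0] = 0.0
    return w


def fourier_line_profiles(
    img: ProjectionImage, n_theta: int = 180, r_band: tuple[float, float] | None = None
) -> np.ndarray:
    """Complex profiles along central rays of the 2-D Fourier transform.

    Returns an (n_theta, n_r) complex array; ray ``t`` has angle
    ``t * 180 / n_theta`` degrees, radial samples run over integer
    frequency pixels in ``r_band`` (DC excluded by ``r_min > 0``).
    """
    if n_theta < 36:
        raise ValueError("need n_theta >= 36")
    L = img.pixels.shape[0]
    if r_band is None:
        r_band = (3.0, L / 2 - 2.0)
    rmin, rmax = r_band
    if not (0 < rmin < rmax <= L / 2):
        raise ValueError("need 0 < rmin < rmax <= Nyquist")
    pix = img.pixels * _radial_window(L)
    # centered DFT: without ifftshift the half-grid offset adds a
    # (-1)^(k+l) phase in each image's own frame and breaks the
    # common-line equality between images
    F = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(pix)))
    c = L // 2
    radii = np.arange(np.ceil(rmin), np.floor(rmax) + 1)
    thetas = np.arange(n_theta) * np.pi / n_theta
    # image axis0 = x, axis1 = y -> frequency coords likewise
    fx = c + radii[None, :] * np.cos(thetas)[:, None]
    fy = c + radii[None, :] * np.sin(thetas)[:, None]
    coords = np.stack([fx.ravel(), fy.ravel()])
    # cubic spline: bilinear interpolation of the oscillatory complex
    # field costs degrees of angular accuracy on the argmax
    re = map_coordinates(F.real, coords, order=3, mode="constant")
    im = map_coordinates(F.imag, coords, order=3, mode="constant")
    return (re + 1j * im).reshape(n_theta, len(radii))


def detect_common_line(
    pi: ProjectionImage, pj: ProjectionImage, params: DetectionParams | None = None
) -> DetectionResult:
    """Best-correlating ray pair between two projection images.

    Both relative ray orientations are tried (the ray at theta + 180 deg
    is the complex conjugate of the ray at theta for a real image); the
    winning orientation is encoded in the sign of ``rep_j``.
    """
    if params is None:
        params = DetectionParams()
    if pi.pixels.shape != pj.pixels.shape:
        raise ValueError("images must share a grid")
    if not np.any(pi.pixels) or not np.any(pj.pixels):
        raise ValueError("detection undefined for an all-zero image")
    L = pi.pixels.shape[0]
    r_max = params.r_max if params.r_max is not None else L / 2 - 2
    band = (params.r_min, r_max)
    Pi = fourier_line_profiles(pi, params.n_theta, band)
    Pj = fourier_line_profiles(pj, params.n_theta, band)
    Pi = Pi / np.linalg.norm(Pi, axis=1, keepdims=True)
    Pj = Pj / np.linalg.norm(Pj, axis=1, keepdims=True)
    C_same = np.real(Pi @ Pj.conj().T)
    C_flip = np.real(Pi @ Pj.T)  # ray j reversed (conjugate profile)
    flip = C_flip.max() > C_same.max()
    C = C_flip if flip else C_same
    ti, tj = np.unravel_index(np.argmax(C), C.shape)
    step = 180.0 / params.n_theta
    theta_i, theta_j = ti * step, tj * step
    rep_i = np.array([np.cos(np.deg2rad(theta_i)), np.sin(np.deg2rad(theta_i))])
    rep_j = np.array([np.cos(np.deg2rad(theta_j)), np.sin(np.deg2rad(theta_j))])
    if flip:
        rep_j = -rep_j
    return DetectionResult(
        theta_i=theta_i,
        theta_j=theta_j,
        correlation=float(C[ti, tj]),
        rep_i=rep_i,
        rep_j=rep_j,
    )


def detected_matrix(
    images: list[ProjectionImage], params: DetectionParams | None = None
) -> CommonLinesMatrix:
    """Common-lines matrix of unit representatives from pairwise detection."""
    n = len(images)
    if n < 3:
        raise ValueError("need at least 3 images")
    blocks = np.zeros((n, n, 2))
    for i in range(n):
        for j in range(i + 1, n):
            det = detect_common_line(images[i], images[j], params)
            blocks[i, j] = det.rep_i
            blocks[j, i] = det.rep_j
    return CommonLinesMatrix.from_blocks(blocks, check=False)


def ground_truth_angles(Ri: np.ndarray, Rj: np.ndarray) -> tuple[float, float]:
    """Common-line angles (degrees, in [0, 180)) from the true rotations."""
    ai = pure_block(Ri, Rj)
    aj = pure_block(Rj, Ri)
    ti = np.degrees(np.arctan2(ai[1], ai[0])) % 180.0
    tj = np.degrees(np.arctan2(aj[1], aj[0])) % 180.0
    return float(ti), float(tj)
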