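"""Subpixel rigid registration by upsampled DFT cross-correlation, with an
exhaustive in-plane rotation search and the template-free iterative
averaging loop.

Alignment metric
----------------
A moving image *g* is registered to a reference *f* by minimizing the
normalized root-mean-square error

    E² = min over (α, x0, y0, θ)  Σ |α·g_θ(x−x0, y−y0) − f(x, y)|² / Σ |f|²

which, at the optimal intensity scaling α, is equivalent to maximizing the
cross-correlation r_fg(x0, y0, θ) evaluated in the Fourier domain.  The
translation search first locates the integer-pixel correlation peak with an
FFT, then refines it on a ±1.5-pixel neighborhood sampled at 1/upsample
pixel by a matrix-multiply DFT (default 1/100 pixel).  Rotation is searched
exhaustively on a grid (default 0–359° in 1° steps); the angular resolution
stays at the grid step.

Conventions
-----------
``theta`` is the in-plane rotation (degrees, matrix [[cos,−sin],[sin,cos]]
on (x, y) = (col, row)) that must be applied to the *moving* image, about
the raster center, followed by ``shift`` (pixels, (dx, dy) = (col, row)),
to match the reference.  Ties between equal correlation peaks break toward
the smallest angle, then the lexicographically smallest signed shift.

Before the FFT, images are mean-subtracted and tapered with a radial
raised-cosine window over the outer fraction of the inscribed circle
(default 5%) to suppress wrap-around artifacts; pass ``window=False`` to
disable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .molecules import PixelImage, StructureTransform, rot2

logger = logging.getLogger(__name__)

__all__ = [
    "RegistrationResult",
    "AlignmentRun",
    "preprocess",
    "rotate_raster",
    "fourier_shift_raster",
    "dft_translation_register",
    "rotation_translation_register",
    "nrmse",
    "iterative_align",
]


@dataclass(frozen=True)
class RegistrationResult:
    """Optimal rigid registration of one moving image to a reference."""

    theta: float  # degrees in [0, 360)
    shift: tuple[float, float]  # (dx, dy) pixels, continuous
    peak_correlation: float
    nrmse: float
    alpha: float

    def to_nm(self, pixel_size: float) -> StructureTransform:
        """Express as a coordinate-domain transform (rotation about the nm
        origin, which coincides with the raster center)."""
        return StructureTransform(
            theta=self.theta,
            shift=(self.shift[0] * pixel_size, self.shift[1] * pixel_size),
        )


@dataclass
class AlignmentRun:
    """History of the iterative template-free averaging loop."""

    history: list  # per iteration: list[RegistrationResult] per image
    references: list  # per iteration: reference raster (np.ndarray)
    mean_nrmse: list
    n_iterations: int
    converged: bool
    pixel_size: float

    @property
    def final_transforms(self) -> list:
        return self.history[-1]

    def final_average(self, images: list) -> np.ndarray:
        """Average of the input rasters aligned by the final transforms."""
        return np.mean(
            [_apply_result(img.values, r) for img, r in zip(images, self.final_transforms)],
            axis=0,
        )


# ---------------------------------------------------------------------------
# Raster helpers
# ---------------------------------------------------------------------------

def _as_array(img) -> np.ndarray:
    return img.values if isinstance(img, PixelImage) else np.asarray(img, dtype=float)


def radial_window(shape: tuple[int, int], taper: float = 0.05) -> np.ndarray:
    """Radial raised-cosine window: 1 inside (1−taper)·Rmax, cosine rolloff
    to 0 at Rmax = half the smaller image dimension."""
    m, n = shape
    rr = np.arange(m) - (m - 1) / 2.0
    cc = np.arange(n) - (n - 1) / 2.0
    rho = np.hypot(rr[:, None], cc[None, :])
    rmax = min(m, n) / 2.0 - 0.5
    r0 = rmax * (1.0 - taper)
    w = np.ones(shape)
    edge = (rho > r0) & (rho <= rmax)
    w[edge] = 0.5 * (1.0 + np.cos(np.pi * (rho[edge] - r0) / (rmax - r0)))
    w[rho > rmax] = 0.0
    return w


def preprocess(img, window: bool = True, taper: float = 0.05) -> np.ndarray:
    """Mean-subtract and (optionally) radially taper an image before FFT."""
    arr = _as_array(img)
    if not np.any(arr):
        raise ValueError("zero image cannot be registered")
    out = arr - arr.mean()
    if window:
        out = out * radial_window(arr.shape, taper)
    return out


def rotate_raster(img: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotate raster content by ``theta_deg`` about the continuous raster
    center, in the same sense as rotating the underlying (x, y) = (col, row)
    coordinates by the matrix [[cos,−sin],[sin,cos]].  Bilinear, zero fill."""
    if theta_deg % 360.0 == 0.0:
        return np.array(img, dtype=float, copy=True)
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    # output(p) = input(R_{-theta} p); in (row, col) order R_{-theta} is
    # [[c, -s], [s, c]] (row ~ y, col ~ x)
    A = np.array([[c, -s], [s, c]])
    m, n = img.shape
    ctr = np.array([(m - 1) / 2.0, (n - 1) / 2.0])
    offset = ctr - A @ ctr
    return ndimage.affine_transform(
        np.asarray(img, dtype=float), A, offset=offset, order=1,
        mode="constant", cval=0.0, prefilter=False,
    )


def fourier_shift_raster(img: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Shift raster content by (dx, dy) pixels via the Fourier phase ramp."""
    dx, dy = shift
    if dx == 0.0 and dy == 0.0:
        return np.array(img, dtype=float, copy=True)
    f = np.fft.fft2(img)
    m, n = img.shape
    fy = np.fft.fftfreq(m)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    f = f * np.exp(-2j * np.pi * (fy * dy + fx * dx))
    return np.real(np.fft.ifft2(f))


def _apply_result(img: np.ndarray, r: RegistrationResult) -> np.ndarray:
    """Apply (rotate by theta, then shift) to a raster."""
    return fourier_shift_raster(rotate_raster(img, r.theta), r.shift)


# ---------------------------------------------------------------------------
# Translation registration
# ---------------------------------------------------------------------------

def _wrap_peak(idx: tuple[int, int], shape: tuple[int, int]) -> tuple[int, int]:
    """Convert an argmax index of the circular correlation into a signed
    integer shift (dy, dx)."""
    m, n = shape
    dy, dx = idx
    if dy > m // 2:
        dy -= m
    if dx > n // 2:
        dx -= n
    return dy, dx


def _upsampled_cc(product: np.ndarray, coarse: tuple[int, int],
                  upsample: int, halfwidth: float = 1.5) -> tuple[tuple[float, float], float]:
    """Evaluate the cross-correlation on a (2·halfwidth)-pixel neighborhood
    of the coarse peak at 1/upsample pixel spacing by matrix-multiply DFT.

    ``product`` is F·conj(G).  Returns the refined (dy, dx) and the peak
    correlation value (same normalization as ifft2 of the product).
    """
    m, n = product.shape
    nsteps = int(np.ceil(halfwidth * upsample))
    offsets = np.arange(-nsteps, nsteps + 1) / upsample
    fy = np.fft.fftfreq(m)
    fx = np.fft.fftfreq(n)
    dys = coarse[0] + offsets
    dxs = coarse[1] + offsets
    ky = np.exp(2j * np.pi * dys[:, None] * fy[None, :])
    kx = np.exp(2j * np.pi * dxs[:, None] * fx[None, :])
    cc = np.real(ky @ product @ kx.T) / (m * n)
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
    return (float(dys[iy]), float(dxs[ix])), float(cc[iy, ix])


def _coarse_peak(cc: np.ndarray) -> tuple[tuple[int, int], float]:
    idx = np.unravel_index(np.argmax(cc), cc.shape)
    return _wrap_peak(idx, cc.shape), float(cc[idx])


def _result_from_cc(
    f_pre: np.ndarray,
    g_pre: np.ndarray,
    product: np.ndarray,
    cc: np.ndarray,
    upsample: int,
    theta: float = 0.0,
) -> RegistrationResult:
    (dy, dx), peak = _coarse_peak(cc)
    if upsample > 1:
        (dy, dx), peak = _upsampled_cc(product, (dy, dx), upsample)
    sum_f2 = float(np.sum(f_pre**2))
    sum_g2 = float(np.sum(g_pre**2))
    err = float(np.sqrt(max(0.0, 1.0 - peak**2 / (sum_f2 * sum_g2))))
    return RegistrationResult(
        theta=float(theta) % 360.0,
        shift=(float(dx), float(dy)),
        peak_correlation=peak,
        nrmse=err,
        alpha=peak / sum_g2 if sum_g2 > 0 else 0.0,
    )


def _check_pair(moving, reference) -> tuple[np.ndarray, np.ndarray]:
    mv, rf = _as_array(moving), _as_array(reference)
    if mv.shape != rf.shape:
        raise ValueError(f"image dimensions differ: {mv.shape} vs {rf.shape}")
    if isinstance(moving, PixelImage) and isinstance(reference, PixelImage):
        if moving.pixel_size != reference.pixel_size:
            raise ValueError("pixel sizes differ")
    return mv, rf


def dft_translation_register(
    moving, reference, upsample: int = 100, window: bool = False
) -> RegistrationResult:
    """Register a pure translation between two images.

    Coarse integer-pixel estimate from the FFT cross-correlation peak,
    refined to 1/upsample pixel on a ±1.5-pixel neighborhood by
    matrix-multiply DFT.  ``theta`` is 0 in the result.

    Translation-only registration follows the classic upsampled-DFT scheme
    without edge tapering (a taper fixed to the raster biases the estimate
    of a moving pattern by ~0.01 px); the rotation search and the iterative
    loop, where wrap-around under rotation matters, taper by default.
    """
    if upsample < 1 or int(upsample) != upsample:
        raise ValueError("upsample must be a positive integer")
    mv, rf = _check_pair(moving, reference)
    f_pre = preprocess(rf, window=window)
    g_pre = preprocess(mv, window=window)
    F = np.fft.fft2(f_pre)
    G = np.fft.fft2(g_pre)
    product = F * np.conj(G)
    cc = np.real(np.fft.ifft2(product))
    return _result_from_cc(f_pre, g_pre, product, cc, int(upsample))


# ---------------------------------------------------------------------------
# Rotation + translation registration
# ---------------------------------------------------------------------------

def _angle_grid(angle_step: float) -> np.ndarray:
    n = 360.0 / angle_step
    if abs(n - round(n)) > 1e-9:
        raise ValueError("angle_step must divide 360")
    return np.arange(int(round(n))) * float(angle_step)


def rotation_translation_register(
    moving, reference, angle_step: float = 1.0, upsample: int = 100,
    window: bool = True,
) -> RegistrationResult:
    """Exhaustive rotation search with DFT translation registration.

    For each trial angle the moving image is rotated about the raster center
    and the integer-grid correlation peak computed; the angle with the
    largest peak wins (ties toward the smallest angle, then the smallest
    signed shift), and the translation is then refined at that angle by the
    upsampled DFT.
    """
    if upsample < 1 or int(upsample) != upsample:
        raise ValueError("upsample must be a positive integer")
    mv, rf = _check_pair(moving, reference)
    f_pre = preprocess(rf, window=window)
    g_pre = preprocess(mv, window=window)
    F = np.fft.fft2(f_pre)

    best = None  # (peak, theta, (dy, dx), product, g_rot)
    for theta in _angle_grid(angle_step):
        g_rot = rotate_raster(g_pre, theta)
        product = F * np.conj(np.fft.fft2(g_rot))
        cc = np.real(np.fft.ifft2(product))
        (dy, dx), peak = _coarse_peak(cc)
        if best is None or peak > best[0]:
            best = (peak, theta, (dy, dx), product, g_rot)
    peak, theta, coarse, product, g_rot = best
    if upsample > 1:
        (dy, dx), peak = _upsampled_cc(product, coarse, int(upsample))
    else:
        dy, dx = coarse
    sum_f2 = float(np.sum(f_pre**2))
    sum_g2 = float(np.sum(g_rot**2))
    err = float(np.sqrt(max(0.0, 1.0 - peak**2 / (sum_f2 * sum_g2))))
    return RegistrationResult(
        theta=float(theta) % 360.0,
        shift=(float(dx), float(dy)),
        peak_correlation=peak,
        nrmse=err,
        alpha=peak / sum_g2 if sum_g2 > 0 else 0.0,
    )


def nrmse(f, g, t: RegistrationResult, window: bool = True) -> float:
    """Normalized RMS error between ``f`` and the transformed ``g`` with the
    intensity scaling α at its closed-form least-squares optimum."""
    garr, farr = _check_pair(g, f)
    f_pre = preprocess(farr, window=window)
    g_pre = preprocess(garr, window=window)
    g_t = _apply_result(g_pre, t)
    sum_f2 = float(np.sum(f_pre**2))
    if sum_f2 == 0:
        raise ValueError("reference image is identically zero")
    sum_g2 = float(np.sum(g_t**2))
    if sum_g2 == 0:
        return 1.0
    cross = float(np.sum(f_pre * g_t))
    return float(np.sqrt(max(0.0, (sum_f2 - cross**2 / sum_g2) / sum_f2)))


# ---------------------------------------------------------------------------
# Iterative template-free alignment
# ---------------------------------------------------------------------------

def _register_to_rotated_stack(
    M: np.ndarray,
    H: np.ndarray,
    angles: np.ndarray,
    upsample: int,
    sum_f2: float,
    sum_g2: float,
) -> RegistrationResult:
    """Register one image (FFT ``M``) against a stack of rotated-reference
    FFTs ``H[k]`` (reference rotated by −angles[k]).

    Evaluates the same objective as rotating the moving image by +angle:
    the correlation lag ``t`` found against the rotated reference maps to
    the moving-frame shift ``s = R_theta t``.
    """
    prod = H * np.conj(M)[None, :, :]
    cc = np.real(np.fft.ifft2(prod, axes=(-2, -1)))
    flat = cc.reshape(cc.shape[0], -1)
    per_angle_peak = flat.max(axis=1)
    k = int(np.argmax(per_angle_peak))  # first occurrence = smallest angle
    theta = float(angles[k])
    idx = np.unravel_index(int(np.argmax(flat[k])), cc.shape[1:])
    coarse = _wrap_peak(idx, cc.shape[1:])
    if upsample > 1:
        (dy, dx), peak = _upsampled_cc(prod[k], coarse, upsample)
    else:
        (dy, dx), peak = (float(coarse[0]), float(coarse[1])), float(per_angle_peak[k])
    sx, sy = rot2(np.deg2rad(theta)) @ np.array([dx, dy])
    err = float(np.sqrt(max(0.0, 1.0 - peak**2 / (sum_f2 * sum_g2))))
    return RegistrationResult(
        theta=theta % 360.0,
        shift=(float(sx), float(sy)),
        peak_correlation=peak,
        nrmse=err,
        alpha=peak / sum_g2 if sum_g2 > 0 else 0.0,
    )


def build_reference_stack(
    ref_pre: np.ndarray, angles: np.ndarray
) -> np.ndarray:
    """FFTs of the preprocessed reference rotated by −angle for each trial
    angle (shared across all images of an iteration)."""
    H = np.empty((angles.size, *ref_pre.shape), dtype=complex)
    for k, theta in enumerate(angles):
        H[k] = np.fft.fft2(rotate_raster(ref_pre, -theta))
    return H


def iterative_align(
    images: list,
    n_iterations: int = 10,
    angle_step: float = 1.0,
    upsample: int = 100,
    window: bool = True,
    early_stop: bool = False,
    tol_shift: float = 0.01,
) -> AlignmentRun:
    """Template-free iterative alignment of a stack of images.

    The iteration-1 reference is the unweighted average of all inputs (so no
    external template biases the result); each iteration registers every
    *original* image to the current reference, and the average of the
    aligned images becomes the next reference.  Runs ``n_iterations`` times
    (default 10); with ``early_stop`` the loop ends when no transform moved
    by more than ``tol_shift`` pixels and ``angle_step`` degrees.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 images to align")
    arrs = [_as_array(im) for im in images]
    shape = arrs[0].shape
    for i, a in enumerate(arrs):
        if a.shape != shape:
            raise ValueError(f"image {i} has shape {a.shape}, expected {shape}")
        if not np.any(a):
            raise ValueError(f"image {i} is identically zero")
    pixel_size = images[0].pixel_size if isinstance(images[0], PixelImage) else 1.0
    angles = _angle_grid(angle_step)

    pre = [preprocess(a, window=window) for a in arrs]
    M = [np.fft.fft2(p) for p in pre]
    sum_g2 = [float(np.sum(p**2)) for p in pre]

    aligned = [a.copy() for a in arrs]
    history: list[list[RegistrationResult]] = []
    references: list[np.ndarray] = []
    mean_nrmse: list[float] = []
    converged = False

    for it in range(n_iterations):
        ref = np.mean(aligned, axis=0)
        references.append(ref)
        ref_pre = preprocess(ref, window=window)
        sum_f2 = float(np.sum(ref_pre**2))
        H = build_reference_stack(ref_pre, angles)
        results = [
            _register_to_rotated_stack(M[i], H, angles, upsample, sum_f2, sum_g2[i])
            for i in range(len(arrs))
        ]
        aligned = [_apply_result(arrs[i], results[i]) for i in range(len(arrs))]
        history.append(results)
        mean_nrmse.append(float(np.mean([r.nrmse for r in results])))
        logger.info("iteration %d: mean NRMSE %.5f", it + 1, mean_nrmse[-1])
        if it > 0:
            prev = history[-2]
            dmax_shift = max(
                np.hypot(r.shift[0] - p.shift[0], r.shift[1] - p.shift[1])
                for r, p in zip(results, prev)
            )
            dmax_theta = max(
                abs((r.theta - p.theta + 180.0) % 360.0 - 180.0)
                for r, p in zip(results, prev)
            )
            if dmax_shift < tol_shift and dmax_theta < angle_step:
                converged = True
                if early_stop:
                    break
    return AlignmentRun(
        history=history,
        references=references,
        mean_nrmse=mean_nrmse,
        n_iterations=len(history),
        converged=converged,
        pixel_size=pixel_size,
    )
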