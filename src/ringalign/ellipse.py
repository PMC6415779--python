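"""Robust ellipse fitting, outlier trimming, and circularization.

Semi-flexible ring structures (e.g. ciliary distal appendages, 369–494 nm in
diameter) keep their symmetry but vary in size and shape across instances.
Before rigid alignment, each structure's localizations are fitted to an
ellipse, trimmed of outliers, and anisotropically rescaled so the fitted
ellipse maps onto a common circle of radius R (the mean radius over all
structures):

    x_circ = x / a * R,    y_circ = y / b * R

after translating the ellipse center to the origin and rotating the long
axis onto x.

Because localization data are noisy and contaminated (nonspecific binding,
mislocalizations), the default fit minimizes least *absolute* algebraic
deviations of the full conic  A x² + B xy + C y² + D x + E y + F = 0,
approximated by iteratively reweighted least squares (IRLS) around an
ellipse-constrained direct solve.  A plain least-squares fit is available
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molecules import MoleculeList, StructureTransform, rot2

__all__ = [
    "EllipseFit",
    "fit_ellipse",
    "remove_outliers",
    "circularize",
    "average_radius",
    "conic_to_geometry",
    "geometry_to_conic",
]

_IRLS_MAX_ITER = 50
_IRLS_TOL = 1e-8


@dataclass(frozen=True)
class EllipseFit:
    """Geometric ellipse parameters plus fit diagnostics for one structure.

    ``a >= b > 0``; ``phi`` (radians) is the orientation of the long axis,
    normalized to [0, pi).  ``conic`` stores the algebraic coefficients
    (A, B, C, D, E, F) consistent with the geometry to <= 1e-6 relative.
    """

    center: tuple[float, float]
    a: float
    b: float
    phi: float
    conic: np.ndarray
    n_used: int
    method: str
    structure_id: str = ""

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"require a >= b > 0; got a={self.a}, b={self.b}")
        object.__setattr__(self, "phi", float(self.phi) % np.pi)

    def radius_at(self, alpha: np.ndarray) -> np.ndarray:
        """Ellipse radius along polar angle ``alpha`` measured in the
        ellipse frame (long axis = x)."""
        return (self.a * self.b) / np.sqrt(
            (self.b * np.cos(alpha)) ** 2 + (self.a * np.sin(alpha)) ** 2
        )


def geometry_to_conic(
    center: tuple[float, float], a: float, b: float, phi: float
) -> np.ndarray:
    """Conic coefficients (A, B, C, D, E, F), unit-norm, for an ellipse."""
    R = rot2(phi)
    Q = R @ np.diag([1.0 / a**2, 1.0 / b**2]) @ R.T
    c = np.asarray(center, dtype=float)
    lin = -2.0 * Q @ c
    const = c @ Q @ c - 1.0
    conic = np.array([Q[0, 0], 2 * Q[0, 1], Q[1, 1], lin[0], lin[1], const])
    return conic / np.linalg.norm(conic)


def conic_to_geometry(conic: np.ndarray):
    """Convert (A, B, C, D, E, F) to (center, a, b, phi).

    Raises ``ValueError`` for non-ellipse conics (parabola/hyperbola or
    degenerate).
    """
    A, B, C, D, E, F = (float(v) for v in conic)
    Q = np.array([[A, B / 2.0], [B / 2.0, C]])
    det = np.linalg.det(Q)
    if det <= 0:
        raise ValueError("conic is not an ellipse (B^2 - 4AC >= 0)")
    center = np.linalg.solve(Q, -0.5 * np.array([D, E]))
    # conic value at the center; an ellipse requires it opposite in sign
    # to the (definite) quadratic form
    k = F + 0.5 * (D * center[0] + E * center[1])
    evals, evecs = np.linalg.eigh(Q)
    if np.any(evals * k >= 0):  # ellipse needs both ratios -k/eval positive
        raise ValueError("degenerate or imaginary ellipse")
    axes = np.sqrt(-k / evals)
    long_i = int(np.argmax(axes))
    a, b = float(axes[long_i]), float(axes[1 - long_i])
    v_long = evecs[:, long_i]
    phi = float(np.arctan2(v_long[1], v_long[0])) % np.pi
    return (float(center[0]), float(center[1])), a, b, phi


def _direct_ellipse_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted ellipse-constrained direct conic fit (Halir–Flusser scheme).

    Returns unit-norm (A, B, C, D, E, F) guaranteed to satisfy B² - 4AC < 0.
    """
    sw = np.sqrt(w)
    D1 = np.column_stack([x * x, x * y, y * y]) * sw[:, None]
    D2 = np.column_stack([x, y, np.ones_like(x)]) * sw[:, None]
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate point set for ellipse fitting") from exc
    M = S1 + S2 @ T
    # inverse of the constraint matrix C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    evals, evecs = np.linalg.eig(M)
    evecs_r = np.real(evecs)
    cond = 4.0 * evecs_r[0] * evecs_r[2] - evecs_r[1] ** 2
    ok = np.where(np.isreal(evals) & (cond > 0))[0]
    if ok.size == 0:
        raise ValueError("no ellipse solution (degenerate or non-elliptical data)")
    a1 = evecs_r[:, ok[0]]
    conic = np.concatenate([a1, T @ a1])
    return conic / np.linalg.norm(conic)


def fit_ellipse(ml: MoleculeList, method: str = "robust") -> EllipseFit:
    """Fit the (x, y) coordinates of one structure to an ellipse.

    ``method="least_squares"`` minimizes the sum of squared algebraic conic
    residuals under the ellipse constraint.  ``method="robust"`` approximates
    the least-absolute-deviations solution by IRLS with weights 1/|residual|
    (at most 50 passes, converged at 1e-8 relative coefficient change),
    which resists the outlier localizations typical of STORM data.
    """
    if method not in ("robust", "least_squares"):
        raise ValueError(f"unknown method {method!r}")
    ml.require_nonempty()
    if ml.n < 6:
        raise ValueError(
            f"structure {ml.structure_id!r}: need >= 6 points to fit an ellipse"
        )
    # center/scale for numerical conditioning; mapped back via geometry
    mx, my = float(np.mean(ml.x)), float(np.mean(ml.y))
    x = ml.x - mx
    y = ml.y - my
    scale = float(np.mean(np.hypot(x, y)))
    if scale == 0:
        raise ValueError(f"structure {ml.structure_id!r}: coincident points")
    x = x / scale
    y = y / scale

    w = np.ones(ml.n)
    conic = _direct_ellipse_fit(x, y, w)
    if method == "robust":
        design = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
        for _ in range(_IRLS_MAX_ITER):
            r = design @ conic
            w = 1.0 / np.maximum(np.abs(r), 1e-12)
            new = _direct_ellipse_fit(x, y, w)
            if np.dot(new, conic) < 0:
                new = -new
            if np.linalg.norm(new - conic) < _IRLS_TOL:
                conic = new
                break
            conic = new

    (cx, cy), a, b, phi = conic_to_geometry(conic)
    center = (cx * scale + mx, cy * scale + my)
    a *= scale
    b *= scale
    return EllipseFit(
        center=center,
        a=a,
        b=b,
        phi=phi,
        conic=geometry_to_conic(center, a, b, phi),
        n_used=ml.n,
        method=method,
        structure_id=ml.structure_id,
    )


def _radial_residuals(ml: MoleculeList, fit: EllipseFit) -> np.ndarray:
    """Signed radial residual: point radius minus ellipse radius along the
    ray from the fitted center (computed in the ellipse frame)."""
    xy = ml.xyz[:, :2] - np.asarray(fit.center)
    xy = xy @ rot2(-fit.phi).T
    r = np.hypot(xy[:, 0], xy[:, 1])
    alpha = np.arctan2(xy[:, 1], xy[:, 0])
    return r - fit.radius_at(alpha)


def remove_outliers(
    ml: MoleculeList, fit: EllipseFit, k: float = 1.5
) -> tuple[MoleculeList, int]:
    """Drop localizations whose radial residual is > k standard deviations
    from the mean residual (default k = 1.5).

    Returns the cleaned list and the number of removed points.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    res = _radial_residuals(ml, fit)
    sd = res.std()
    if sd < 1e-6:  # numerically exact fit: nothing is an outlier
        return ml, 0
    keep = np.abs(res - res.mean()) <= k * sd
    n_keep = int(keep.sum())
    if n_keep < 6:
        raise ValueError(
            f"structure {ml.structure_id!r}: outlier removal would leave "
            f"{n_keep} < 6 points"
        )
    cleaned = ml.with_coords(ml.xyz[keep])
    if ml.photons is not None:
        cleaned = MoleculeList(
            ml.xyz[keep],
            structure_id=ml.structure_id,
            channel_id=ml.channel_id,
            photons=ml.photons[keep],
        )
    return cleaned, int(ml.n - n_keep)


def circularize(
    ml: MoleculeList, fit: EllipseFit, R: float
) -> tuple[MoleculeList, StructureTransform]:
    """Deform a structure so its fitted ellipse becomes a circle of radius R.

    Translates by -center, rotates by -phi (long axis onto x), scales x by
    R/a and y by R/b.  Returns the deformed list and the transform recording
    those operations (z, if present, is carried through unchanged).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    t = StructureTransform(
        center=fit.center,
        pre_rotation=-fit.phi,
        scale_x=R / fit.a,
        scale_y=R / fit.b,
    )
    from .molecules import apply_transform

    return apply_transform(ml, t), t


def average_radius(fits) -> float:
    """Mean over structures of (a + b) / 2 — the common circle radius R."""
    fits = list(fits)
    if not fits:
        raise ValueError("no ellipse fits given")
    return float(np.mean([(f.a + f.b) / 2.0 for f in fits]))
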