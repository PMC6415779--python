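"""End-to-end alignment workflows.

``align_structures_2d`` runs the deformed 2D workflow: robust ellipse fit →
1.5-SD radial outlier removal → refit → circularization to the mean radius
R → rendering → iterative Fourier-domain rotation/translation alignment →
application of the final transforms to the coordinates.  With
``deform=False`` it reproduces the rigid-registration baseline (centroid
centering only, no ellipse deformation).

``align_structures_3d`` wraps the tilt-search alignment of
:mod:`ringalign.register3d` with the same rendering defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ellipse import (
    EllipseFit,
    average_radius,
    circularize,
    fit_ellipse,
    geometry_to_conic,
    remove_outliers,
)
from .molecules import (
    MoleculeList,
    PixelImage,
    StructureTransform,
    apply_transform,
    field_pixels,
    render_image,
)
from .register import AlignmentRun, iterative_align
from .register3d import Align3DRun, TiltSearchSpec, align_3d

logger = logging.getLogger(__name__)

__all__ = [
    "Align2DResult",
    "align_structures_2d",
    "align_structures_3d",
    "auto_field_size",
    "render_average",
    "ring_phase",
]


def auto_field_size(
    lists, pixel_size: float, blur_sigma: float, margin: float = 3.0
) -> float:
    """Square field (nm) covering every centered structure plus a blur
    margin, rounded up to an even number of pixels."""
    extent = max(float(np.abs(ml.xyz[:, :2]).max()) for ml in lists)
    field = 2.0 * (extent + margin * max(blur_sigma, pixel_size))
    return field_pixels(field, pixel_size) * pixel_size


def render_average(
    lists, pixel_size: float = 10.0, field_size: float | None = None,
    blur_sigma: float = 15.0,
) -> PixelImage:
    """Render the pooled localizations of aligned structures."""
    pooled = np.vstack([ml.xyz[:, :2] for ml in lists])
    if field_size is None:
        field_size = auto_field_size(
            [MoleculeList(pooled)], pixel_size, blur_sigma
        )
    return render_image(
        MoleculeList(pooled, structure_id="average"),
        pixel_size=pixel_size, field_size=field_size, blur_sigma=blur_sigma,
    )


@dataclass
class Align2DResult:
    aligned: list  # MoleculeList per surviving structure
    transforms: list  # full StructureTransform per structure
    fits: list  # EllipseFit or None (rigid mode)
    run: AlignmentRun
    radius: float | None
    n_removed: list
    failures: dict  # structure_id -> error message
    pixel_size: float
    field_size: float
    blur_sigma: float

    def average_image(self, pixel_size: float | None = None,
                      blur_sigma: float | None = None) -> PixelImage:
        return render_average(
            self.aligned,
            pixel_size=pixel_size or self.pixel_size,
            field_size=self.field_size,
            blur_sigma=self.blur_sigma if blur_sigma is None else blur_sigma,
        )


def align_structures_2d(
    structures,
    deform: bool = True,
    fit_method: str = "robust",
    outlier_k: float = 1.5,
    radius: float | None = None,
    n_iterations: int = 10,
    angle_step: float = 1.0,
    upsample: int = 100,
    pixel_size: float = 10.0,
    field_size: float | None = None,
    blur_sigma: float = 15.0,
    window: bool = True,
    max_aspect: float = 1.5,
    recenter: bool = True,
) -> Align2DResult:
    """Deformed (or rigid-baseline) 2D alignment of ring structures.

    Per-structure ellipse-fit failures are collected rather than fatal; the
    run aborts only if fewer than 2 structures survive.  The returned
    transforms compose the deformation and the recovered rigid motion in
    the fixed order center → pre-rotate → scale → in-plane rotate → shift,
    and the aligned molecule lists are the inputs with those transforms
    applied (outlier localizations removed in deformed mode).

    ``max_aspect`` guards against arc degeneracy: on heavily under-labeled
    rings the visible clusters may span only part of the circle and the
    ellipse fit can report a wildly elongated shape that no semi-flexible
    structure of this kind takes (the observed range is a/b <~ 1.35).  A
    fit with a/b above the guard is treated as a circle of radius
    (a + b)/2 — isotropic normalization to R, no anisotropic deformation.
    """
    structures = list(structures)
    failures: dict[str, str] = {}
    prepared: list[MoleculeList] = []
    fits: list[EllipseFit | None] = []
    deforms: list[StructureTransform] = []
    n_removed: list[int] = []
    kept: list[MoleculeList] = []

    if deform:
        cleaned_fits = []
        for ml in structures:
            try:
                fit0 = fit_ellipse(ml, method=fit_method)
                cleaned, removed = remove_outliers(ml, fit0, k=outlier_k)
                fit = fit_ellipse(cleaned, method=fit_method)
                cleaned_fits.append((cleaned, fit, removed))
            except (ValueError, KeyError) as exc:
                failures[ml.structure_id] = str(exc)
                logger.warning("structure %r dropped: %s", ml.structure_id, exc)
        if len(cleaned_fits) < 2:
            raise ValueError(
                f"fewer than 2 structures survived ellipse fitting "
                f"({len(failures)} failures)"
            )
        R = radius if radius is not None else average_radius(
            [f for _, f, _ in cleaned_fits]
        )
        for cleaned, fit, removed in cleaned_fits:
            if fit.a / fit.b > max_aspect:
                logger.info(
                    "structure %r: fitted aspect %.2f exceeds %.2f "
                    "(arc-degenerate fit); normalizing isotropically",
                    cleaned.structure_id, fit.a / fit.b, max_aspect,
                )
                r_iso = (fit.a + fit.b) / 2.0
                fit = EllipseFit(
                    center=fit.center, a=r_iso, b=r_iso, phi=0.0,
                    conic=geometry_to_conic(fit.center, r_iso, r_iso, 0.0),
                    n_used=fit.n_used, method=fit.method,
                    structure_id=fit.structure_id,
                )
            circ, t = circularize(cleaned, fit, R)
            prepared.append(circ)
            fits.append(fit)
            deforms.append(t)
            n_removed.append(removed)
            kept.append(cleaned)
    else:
        R = radius
        for ml in structures:
            ml.require_nonempty()
            centroid = ml.xyz[:, :2].mean(axis=0)
            t = StructureTransform(center=(float(centroid[0]), float(centroid[1])))
            prepared.append(apply_transform(ml, t))
            fits.append(None)
            deforms.append(t)
            n_removed.append(0)
            kept.append(ml)

    if field_size is None:
        field_size = auto_field_size(prepared, pixel_size, blur_sigma)
    images = [
        render_image(ml, pixel_size=pixel_size, field_size=field_size,
                     blur_sigma=blur_sigma)
        for ml in prepared
    ]
    run = iterative_align(
        images, n_iterations=n_iterations, angle_step=angle_step,
        upsample=upsample, window=window,
    )

    aligned = []
    transforms = []
    for ml, d, res in zip(prepared, deforms, run.final_transforms):
        rigid = res.to_nm(pixel_size)
        aligned.append(apply_transform(ml, rigid))
        transforms.append(
            StructureTransform(
                center=d.center,
                pre_rotation=d.pre_rotation,
                scale_x=d.scale_x,
                scale_y=d.scale_y,
                theta=rigid.theta,
                shift=rigid.shift,
            )
        )
    # translation gauge fix: the mutual-alignment objective is invariant
    # under one common shift, so the consensus can drift off the raster
    # center; anchor it at the fitted center of the pooled aligned ring
    if recenter:
        pooled = MoleculeList(
            np.vstack([ml.xyz[:, :2] for ml in aligned]), structure_id="pooled"
        )
        try:
            c0 = np.asarray(fit_ellipse(pooled, method="robust").center)
        except ValueError:
            c0 = pooled.xyz.mean(axis=0)
        logger.info("recentered aligned ensemble by (%.1f, %.1f) nm", *c0)
        aligned = [
            ml.with_coords(
                np.column_stack([ml.xyz[:, :2] - c0, ml.xyz[:, 2:]])
                if ml.is_3d else ml.xyz - c0
            )
            for ml in aligned
        ]
        transforms = [
            StructureTransform(
                center=t.center, pre_rotation=t.pre_rotation,
                scale_x=t.scale_x, scale_y=t.scale_y, tilt_phi=t.tilt_phi,
                theta=t.theta,
                shift=(t.shift[0] - c0[0], t.shift[1] - c0[1]),
            )
            for t in transforms
        ]
    return Align2DResult(
        aligned=aligned,
        transforms=transforms,
        fits=fits,
        run=run,
        radius=R,
        n_removed=n_removed,
        failures=failures,
        pixel_size=pixel_size,
        field_size=field_size,
        blur_sigma=blur_sigma,
    )


def align_structures_3d(
    structures,
    spec: TiltSearchSpec | None = None,
    angle_step: float = 1.0,
    upsample: int = 100,
    pixel_size: float = 10.0,
    field_size: float | None = None,
    blur_sigma: float = 15.0,
    window: bool = True,
    global_detilt: bool = True,
) -> Align3DRun:
    """3D tilt-search alignment with automatic field sizing (no deformation)."""
    structures = list(structures)
    if field_size is None:
        centered = [
            ml.with_coords(ml.xyz - ml.xyz.mean(axis=0)) for ml in structures
        ]
        field_size = auto_field_size(centered, pixel_size, blur_sigma)
    return align_3d(
        structures, spec=spec, angle_step=angle_step, upsample=upsample,
        pixel_size=pixel_size, field_size=field_size, blur_sigma=blur_sigma,
        window=window, global_detilt=global_detilt,
    )


def ring_phase(img: PixelImage | np.ndarray, n_fold: int,
               pixel_size: float | None = None) -> float:
    """Phase (degrees, in (-180/n, 180/n]) of the n-fold harmonic of an
    image's angular intensity distribution about the raster center.

    Used to read the cluster phase of an averaged ring image; the phase
    difference between two channels gives their angular offset modulo
    360/n degrees.
    """
    arr = img.values if isinstance(img, PixelImage) else np.asarray(img, dtype=float)
    m, n = arr.shape
    rr = (np.arange(m) - (m - 1) / 2.0)[:, None]
    cc = (np.arange(n) - (n - 1) / 2.0)[None, :]
    alpha = np.arctan2(rr, cc)  # y over x
    w = arr - arr.mean()
    w = np.where(w > 0, w, 0.0)
    zsum = np.sum(w * np.exp(1j * n_fold * alpha))
    if np.abs(zsum) == 0:
        raise ValueError("no angular structure")
    return float(np.rad2deg(np.angle(zsum)) / n_fold)


def phase_offset(phase1: float, phase2: float, n_fold: int) -> float:
    """Absolute angular offset |phase1 - phase2| wrapped to [0, 180/n]."""
    period = 360.0 / n_fold
    d = (phase1 - phase2) % period
    return float(min(d, period - d))
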