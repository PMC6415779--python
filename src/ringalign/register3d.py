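"""3D alignment of tilted flat structures.

Randomly oriented flat rings project onto the x–y plane as heterogeneous
ellipses.  Instead of deforming them, the 3D algorithm adds one exhaustive
search loop over a rotation about the x axis: for each trial tilt phi the
coordinates are rotated by

    [x', y', z'] = [[1, 0, 0], [0, cos phi, -sin phi], [0, sin phi, cos phi]] [x, y, z]

about the structure centroid, the x–y projection is rendered, and the 2D
(theta, shift) search runs against the evolving average reference.  By
Euler's rotation theorem, compositions of the z- and x-rotations accumulated
over iterations cover arbitrary orientations of a flat structure (a y-axis
tilt equals z(90°) · x(tilt) · z(−90°)), so the loop is iterated (default 5
times) with the coordinates re-transformed between iterations.  No
circularization is applied in 3D mode.

With a tilt grid of exactly {0} the algorithm delegates to the 2D iterative
loop on the projections, so the two paths produce identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .molecules import MoleculeList, PixelImage, render_image, rotx3, rotz3
from .register import (
    AlignmentRun,
    RegistrationResult,
    _register_to_rotated_stack,
    _angle_grid,
    build_reference_stack,
    iterative_align,
    preprocess,
)

logger = logging.getLogger(__name__)

__all__ = ["TiltSearchSpec", "rotate_about_x", "align_3d", "Align3DRun"]


@dataclass(frozen=True)
class TiltSearchSpec:
    """Grid for the exhaustive x-axis tilt search (degrees)."""

    phi_min: float = -90.0
    phi_max: float = 90.0
    phi_step: float = 2.0
    n_iterations: int = 5

    def __post_init__(self) -> None:
        if self.phi_step <= 0:
            raise ValueError("phi_step must be positive")
        if self.phi_max < self.phi_min:
            raise ValueError("phi_max must be >= phi_min")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def grid(self) -> np.ndarray:
        """Trial tilts ordered by |phi| (positive before negative), so exact
        correlation ties break toward the smallest tilt magnitude."""
        n = int(np.floor((self.phi_max - self.phi_min) / self.phi_step + 1e-9)) + 1
        phis = self.phi_min + self.phi_step * np.arange(n)
        if not phis.size:
            raise ValueError("empty tilt grid")
        order = np.lexsort((phis < 0, np.abs(phis)))
        return phis[order]


def rotate_about_x(ml: MoleculeList, phi: float) -> MoleculeList:
    """Rotate 3D coordinates by ``phi`` degrees about the x axis through the
    structure centroid."""
    if not ml.is_3d:
        raise ValueError(f"structure {ml.structure_id!r} has no z coordinates")
    if phi % 360.0 == 0.0:
        return ml.with_coords(ml.xyz.copy())
    centroid = ml.xyz.mean(axis=0)
    return ml.with_coords((ml.xyz - centroid) @ rotx3(np.deg2rad(phi)).T + centroid)


@dataclass
class Align3DRun:
    """Outcome of the iterative 3D alignment."""

    aligned: list  # MoleculeList, centroid-centered and transformed
    history: list  # per iteration: list of (phi, RegistrationResult)
    references: list  # per iteration reference raster
    rotations: list  # per structure cumulative 3x3 rotation matrix
    centroids: list  # original centroid removed from each structure
    boundary_flags: list  # structures whose best phi hit the grid boundary
    n_iterations: int
    pixel_size: float

    def final_tilts(self) -> list:
        return [phi for phi, _ in self.history[-1]]


def _render_xy(coords: np.ndarray, sid: str, pixel_size: float,
               field_size: float, blur_sigma: float) -> PixelImage:
    return render_image(
        MoleculeList(coords[:, :2], structure_id=sid),
        pixel_size=pixel_size, field_size=field_size, blur_sigma=blur_sigma,
    )


def _ensemble_detilt(coords: list) -> np.ndarray:
    """Global gauge fix: rotation taking the pooled cloud's smallest
    principal axis (the ring normal) onto z.

    The mutual-alignment objective is invariant under one rigid rotation
    applied to every structure, so the iteration may settle in a uniformly
    tilted frame; this anchors the gauge so the averaged ring lies flat.
    """
    pooled = np.vstack(coords)
    pooled = pooled - pooled.mean(axis=0)
    evals, evecs = np.linalg.eigh(pooled.T @ pooled)
    n = evecs[:, 0]  # smallest variance = ring normal
    if n[2] < 0:
        n = -n
    axis = np.cross(n, [0.0, 0.0, 1.0])
    s = np.linalg.norm(axis)
    c = float(np.clip(n[2], -1.0, 1.0))
    if s < 1e-12:
        return np.eye(3)
    axis = axis / s
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(np.arccos(c)) * K + (1 - c) * (K @ K)


def align_3d(
    structures: list,
    spec: TiltSearchSpec | None = None,
    angle_step: float = 1.0,
    upsample: int = 100,
    pixel_size: float = 10.0,
    field_size: float = 1024.0,
    blur_sigma: float = 15.0,
    window: bool = True,
    global_detilt: bool = True,
) -> Align3DRun:
    """Iteratively align tilted flat 3D structures by their x–y projections.

    Each structure is first centered on its centroid.  Per iteration and per
    structure, every tilt in ``spec.grid()`` is tried: the coordinates are
    rotated about x, the projection rendered, and the in-plane (theta,
    shift) search run against the average-projection reference; the
    (phi, theta, shift) with the largest correlation peak wins.  The
    increments are applied to the coordinates (z carried through), and the
    cumulative rotation accumulates Rz(theta)·Rx(phi) across iterations.
    """
    spec = spec or TiltSearchSpec()
    if len(structures) < 2:
        raise ValueError("need at least 2 structures to align")
    for ml in structures:
        if not ml.is_3d:
            raise ValueError(f"structure {ml.structure_id!r} is not 3D")
        ml.require_nonempty()
    phis = spec.grid()

    centroids = [ml.xyz.mean(axis=0) for ml in structures]
    coords = [ml.xyz - c for ml, c in zip(structures, centroids)]

    if phis.size == 1 and phis[0] == 0.0:
        return _align_3d_flat(
            structures, coords, centroids, spec, angle_step, upsample,
            pixel_size, field_size, blur_sigma, window,
        )

    angles = _angle_grid(angle_step)
    rotations = [np.eye(3) for _ in structures]
    history: list = []
    references: list = []

    for it in range(spec.n_iterations):
        projections = [
            _render_xy(c, ml.structure_id, pixel_size, field_size, blur_sigma)
            for c, ml in zip(coords, structures)
        ]
        ref = np.mean([p.values for p in projections], axis=0)
        references.append(ref)
        ref_pre = preprocess(ref, window=window)
        sum_f2 = float(np.sum(ref_pre**2))
        H = build_reference_stack(ref_pre, angles)

        iter_results = []
        for i, ml in enumerate(structures):
            best: tuple | None = None
            cen = coords[i].mean(axis=0)
            for phi in phis:
                rot = rotx3(np.deg2rad(phi))
                cphi = (coords[i] - cen) @ rot.T + cen
                img = _render_xy(cphi, ml.structure_id, pixel_size,
                                 field_size, blur_sigma)
                pre = preprocess(img, window=window)
                M = np.fft.fft2(pre)
                res = _register_to_rotated_stack(
                    M, H, angles, upsample, sum_f2, float(np.sum(pre**2))
                )
                # across tilts the moving image's energy changes, so the
                # comparable objective is the NRMSE (normalized correlation),
                # not the raw correlation peak
                if best is None or res.nrmse < best[1].nrmse:
                    best = (float(phi), res, cphi)
            phi0, res, cphi = best
            rz = rotz3(np.deg2rad(res.theta))
            coords[i] = cphi @ rz.T
            coords[i][:, :2] += np.array(res.shift) * pixel_size
            rotations[i] = rz @ rotx3(np.deg2rad(phi0)) @ rotations[i]
            iter_results.append((phi0, res))
        history.append(iter_results)
        logger.info(
            "3D iteration %d: mean NRMSE %.5f",
            it + 1, float(np.mean([r.nrmse for _, r in iter_results])),
        )

    boundary = [
        i for i, (phi, _) in enumerate(history[-1])
        if phi in (phis.min(), phis.max()) and phis.size > 1
    ]
    if boundary:
        logger.warning(
            "structures %s selected a tilt on the grid boundary; the tilt "
            "range may under-cover their orientations", boundary,
        )
    if global_detilt:
        R = _ensemble_detilt(coords)
        coords = [c @ R.T for c in coords]
        rotations = [R @ rot for rot in rotations]
    aligned = [
        ml.with_coords(c) for ml, c in zip(structures, coords)
    ]
    return Align3DRun(
        aligned=aligned,
        history=history,
        references=references,
        rotations=rotations,
        centroids=centroids,
        boundary_flags=boundary,
        n_iterations=spec.n_iterations,
        pixel_size=pixel_size,
    )


def _align_3d_flat(structures, coords, centroids, spec, angle_step, upsample,
                   pixel_size, field_size, blur_sigma, window) -> Align3DRun:
    """Tilt grid {0}: run the 2D iterative loop on the projections and apply
    its transforms to the 3D coordinates."""
    projections = [
        _render_xy(c, ml.structure_id, pixel_size, field_size, blur_sigma)
        for c, ml in zip(coords, structures)
    ]
    run: AlignmentRun = iterative_align(
        projections, n_iterations=spec.n_iterations, angle_step=angle_step,
        upsample=upsample, window=window,
    )
    rotations = []
    aligned = []
    for ml, c, res in zip(structures, coords, run.final_transforms):
        rz = rotz3(np.deg2rad(res.theta))
        out = c @ rz.T
        out[:, :2] += np.array(res.shift) * pixel_size
        rotations.append(rz)
        aligned.append(ml.with_coords(out))
    history = [
        [(0.0, r) for r in iteration] for iteration in run.history
    ]
    return Align3DRun(
        aligned=aligned,
        history=history,
        references=run.references,
        rotations=rotations,
        centroids=centroids,
        boundary_flags=[],
        n_iterations=run.n_iterations,
        pixel_size=pixel_size,
    )
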