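"""Localization tables ("molecule lists"), rendering, and coordinate transforms.

The native data unit of single-molecule localization microscopy is a table of
fluorophore coordinates in nanometers, one row per localization.  This module
reads/writes those tables in a plain delimited text format, renders them into
pixel rasters for Fourier-domain registration, and applies the per-structure
alignment transform (deformation + 3D tilt + in-plane rotation + shift) back
onto the coordinates.

Coordinate convention (used everywhere in the package): continuous nm
coordinates (x, y[, z]); a rendered raster stores y along the row axis and x
along the column axis, with y increasing with row index.  Pixel ``(0, 0)`` is
the top-left raster cell; ``PixelImage.origin`` is the nm position of its
center.  The continuous center of the raster maps to nm ``(0, 0)`` when the
field is centered on the origin (the default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeList",
    "PixelImage",
    "StructureTransform",
    "read_molecule_list",
    "write_molecule_list",
    "render_image",
    "apply_transform",
    "invert_transform",
]


@dataclass(frozen=True)
class MoleculeList:
    """Coordinates for one structure / one channel.

    Parameters
    ----------
    xyz:
        ``(n, 2)`` or ``(n, 3)`` float array of coordinates in nm.
    structure_id:
        Identifier of the structure the localizations belong to.
    channel_id:
        Optional small-integer color channel label.
    photons:
        Optional per-localization photon counts.
    """

    xyz: np.ndarray
    structure_id: str = ""
    channel_id: int | None = None
    photons: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.xyz, dtype=float)
        if arr.ndim != 2 or arr.shape[1] not in (2, 3):
            raise ValueError(
                f"coordinates must be (n, 2) or (n, 3); got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            bad = np.where(~np.isfinite(arr).all(axis=1))[0]
            raise ValueError(
                f"non-finite coordinates at rows {bad[:10].tolist()}"
                + ("..." if bad.size > 10 else "")
            )
        object.__setattr__(self, "xyz", arr)
        if self.photons is not None:
            ph = np.asarray(self.photons, dtype=float)
            if ph.shape != (arr.shape[0],):
                raise ValueError("photons must be one value per localization")
            object.__setattr__(self, "photons", ph)

    @property
    def n(self) -> int:
        return self.xyz.shape[0]

    @property
    def is_3d(self) -> bool:
        return self.xyz.shape[1] == 3

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        if not self.is_3d:
            raise ValueError(f"structure {self.structure_id!r} has no z coordinates")
        return self.xyz[:, 2]

    def with_coords(self, xyz: np.ndarray) -> "MoleculeList":
        """Copy of this list with replaced coordinates (metadata preserved)."""
        return replace(self, xyz=np.asarray(xyz, dtype=float))

    def require_nonempty(self) -> None:
        if self.n == 0:
            raise ValueError(f"structure {self.structure_id!r} is empty")


@dataclass(frozen=True)
class PixelImage:
    """Rendered 2D intensity raster with known geometry.

    ``values[row, col]`` covers nm position
    ``(origin[0] + col * pixel_size, origin[1] + row * pixel_size)``.
    """

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("image must be 2D")
        m, n = arr.shape
        if m < 8 or n < 8 or m % 2 or n % 2:
            raise ValueError(f"image dimensions must be even and >= 8; got {arr.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def center_px(self) -> tuple[float, float]:
        """Continuous (row, col) center of the raster."""
        m, n = self.values.shape
        return ((m - 1) / 2.0, (n - 1) / 2.0)

    def to_tiff(self, path: str | Path) -> None:
        """Export as 16-bit TIFF (intensities rescaled to the uint16 range)."""
        import tifffile

        v = self.values
        vmax = float(v.max())
        scaled = (v / vmax * 65535.0) if vmax > 0 else np.zeros_like(v)
        tifffile.imwrite(str(path), scaled.astype(np.uint16))


@dataclass(frozen=True)
class StructureTransform:
    """Accumulated per-structure alignment state.

    Applied to a point ``p`` in this fixed composition order:

    1. translate by ``-center``
    2. rotate in-plane by ``pre_rotation`` (radians, about z)
    3. scale x by ``scale_x`` and y by ``scale_y`` (circularization R/a, R/b)
    4. rotate by ``tilt_phi`` (degrees) about the x axis
    5. rotate in-plane by ``theta`` (degrees, about z)
    6. translate by ``shift``

    The in-plane rotation matrix convention is
    ``[[cos, -sin], [sin, cos]]`` acting on column vectors ``(x, y)``;
    the x-axis rotation is ``[[1,0,0],[0,cos,-sin],[0,sin,cos]]`` on
    ``(x, y, z)``.
    """

    center: tuple[float, float] = (0.0, 0.0)
    pre_rotation: float = 0.0  # radians
    scale_x: float = 1.0
    scale_y: float = 1.0
    tilt_phi: float = 0.0  # degrees
    theta: float = 0.0  # degrees, normalized to [0, 360)
    shift: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ValueError("scale factors must be positive")
        object.__setattr__(self, "theta", float(self.theta) % 360.0)

    @property
    def is_identity(self) -> bool:
        return (
            self.center == (0.0, 0.0)
            and self.pre_rotation == 0.0
            and self.scale_x == 1.0
            and self.scale_y == 1.0
            and self.tilt_phi == 0.0
            and self.theta == 0.0
            and self.shift == (0.0, 0.0)
        )


def rot2(angle_rad: float) -> np.ndarray:
    """2x2 in-plane rotation matrix, counter-clockwise on (x, y)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s], [s, c]])


def rotx3(angle_rad: float) -> np.ndarray:
    """3x3 rotation matrix about the x axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotz3(angle_rad: float) -> np.ndarray:
    """3x3 rotation matrix about the z axis (in-plane)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_CANONICAL_COLUMNS = {"x": "x_nm", "y": "y_nm", "z": "z_nm",
                      "channel": "channel", "photons": "photons"}


def read_molecule_list(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    units: str = "nm",
    structure_id: str | None = None,
) -> MoleculeList:
    """Read a delimited-text molecule list.

    Parameters
    ----------
    path:
        CSV or TSV file with named columns (default header names:
        ``x_nm, y_nm[, z_nm][, channel][, photons]``).
    columns:
        Optional mapping from the canonical names ``x, y, z, channel,
        photons`` to the column names actually present in the file.
    units:
        ``"nm"`` (default) or ``"um"``; micrometer input is converted to nm.

    Raises
    ------
    ValueError
        For an empty table, missing mapped columns, or NaN coordinates
        (the offending row indices are named).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: empty molecule list")
    colmap = dict(_CANONICAL_COLUMNS)
    if columns:
        colmap.update(columns)
    for key in ("x", "y"):
        if colmap[key] not in df.columns:
            raise ValueError(f"{path}: required column {colmap[key]!r} not found")
    if units not in ("nm", "um"):
        raise ValueError(f"unknown units {units!r}")
    factor = 1000.0 if units == "um" else 1.0

    use = [colmap["x"], colmap["y"]]
    if colmap["z"] in df.columns:
        use.append(colmap["z"])
    coords = df[use].to_numpy(dtype=float) * factor
    bad = np.where(~np.isfinite(coords).all(axis=1))[0]
    if bad.size:
        raise ValueError(
            f"{path}: NaN/non-finite coordinate at row(s) {bad[:10].tolist()}"
        )

    photons = None
    if colmap["photons"] in df.columns:
        photons = df[colmap["photons"]].to_numpy(dtype=float)
    channel = None
    if colmap["channel"] in df.columns:
        ch = df[colmap["channel"]].to_numpy()
        uniq = np.unique(ch)
        if uniq.size == 1:
            channel = int(uniq[0])
    return MoleculeList(
        coords,
        structure_id=structure_id if structure_id is not None else path.stem,
        channel_id=channel,
        photons=photons,
    )


def write_molecule_list(ml: MoleculeList, path: str | Path) -> Path:
    """Write a molecule list as delimited text; round-trips to <= 1e-6 nm."""
    ml.require_nonempty()
    path = Path(path)
    data: dict[str, np.ndarray] = {"x_nm": ml.x, "y_nm": ml.y}
    if ml.is_3d:
        data["z_nm"] = ml.z
    if ml.channel_id is not None:
        data["channel"] = np.full(ml.n, ml.channel_id, dtype=int)
    if ml.photons is not None:
        data["photons"] = ml.photons
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.6f")
    return path


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def field_pixels(field_size: float, pixel_size: float) -> int:
    """Number of pixels per side for a square field (forced even, >= 8)."""
    n = int(np.ceil(field_size / pixel_size))
    if n % 2:
        n += 1
    return max(n, 8)


def render_image(
    ml: MoleculeList,
    pixel_size: float = 10.0,
    field_size: float = 1024.0,
    blur_sigma: float = 0.0,
) -> PixelImage:
    """Render a molecule list into a 2D intensity raster.

    A 2D histogram of (x, y) on a square pixel grid centered on the origin,
    optionally followed by Gaussian smoothing with ``blur_sigma`` (nm).  The
    total intensity before smoothing equals the number of in-field points;
    out-of-field points are dropped with a logged count.
    """
    ml.require_nonempty()
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    npix = field_pixels(field_size, pixel_size)
    half = npix * pixel_size / 2.0
    edges = np.linspace(-half, half, npix + 1)
    inside = (
        (ml.x >= -half) & (ml.x < half) & (ml.y >= -half) & (ml.y < half)
    )
    n_dropped = int(ml.n - inside.sum())
    if inside.sum() == 0:
        raise ValueError(
            f"structure {ml.structure_id!r}: all {ml.n} points outside the "
            f"{npix * pixel_size:.0f} nm field"
        )
    if n_dropped:
        logger.info(
            "render_image: dropped %d/%d out-of-field points (structure %r)",
            n_dropped, ml.n, ml.structure_id,
        )
    hist, _, _ = np.histogram2d(ml.y[inside], ml.x[inside], bins=[edges, edges])
    if blur_sigma > 0:
        hist = ndimage.gaussian_filter(hist, sigma=blur_sigma / pixel_size)
    origin = (-half + pixel_size / 2.0, -half + pixel_size / 2.0)
    return PixelImage(hist, pixel_size=pixel_size, origin=origin)


# ---------------------------------------------------------------------------
# Coordinate transforms
# ---------------------------------------------------------------------------

def apply_transform(ml: MoleculeList, t: StructureTransform) -> MoleculeList:
    """Apply a structure transform to coordinates in the documented order.

    ``tilt_phi != 0`` requires 3D coordinates; 2D lists are treated as the
    z = 0 plane only when no tilt is requested.
    """
    ml.require_nonempty()
    if t.tilt_phi != 0.0 and not ml.is_3d:
        raise ValueError(
            f"structure {ml.structure_id!r}: tilt_phi={t.tilt_phi} requires z"
        )
    xy = ml.xyz[:, :2] - np.asarray(t.center)
    xy = xy @ rot2(t.pre_rotation).T
    xy = xy * np.array([t.scale_x, t.scale_y])
    if ml.is_3d:
        p = np.column_stack([xy, ml.xyz[:, 2]])
        if t.tilt_phi != 0.0:
            p = p @ rotx3(np.deg2rad(t.tilt_phi)).T
        p = p @ rotz3(np.deg2rad(t.theta)).T
        p[:, :2] += np.asarray(t.shift)
        return ml.with_coords(p)
    xy = xy @ rot2(np.deg2rad(t.theta)).T
    xy = xy + np.asarray(t.shift)
    return ml.with_coords(xy)


def invert_transform(t: StructureTransform) -> StructureTransform:
    """Inverse transform, when representable in the same parameterization.

    Supported cases: no tilt (any scales), or unit scales (any tilt) — the
    two cases the pipelines produce.  A transform mixing anisotropic scaling
    with an x-tilt has no exact inverse of the same shape and raises.
    """
    theta_rad = np.deg2rad(t.theta)
    if t.tilt_phi == 0.0:
        return StructureTransform(
            center=t.shift,
            pre_rotation=-theta_rad,
            scale_x=1.0 / t.scale_x,
            scale_y=1.0 / t.scale_y,
            tilt_phi=0.0,
            theta=-np.rad2deg(t.pre_rotation),
            shift=t.center,
        )
    if t.scale_x == 1.0 and t.scale_y == 1.0:
        return StructureTransform(
            center=t.shift,
            pre_rotation=-theta_rad,
            scale_x=1.0,
            scale_y=1.0,
            tilt_phi=-t.tilt_phi,
            theta=-np.rad2deg(t.pre_rotation),
            shift=t.center,
        )
    raise ValueError("cannot invert a transform combining scaling and tilt")
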