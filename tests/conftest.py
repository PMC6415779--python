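import numpy as np
import pytest

from ringalign import MoleculeList, render_image
from ringalign.molecules import rot2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ring_points(
    n_fold=9, radius=150.0, locs_per_cluster=50, noise=15.0, spin=0.0,
    rng=None, z=False,
):
    """Noisy ring of Gaussian clusters used across the registration tests."""
    rng = rng or np.random.default_rng(0)
    ang = np.deg2rad(np.arange(n_fold) * 360.0 / n_fold + spin)
    pts = np.repeat(
        np.column_stack([radius * np.cos(ang), radius * np.sin(ang)]),
        locs_per_cluster, axis=0,
    )
    if noise > 0:
        pts = pts + rng.normal(0.0, noise, pts.shape)
    if z:
        zc = rng.normal(0.0, noise, pts.shape[0]) if noise > 0 else np.zeros(pts.shape[0])
        pts = np.column_stack([pts, zc])
    return pts


@pytest.fixture
def ring_image(rng):
    ml = MoleculeList(ring_points(rng=rng), structure_id="ring")
    return render_image(ml, pixel_size=10.0, field_size=640.0, blur_sigma=12.0)


@pytest.fixture
def blob_image(rng):
    """Asymmetric three-blob image with no rotational symmetry."""
    pts = np.vstack([
        rng.normal([80, 0], 12, (300, 2)),
        rng.normal([-40, 60], 12, (200, 2)),
        rng.normal([0, -90], 12, (150, 2)),
    ])
    return render_image(MoleculeList(pts), pixel_size=10.0, field_size=640.0,
                        blur_sigma=12.0)


def ellipse_points(a=200.0, b=150.0, phi_deg=30.0, center=(0.0, 0.0), n=500,
                   noise=10.0, rng=None):
    rng = rng or np.random.default_rng(0)
    t = rng.uniform(0, 2 * np.pi, n)
    xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
    xy = xy @ rot2(np.deg2rad(phi_deg)).T + np.asarray(center)
    if noise > 0:
        xy = xy + rng.normal(0.0, noise, xy.shape)
    return xy
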