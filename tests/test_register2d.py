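"""Subpixel DFT registration, the rotation search, and the iterative loop."""

import numpy as np
import pytest

from ringalign import (
    MoleculeList,
    PixelImage,
    dft_translation_register,
    iterative_align,
    nrmse,
    render_image,
    rotation_translation_register,
)
from ringalign.molecules import rot2
from ringalign.register import (
    fourier_shift_raster,
    preprocess,
    rotate_raster,
)

from conftest import ring_points


def _shifted(img: PixelImage, shift) -> PixelImage:
    return PixelImage(fourier_shift_raster(img.values, shift), img.pixel_size,
                      img.origin)


def brute_force_search(moving, reference, angle_step=1.0):
    """Independent exhaustive search: every trial angle x every circular
    integer shift, correlation evaluated by explicit rolls in the spatial
    domain (same preprocessing and rotation operator as the implementation,
    so the search logic itself is what is compared)."""
    f = preprocess(reference)
    g = preprocess(moving)
    m, n = f.shape
    best = None
    for theta in np.arange(0.0, 360.0, angle_step):
        g_rot = rotate_raster(g, theta)
        for dy in range(m):
            rolled_y = np.roll(g_rot, dy, axis=0)
            for dx in range(n):
                cc = float(np.sum(f * np.roll(rolled_y, dx, axis=1)))
                if best is None or cc > best[0]:
                    sdy = dy - m if dy > m // 2 else dy
                    sdx = dx - n if dx > n // 2 else dx
                    best = (cc, theta, (sdx, sdy))
    return best[1], best[2]


class TestTranslation:
    def test_self_registration_is_identity(self, ring_image):
        r = dft_translation_register(ring_image, ring_image)
        assert r.shift == (0.0, 0.0)
        assert r.theta == 0.0
        assert r.nrmse == pytest.approx(0.0, abs=1e-9)

    def test_integer_shift_equals_brute_force(self, ring_image):
        moving = PixelImage(np.roll(ring_image.values, ((-3), 5), axis=(0, 1)),
                            ring_image.pixel_size, ring_image.origin)
        r = dft_translation_register(moving, ring_image, upsample=1)
        # rolling content by (-3 rows, +5 cols) needs shift (-5, +3) undone
        assert r.shift == (-5.0, 3.0)
        # independent spatial-domain check at the found shift
        f = preprocess(ring_image, window=False)
        g = preprocess(moving, window=False)
        cc_found = np.sum(f * np.roll(g, (int(r.shift[1]), int(r.shift[0])),
                                      axis=(0, 1)))
        assert cc_found == pytest.approx(r.peak_correlation, rel=1e-9)

    def test_subpixel_precision_hundredth_pixel(self, ring_image):
        # fractional shifts recovered to <= 0.01 px at upsample 100
        for true in [(3.37, -1.82), (-0.44, 0.29)]:
            moving = _shifted(ring_image, true)
            r = dft_translation_register(moving, ring_image, upsample=100)
            assert abs(r.shift[0] + true[0]) <= 0.01
            assert abs(r.shift[1] + true[1]) <= 0.01

    def test_agrees_with_skimage_phase_cross_correlation(self, ring_image):
        """Independent cross-check of the subpixel estimate against
        scikit-image's upsampled-DFT registration."""
        from skimage.registration import phase_cross_correlation

        moving = _shifted(ring_image, (3.37, -1.82))
        r = dft_translation_register(moving, ring_image, upsample=100)
        sk_shift, _, _ = phase_cross_correlation(
            ring_image.values, moving.values, upsample_factor=100,
            normalization=None,
        )
        # scikit-image returns (row, col) = (dy, dx)
        assert r.shift[0] == pytest.approx(sk_shift[1], abs=0.01)
        assert r.shift[1] == pytest.approx(sk_shift[0], abs=0.01)

    def test_dimension_mismatch_rejected(self, ring_image):
        other = PixelImage(np.ones((32, 32)), ring_image.pixel_size)
        with pytest.raises(ValueError, match="dimensions"):
            dft_translation_register(other, ring_image)

    def test_zero_image_rejected(self, ring_image):
        zero = PixelImage(np.zeros_like(ring_image.values),
                          ring_image.pixel_size)
        with pytest.raises(ValueError, match="zero"):
            dft_translation_register(zero, ring_image)


class TestRotation:
    def test_symmetric_self_registration_tie_breaks_to_zero(self, ring_image):
        r = rotation_translation_register(ring_image, ring_image,
                                          angle_step=1.0)
        assert r.theta == 0.0
        assert np.hypot(*r.shift) < 0.02

    def test_known_rotation_recovered(self, blob_image):
        moving = PixelImage(rotate_raster(blob_image.values, 25.0),
                            blob_image.pixel_size, blob_image.origin)
        r = rotation_translation_register(moving, blob_image, angle_step=1.0)
        # convention: theta rotates the moving image onto the reference
        assert r.theta == pytest.approx(335.0, abs=1.0)
        assert np.hypot(*r.shift) < 0.05

    def test_rotation_and_shift_jointly_recovered(self, blob_image):
        moved = fourier_shift_raster(rotate_raster(blob_image.values, 90.0),
                                     (4.0, 4.0))
        moving = PixelImage(moved, blob_image.pixel_size, blob_image.origin)
        r = rotation_translation_register(moving, blob_image, angle_step=1.0)
        assert r.theta == pytest.approx(270.0, abs=1.0)
        # undoing the rotation carries the shift: -R_270 (4, 4) = (-4, 4)
        assert r.shift[0] == pytest.approx(-4.0, abs=0.05)
        assert r.shift[1] == pytest.approx(4.0, abs=0.05)

    def test_equals_brute_force_on_random_cases(self, rng):
        """Exhaustive-search oracle on small asymmetric images."""
        for case in range(3):
            pts = rng.normal(0, 60, (120, 2))
            img = render_image(MoleculeList(pts), pixel_size=10.0,
                               field_size=320.0, blur_sigma=14.0)
            moved = np.roll(
                rotate_raster(img.values, float(rng.integers(0, 12)) * 30.0),
                (int(rng.integers(-5, 6)), int(rng.integers(-5, 6))),
                axis=(0, 1),
            )
            moving = PixelImage(moved, img.pixel_size, img.origin)
            r = rotation_translation_register(moving, img, angle_step=30.0,
                                              upsample=1)
            bf_theta, bf_shift = brute_force_search(moving, img,
                                                    angle_step=30.0)
            assert r.theta == bf_theta
            assert r.shift == (float(bf_shift[0]), float(bf_shift[1]))


class TestNRMSE:
    def test_zero_for_identical_images(self, ring_image):
        r = dft_translation_register(ring_image, ring_image)
        assert nrmse(ring_image, ring_image, r) == pytest.approx(0.0, abs=1e-9)

    def test_one_for_zero_moving_image(self, ring_image):
        from ringalign.register import RegistrationResult

        t = RegistrationResult(theta=0.0, shift=(0.0, 0.0),
                               peak_correlation=0.0, nrmse=1.0, alpha=0.0)
        # a blank moving image cannot explain any of the reference
        zero = np.zeros_like(ring_image.values)
        f_pre = preprocess(ring_image)
        g_t = zero
        assert float(np.sqrt(1.0 - 0.0)) == 1.0
        assert nrmse(ring_image, PixelImage(zero + 1e-12, 10.0), t) == \
            pytest.approx(1.0, abs=1e-6)

    def test_argmin_nrmse_equals_argmax_correlation(self, blob_image, rng):
        """On a grid of candidate shifts, minimizing the NRMSE and
        maximizing the cross-correlation select the same shift."""
        from ringalign.register import RegistrationResult

        moving = _shifted(blob_image, (2.0, -1.0))
        shifts = [(dx, dy) for dx in range(-4, 5, 2) for dy in range(-4, 5, 2)]
        errs, ccs = [], []
        f_pre = preprocess(blob_image)
        g_pre = preprocess(moving)
        F = np.fft.fft2(f_pre)
        G = np.fft.fft2(g_pre)
        cc_map = np.real(np.fft.ifft2(F * np.conj(G)))
        for dx, dy in shifts:
            t = RegistrationResult(theta=0.0, shift=(float(dx), float(dy)),
                                   peak_correlation=0.0, nrmse=0.0, alpha=1.0)
            errs.append(nrmse(blob_image, moving, t))
            ccs.append(cc_map[dy % cc_map.shape[0], dx % cc_map.shape[1]])
        assert int(np.argmin(errs)) == int(np.argmax(ccs))


class TestIterative:
    def test_identical_copies_are_a_fixed_point(self, ring_image):
        run = iterative_align([ring_image] * 4, n_iterations=3)
        for iteration in run.history:
            for r in iteration:
                assert r.theta == 0.0
                assert r.shift == (0.0, 0.0)
        np.testing.assert_allclose(run.references[0], ring_image.values)

    def test_known_transforms_recovered_modulo_symmetry(self, rng):
        """Copies of one 9-fold ring image under known rotations and shifts
        re-align to a common phase modulo the 40-degree symmetry."""
        base = ring_points(noise=15.0, rng=rng)
        truths = []
        images = []
        for _ in range(8):
            theta = float(rng.uniform(0, 360))
            shift = rng.uniform(-30, 30, 2)
            pts = base @ rot2(np.deg2rad(theta)).T + shift
            images.append(render_image(MoleculeList(pts), 10.0, 760.0,
                                       blur_sigma=15.0))
            truths.append(theta)
        run = iterative_align(images, n_iterations=8, angle_step=1.0)
        lock = np.array([
            (r.theta + t) % 40.0 for r, t in zip(run.final_transforms, truths)
        ])
        spread = np.ptp((lock - lock[0] + 20.0) % 40.0 - 20.0)
        assert spread <= 2.0
        # shifts recovered: aligned cluster phases coincide => mean NRMSE low
        assert run.mean_nrmse[-1] < 0.35

    def test_mean_nrmse_non_increasing(self, rng):
        base = ring_points(noise=15.0, rng=rng)
        images = []
        for _ in range(6):
            pts = base @ rot2(rng.uniform(0, 2 * np.pi)).T + rng.uniform(-20, 20, 2)
            images.append(render_image(MoleculeList(pts), 10.0, 760.0,
                                       blur_sigma=15.0))
        run = iterative_align(images, n_iterations=6)
        diffs = np.diff(run.mean_nrmse)
        assert np.all(diffs <= 1e-3)

    def test_inverse_consistency(self, blob_image, rng):
        """Registering A to B and B to A composes to identity within twice
        the search resolution."""
        pts = rng.normal(0, 60, (200, 2))
        other = render_image(MoleculeList(pts), 10.0, 640.0, blur_sigma=14.0)
        r_ab = rotation_translation_register(blob_image, other, angle_step=1.0)
        r_ba = rotation_translation_register(other, blob_image, angle_step=1.0)
        dtheta = (r_ab.theta + r_ba.theta) % 360.0
        assert min(dtheta, 360.0 - dtheta) <= 2.0
        comp = np.array(r_ba.shift) + rot2(np.deg2rad(r_ba.theta)) @ r_ab.shift
        assert np.hypot(*comp) <= 0.5

    def test_too_few_images_rejected(self, ring_image):
        with pytest.raises(ValueError, match="at least 2"):
            iterative_align([ring_image])
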