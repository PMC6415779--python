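"""Alignment quality metrics: Fourier Ring Correlation resolution and
rotational autocorrelation for symmetry detection.

FRC: the pooled aligned localizations are randomly split in half, each half
is rendered as a localization histogram, and the normalized correlation of
the two Fourier transforms is computed ring by ring of spatial frequency.
The resolution is the inverse frequency where the (lightly smoothed) curve
first drops below the 1/7 threshold.  The split is repeated (default 20
times) and the mean ± SD reported; the SD is this package's definition of
the FRC uncertainty.

Rotational autocorrelation: correlation of a (mean-subtracted, circularly
masked) image with itself rotated about the raster center, normalized so
the value at 0° is 1.  An N-fold symmetric ring shows peaks at multiples of
360°/N.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .molecules import MoleculeList, PixelImage, render_image
from .register import rotate_raster

logger = logging.getLogger(__name__)

__all__ = [
    "FRCCurve",
    "AutocorrCurve",
    "frc_resolution",
    "rotational_autocorrelation",
    "dominant_symmetry_peak",
]

UNRESOLVED = math.inf


@dataclass(frozen=True)
class FRCCurve:
    spatial_frequency: np.ndarray  # 1/nm
    correlation: np.ndarray  # mean curve over splits
    threshold: float
    resolution: float  # nm (inf if no crossing from above)
    n_splits: int
    resolution_sd: float
    per_split: np.ndarray

    @property
    def unresolved(self) -> bool:
        return not math.isfinite(self.resolution)


@dataclass(frozen=True)
class AutocorrCurve:
    angle: np.ndarray  # degrees
    correlation: np.ndarray
    peaks: list  # (angle, height) local maxima in (0, 180]


def _frc_single(
    h1: np.ndarray, h2: np.ndarray, pixel_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ring-wise normalized cross-correlation of two half-data images."""
    F1 = np.fft.fft2(h1)
    F2 = np.fft.fft2(h2)
    n = h1.shape[0]
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    radius = np.hypot(fy * n, fx * n)
    rings = np.clip(radius.astype(int), 0, n // 2)
    nbins = n // 2
    num = np.real(F1 * np.conj(F2))
    d1 = np.abs(F1) ** 2
    d2 = np.abs(F2) ** 2
    ring_num = np.bincount(rings.ravel(), num.ravel(), minlength=nbins + 1)[:nbins]
    ring_d1 = np.bincount(rings.ravel(), d1.ravel(), minlength=nbins + 1)[:nbins]
    ring_d2 = np.bincount(rings.ravel(), d2.ravel(), minlength=nbins + 1)[:nbins]
    denom = np.sqrt(ring_d1 * ring_d2)
    frc = np.divide(ring_num, denom, out=np.zeros(nbins), where=denom > 0)
    freqs = np.arange(nbins) / (n * pixel_size)
    return freqs, frc


def _threshold_crossing(
    freqs: np.ndarray, frc: np.ndarray, threshold: float
) -> float:
    """Inverse frequency of the first drop below threshold (nm); inf if the
    curve starts below, 0 frequency bin excluded."""
    curve = frc[1:]
    f = freqs[1:]
    if curve[0] < threshold:
        return UNRESOLVED
    below = np.where(curve < threshold)[0]
    if below.size == 0:
        return UNRESOLVED  # caller substitutes the Nyquist bound
    i = below[0]
    f0, f1 = f[i - 1], f[i]
    c0, c1 = curve[i - 1], curve[i]
    fc = f0 + (c0 - threshold) / (c0 - c1) * (f1 - f0)
    return 1.0 / fc


def frc_resolution(
    aligned,
    pixel_size: float = 5.0,
    n_splits: int = 20,
    seed: int | None = None,
    threshold: float = 1.0 / 7.0,
    field_size: float | None = None,
    smooth: int = 3,
) -> FRCCurve:
    """FRC resolution of a set of aligned structures.

    ``aligned`` is a collection of MoleculeLists (pooled) or a single pooled
    MoleculeList.  Each repeat randomly halves the pooled localizations,
    renders the two halves as unsmoothed histograms, and reads the 1/7
    threshold crossing; if the curve never crosses, the Nyquist bound
    2·pixel_size is reported with a warning, and if it starts below the
    threshold the split is unresolved (inf).
    """
    if isinstance(aligned, MoleculeList):
        coords = aligned.xyz[:, :2]
    else:
        mls = list(aligned)
        if len(mls) < 2 and (len(mls) == 0 or not isinstance(mls[0], MoleculeList)):
            raise ValueError("need aligned molecule lists")
        coords = np.vstack([ml.xyz[:, :2] for ml in mls])
    if coords.shape[0] < 100:
        raise ValueError(
            f"too few localizations ({coords.shape[0]}) for a stable FRC split"
        )
    if field_size is None:
        field_size = 2.0 * float(np.abs(coords).max()) + 10 * pixel_size
    rng = np.random.default_rng(seed)

    resolutions = []
    curves = []
    freqs = None
    n = coords.shape[0]
    for _ in range(n_splits):
        perm = rng.permutation(n)
        half = n // 2
        h1 = render_image(MoleculeList(coords[perm[:half]]), pixel_size,
                          field_size, blur_sigma=0.0).values
        h2 = render_image(MoleculeList(coords[perm[half:]]), pixel_size,
                          field_size, blur_sigma=0.0).values
        freqs, frc = _frc_single(h1, h2, pixel_size)
        if smooth > 1:
            frc = ndimage.uniform_filter1d(frc, size=smooth, mode="nearest")
        res = _threshold_crossing(freqs, frc, threshold)
        if math.isinf(res) and frc[1] >= threshold:
            logger.warning(
                "FRC curve never crossed %.3f; reporting the Nyquist bound "
                "%.1f nm", threshold, 2 * pixel_size,
            )
            res = 2.0 * pixel_size
        curves.append(frc)
        resolutions.append(res)
    resolutions = np.asarray(resolutions)
    finite = resolutions[np.isfinite(resolutions)]
    mean_res = float(finite.mean()) if finite.size else UNRESOLVED
    sd_res = float(finite.std()) if finite.size > 1 else 0.0
    return FRCCurve(
        spatial_frequency=freqs,
        correlation=np.mean(curves, axis=0),
        threshold=threshold,
        resolution=mean_res,
        n_splits=n_splits,
        resolution_sd=sd_res,
        per_split=resolutions,
    )


def frc_between(ml1: MoleculeList, ml2: MoleculeList, pixel_size: float = 5.0,
                field_size: float | None = None, threshold: float = 1.0 / 7.0,
                smooth: int = 3) -> tuple[np.ndarray, np.ndarray, float]:
    """FRC between two fixed half-data sets (no random splitting).

    With the two halves identical the correlation is 1 at every frequency
    and the Nyquist bound 2·pixel_size is reported with a warning.
    """
    coords = np.vstack([ml1.xyz[:, :2], ml2.xyz[:, :2]])
    if field_size is None:
        field_size = 2.0 * float(np.abs(coords).max()) + 10 * pixel_size
    h1 = render_image(ml1, pixel_size, field_size, blur_sigma=0.0).values
    h2 = render_image(ml2, pixel_size, field_size, blur_sigma=0.0).values
    freqs, frc = _frc_single(h1, h2, pixel_size)
    if smooth > 1:
        frc = ndimage.uniform_filter1d(frc, size=smooth, mode="nearest")
    res = _threshold_crossing(freqs, frc, threshold)
    if math.isinf(res) and frc[1] >= threshold:
        logger.warning("FRC never crossed the threshold; Nyquist bound reported")
        res = 2.0 * pixel_size
    return freqs, frc, res


def rotational_autocorrelation(
    img: PixelImage | np.ndarray,
    angle_step: float = 1.0,
    prominence: float = 0.05,
) -> AutocorrCurve:
    """Correlation of an image with itself rotated about the raster center.

    The image is circularly masked and mean-subtracted (within the mask)
    before correlating, and the curve is normalized so correlation(0°) = 1.
    Peaks are local maxima on angles in (0°, 180°] with at least the given
    prominence (fraction of the zero-angle value).
    """
    arr = img.values if isinstance(img, PixelImage) else np.asarray(img, dtype=float)
    n360 = 360.0 / angle_step
    if abs(n360 - round(n360)) > 1e-9:
        raise ValueError("angle_step must divide 360")
    m, n = arr.shape
    rr = np.arange(m) - (m - 1) / 2.0
    cc = np.arange(n) - (n - 1) / 2.0
    mask = np.hypot(rr[:, None], cc[None, :]) <= (min(m, n) / 2.0 - 0.5)
    base = np.zeros_like(arr, dtype=float)
    base[mask] = arr[mask] - arr[mask].mean()
    denom = float(np.sum(base**2))
    if denom == 0:
        raise ValueError("flat image has no rotational structure")

    angles = np.arange(int(round(n360))) * angle_step
    corr = np.empty(angles.size)
    for k, theta in enumerate(angles):
        corr[k] = float(np.sum(base * rotate_raster(base, theta))) / denom

    peaks_idx, props = signal.find_peaks(
        np.concatenate([corr, corr[:1]]),  # wrap so a peak at 360-step is seen
        prominence=prominence,
    )
    peaks = [
        (float(angles[i % angles.size]), float(corr[i % angles.size]))
        for i in peaks_idx
        if 0.0 < angles[i % angles.size] <= 180.0
    ]
    peaks.sort()
    return AutocorrCurve(angle=angles, correlation=corr, peaks=peaks)


def dominant_symmetry_peak(curve: AutocorrCurve) -> tuple[float, float]:
    """Angle and height of the dominant non-zero autocorrelation peak.

    For an N-fold symmetric image the autocorrelation is a comb with local
    maxima at every multiple of 360°/N whose heights agree to within
    sampling noise, so the raw argmax among them is not reproducible.  The
    dominant peak is therefore identified through the periodicity: the
    angular harmonic with the largest Fourier power over the full curve
    fixes the fold order n*, and the local maximum nearest the fundamental
    angle 360°/n* is reported (its measured position, not the nominal
    angle).  If no local maximum lies near the fundamental, the highest
    peak is returned.
    """
    if not curve.peaks:
        raise ValueError("no non-zero autocorrelation peaks found")
    c = curve.correlation - curve.correlation.mean()
    spectrum = np.abs(np.fft.rfft(c))
    # fold orders compatible with peaks on (0°, 180°]: n >= 2
    n_max = min(len(spectrum) - 1, 60)
    n_star = 2 + int(np.argmax(spectrum[2:n_max + 1]))
    fundamental = 360.0 / n_star
    near = [p for p in curve.peaks if abs(p[0] - fundamental) <= fundamental / 2]
    if near:
        return min(near, key=lambda p: abs(p[0] - fundamental))
    return max(curve.peaks, key=lambda p: p[1])
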