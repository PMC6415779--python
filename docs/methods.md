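# Methods

This note documents the models, estimators and numerical choices behind
`ringalign`, in the package's own terms: what is computed, under which
assumptions, with which defaults, and where the genuinely open design
decisions were settled.

## Data model

A *molecule list* is the native SMLM datum: an `(n, 2)` or `(n, 3)` array
of fluorophore coordinates in nm, optionally with a channel label and
photon counts.  Rasters rendered from it (`render_image`) are 2D histograms
on a square, even-dimensioned pixel grid centered on the coordinate origin,
optionally Gaussian-smoothed; the histogram mass before smoothing equals
the in-field localization count.  Raster row = y, column = x, y increasing
with row; the continuous raster center coincides with nm (0, 0).  All
rotations use the convention `[[cos, −sin], [sin, cos]]` acting on (x, y)
and `[[1,0,0],[0,cos,−sin],[0,sin,cos]]` on (x, y, z).

A per-structure alignment state (`StructureTransform`) composes, in this
fixed order: translate by −center → in-plane pre-rotation → anisotropic
scaling (the circularization) → x-axis tilt → in-plane rotation → shift.
With unit scales the rotational part is a ZXZ Euler factorization, so the
accumulated 3D alignment of any number of iterations fits the same record.

## Ellipse fitting and circularization

Structures are fitted to the full conic `Ax² + Bxy + Cy² + Dx + Ey + F = 0`
with the ellipse-constrained direct solve (Halir–Flusser scheme) on
centered, scale-normalized coordinates.  The printed two-axis form without
the cross term cannot represent a rotated ellipse, so the full conic is
what the geometric conversion (center, long axis a, short axis b,
orientation φ) actually requires.

The default *robust* fit approximates least absolute deviations of the
algebraic residual by iteratively reweighted least squares (weights
`1/max(|r|, 1e-12)`, at most 50 passes, convergence at 1e-8 coefficient
change).  Localization data contain outliers (nonspecific binding,
mislocalizations); on contaminated data the robust orientation error beats
plain least squares in ≳90% of paired replicates (tested).

Outlier removal uses the signed radial residual — point radius minus the
ellipse's polar radius `ab/√((b cos α)² + (a sin α)²)` along the point's
ray from the fitted center — and drops points more than k·SD (default
k = 1.5) from the mean residual.  Gaussian noise then retains ≈86.6% of
points, which the tests check against the normal-law value.  The pipeline
fits once, cleans once, refits once; residual SDs below 1e-6 nm (numerically
exact fits) trigger no removal.  Circularization translates by −center,
rotates the long axis onto x, and scales by (R/a, R/b) with R the mean of
(a+b)/2 over all structures.

**Arc-degeneracy guard.**  On heavily under-labeled rings the visible
clusters can span only part of the circle and the fitted ellipse may be
arbitrarily elongated even though the underlying structure class is at most
mildly elliptical (observed aspects for these organelles are ≲1.35).  Fits
with a/b > 1.5 are therefore treated as circles of radius (a+b)/2 —
isotropic normalization only.  Without this guard, wrong anisotropic
deformations of under-labeled circular rings scramble cluster angles and
visibly degrade the aligned average.

## Registration

Registration maximizes the Fourier-domain cross-correlation (equivalently
minimizes the intensity-scaled NRMSE; the optimal scaling α has the closed
form `Σf·g' / Σg'²`).  Images are mean-subtracted and tapered with a
*radial* raised-cosine window over the outer 5% of the inscribed circle —
radial so the window commutes with the rotation search.  Translation-only
registration (`dft_translation_register`) skips the taper: a taper fixed to
the raster biases a moving pattern's shift estimate by ~0.01 px, and the
classic upsampled-DFT scheme it follows uses none.

The coarse translation estimate is the integer-pixel peak of
`ifft2(F·conj(G))`; refinement evaluates the correlation on a ±1.5 px
neighborhood at 1/upsample px (default 1/100) by matrix-multiply DFT.  The
rotation search is exhaustive on a grid (default 1°); no sub-grid angle
refinement is performed, so angular resolution equals the grid step.  Ties
break toward the smallest angle, then the first (row-major) shift.

The iterative loop starts from the unweighted average of all inputs (no
external template), registers every *original* image to the current
reference each iteration — equivalent to composing incremental transforms,
without compounding interpolation error — and averages the aligned images
into the next reference.  Inside the loop the trial rotation is applied to
the reference with opposite sign and shared across all images of an
iteration (`s = R_θ t` maps the lag back to the moving frame); this
evaluates the identical objective on the identical grid and is covered by
an equality test against the rotate-the-moving-image implementation and an
exhaustive-search oracle.

## 3D alignment

Flat structures in random 3D orientations are aligned by adding one
exhaustive loop over a tilt φ about the x axis (rotation about the
structure centroid), rendering the x–y projection, and running the 2D
search; the (φ, θ, x₀, y₀) minimizing the NRMSE wins.  Selection across
tilts must use the NRMSE (normalized correlation), not the raw correlation
peak: tilting compresses the projection and raises its density, which
inflates raw correlation irrespective of pattern match.

Orientations outside the x-tilt circle are reachable only through the
iterated composition `R_z(θ_k) R_x(φ_k) ··· R_z(θ_1) R_x(φ_1)` (for flat
rings, a y-axis tilt equals a z-rotated x-tilt of a re-phased ring — the
Euler identity is tested exactly).  The coordinates are therefore
re-transformed between iterations (default 5), unlike the 2D loop.  With a
tilt grid of exactly {0} the routine delegates to the 2D loop on the
projections, making the reduction property exact.

**Gauge fixing.**  The mutual-alignment objective is invariant under one
rigid motion applied to every structure, so the iteration inherits an
arbitrary global gauge — in 3D it tends to settle at the mean tilt aspect
of the initial average rather than flat.  After the iterations, the
ensemble is rotated so the pooled cloud's smallest principal axis lies
along z (`global_detilt`), and the 2D pipeline re-centers the pooled ring
by a robust fit (`recenter`).  The benchmark protocol runners leave the
translation gauge untouched, as the original workflow does.

**Known limitations.**  Tilt precision is physics-limited: a tilt φ moves
a ring's extreme clusters by only `r(1 − cos φ)` (≈9 nm at 20° for
r = 150 nm), so at realistic noise the per-structure tilt landscape is
shallow and recovered tilts scatter by ~5–10°.  A single structure whose
residual tilt axis lies along y can linger for several iterations, since
each iteration corrects only the x-component and the 9-fold pattern
quantizes the in-plane re-orientation; ensemble symmetry recovery is
nevertheless robust (tested on tilts within ±60° and ±90°).

## Multicolor

One channel (chosen by the caller; in practice the higher-resolution one)
is aligned and each structure's transform — deformation scales included in
2D mode — is applied verbatim to the other channels.  In 3D mode the net
map is affine with the accumulated rotation as linear part, so
inter-channel distances are preserved exactly (tested to 1e-6 nm).  The
scheme is k-channel by construction.

## Simulator

Each structure places cluster centers at configured angles on each
channel's ring, drops clusters by labeling (exact count or independent
Bernoulli; a structure that would lose every cluster keeps one), draws
Poisson localization counts per retained cluster (mean 50), scatters them
by the intrinsic cluster size (default 10 nm SD; 0 in the pure-precision
presets), applies the pose — elliptical aspect, x-tilt, z-spin, in that
order, i.e. `p = R_z(θ) R_x(φ) diag(q,1,1) p₀ + t` — and finally adds
lateral/axial Gaussian localization noise in the lab frame.  Poses and
occupancies are recorded as ground truth; a seed makes runs bit-identical.

**Precision convention.**  The benchmark presets interpret their stated
localization precisions as FWHM figures (σ = value/2.355).  Read as
Gaussian SDs they are irreconcilable with the benchmark outcomes for *any*
algorithm: an SD of 60 nm attenuates the 9th angular harmonic of a 150 nm
ring by exp(−(9·60/150)²/2) ≈ 1.5·10⁻³, erasing the information the
alignment provably recovers, and an SD of 15 nm makes clusters 15° apart
(39 nm) unresolvable even under ground-truth alignment.  Under the FWHM
reading every benchmark outcome is reproducible.  `SimulationConfig`
defaults to SD semantics; the presets set `precision_convention="fwhm"`.

Simulator defaults chosen once where the protocols are silent: 50
localizations per cluster, 20 nm SD translation jitter ("small
translations"), tilts two-sided uniform on ±range, aspect ratios uniform
on [1.0, 1.35] for the semi-flexible presets (spanning the observed
369–494 nm diameter spread).  Not modeled: blinking/photophysics, repeated
appearances, background localizations, camera noise — so passing tests
demonstrate correctness of the alignment machinery under idealized
coordinate noise, not robustness to every artifact of real acquisitions.

## Metrics

**FRC.**  The pooled aligned localizations are randomly halved, each half
rendered as a plain 5 nm-pixel histogram (no smoothing — the localization
error is already in the coordinates, and added blur would just cancel in
the ratio at low frequency while suppressing the signal band), and the
ring-wise normalized correlation of the two FFTs is lightly smoothed
(3-bin moving average).  Resolution is the inverse frequency of the first
drop below 1/7; curves that never cross report the Nyquist bound
2·pixel_size with a warning, curves starting below the threshold are
unresolved.  The split is repeated (default 20×); the reported uncertainty
is the SD over splits — this package's definition, since frame-based
splitting is not possible on a coordinate table without frame metadata.

**Rotational autocorrelation.**  The image is circularly masked,
mean-subtracted within the mask, and correlated with itself rotated about
the raster center; the curve is normalized to 1 at 0°.  Peaks are local
maxima in (0°, 180°] above a prominence threshold (default 5% of the
zero-angle value; the benchmark runners use 3% to retain the weaker
secondary-period peaks of alternating-gap rings).

**Dominant peak.**  For a well-aligned N-fold ring the autocorrelation
peaks at all multiples of 360°/N agree to within ~1–3% even under
ground-truth alignment, so the raw argmax among them is sampling noise.
`dominant_symmetry_peak` instead determines the fold order from the
largest-power angular harmonic of the whole curve and reports the measured
local maximum nearest the fundamental 360°/n\* — a reproducible estimator
of "the peak that reveals the symmetry" that still reports a measured
position, not a nominal one.

## Benchmark problem sizes

The 2D benchmark protocols run at full scale (20 structures, 10
iterations, 1° rotation grid, 1/100 px refinement).  The exhaustive
tilt-by-rotation 3D search is quadratic in grid resolution, so the 3D
benchmark runs use coarsened grids chosen as a sensible accuracy/cost
point for this structure class (3° rotation step, 5–6° tilt step over
±72–75°, upsample 10); the two-color protocol, whose structures carry no
tilt, uses the exact {0}-grid reduction.  The FRC deformation-benefit
comparison uses 10 structures, 6 iterations, 2° steps and 5 splits per
replicate over 20 seeded replicates.
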