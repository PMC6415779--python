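# ringalign

Deformed alignment and averaging of single-molecule localization microscopy
(SMLM/STORM) images of **semi-flexible ring-shaped structures** — ciliary
distal appendages, centrioles, nuclear pores and similar organelle-scale
assemblies that keep their symmetry but vary in size and shape from copy to
copy.

SMLM data are lists of fluorophore coordinates, and individual structures
are under-labeled and heterogeneous, so quantitative conclusions usually
require aligning and averaging tens of structures.  Rigid registration
blurs semi-flexible structures; template-based alignment biases the result.
This package implements a template-free, deformation-aware pipeline:

1. **Circularization** — each structure's localizations are fitted to an
   ellipse via the full conic `A x² + B xy + C y² + D x + E y + F = 0`
   (robust least-absolute-deviations fit by default), radial outliers
   beyond 1.5 SD are removed, and the coordinates are rescaled
   `x → x/a·R`, `y → y/b·R` so every ring becomes a circle of the common
   radius `R` (the mean of all fitted radii).
2. **Fourier-domain registration** — each rendered image `g` is registered
   to the reference `f` by minimizing the normalized RMS error

   `E² = min over (α, x₀, y₀, θ)  Σ|α·g_θ(x−x₀, y−y₀) − f(x, y)|² / Σ|f|²`

   equivalently maximizing the cross-correlation `r_fg` in the Fourier
   domain: an exhaustive rotation search (0–359° in 1° steps), an FFT for
   the integer-pixel correlation peak, and a matrix-multiply DFT that
   refines the translation to 1/100 pixel.
3. **Template-free iteration** — the first reference is the plain average
   of all images; every iteration re-registers each image and averages the
   aligned set into the next reference (10 iterations in 2D).
4. **3D tilt search** — for randomly oriented flat structures, an extra
   exhaustive loop rotates the coordinates about the x axis
   (`y' = y cos φ − z sin φ`, `z' = y sin φ + z cos φ`) before the in-plane
   search on the x–y projection; no deformation is applied in 3D.
5. **Multicolor transfer** — one channel is aligned; each structure's
   transform is applied verbatim to its other channels, preserving the
   inter-channel geometry being measured.
6. **Metrics** — Fourier Ring Correlation (1/7 threshold, random half-data
   splits) for resolution, and rotational autocorrelation for symmetry
   detection (an N-fold ring peaks at multiples of 360°/N).

A seeded simulator generates all the benchmark conditions: N-fold or
alternating-gap cluster rings, configurable labeling efficiency, lateral
and axial localization precision, random in-plane pose, bounded x-axis
tilts, and two-color double-ring geometries with recorded ground truth.

## Worked example

Align 20 simulated under-labeled rings (9 cluster sites, 5 labeled each,
so no single structure shows the full symmetry):

```python
from ringalign.protocols import run_ring_protocol_2d

report = run_ring_protocol_2d("ring9-underlabeled", seed=1)
print(report.result.radius, report.autocorr.peaks, report.dominant_angle)
```

or `python examples/align_2d_rings.py`, which prints:

```
aligned structures : 20
common radius R    : 144.2 nm
final mean NRMSE   : 0.680
autocorr peaks     : [(41, 0.6), (81, 0.53), (122, 0.5), (162, 0.29)]
dominant peak      : 41 deg
```

The fitted common radius (144 nm) matches the simulated 150 nm rings to
within the under-labeling bias, and the autocorrelation of the averaged
image peaks at ~40° and its multiples — the signature of the 9-fold
symmetry that was invisible in any single structure.  The other examples
(`align_3d_tilted.py`, `two_color_transfer.py`,
`frc_deformation_benefit.py`) demonstrate the tilt search, the two-color
transfer (recovering a 20° inter-ring phase offset and 100 nm axial gap),
and the FRC improvement from deformation.

## Command line

```bash
ringalign simulate --preset ring9-underlabeled --seed 1 --out sim/
ringalign align2d sim/sim0*.csv --out aligned/          # add --no-deform for the rigid baseline
ringalign align3d sim3d/*.csv --out aligned3d/ --reference-channel 1
ringalign metrics aligned/*_aligned.csv --out metrics/
```

Molecule lists are plain CSV/TSV with columns `x_nm, y_nm[, z_nm][,
channel][, photons]`; every run writes aligned lists, a delimited
per-iteration report, a 16-bit TIFF average, and a JSON manifest.

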