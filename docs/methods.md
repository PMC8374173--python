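# Methods

## Measurement model

The observable is the background-corrected, area-scaled, exposure-
normalised ROI intensity `I = (Ī_s − Ī_B̄)·A/s` (counts·µm²·s⁻¹). Three
modelling choices deserve explanation:

* **Background is a mean of per-ROI means**, not a pooled pixel mean. The
  background patches are drawn by hand near the feature and vary in size;
  mean-of-means weights each patch equally and makes the estimate
  independent of patch area. Defaults follow the experimental practice of
  five patches around a droplet and three around a crater, but any count
  ≥ 1 is accepted.
* **`A` is the geometric area** (shoelace for polygons, πab for ellipses),
  not the mask pixel count, because the formula multiplies by a continuous
  area in µm². The pixel mask is used only to average intensities. The two
  areas agree to well under 2 % for ROIs with ≥ 1000 interior pixels.
* **Negative corrected intensities are preserved** (with a warning).
  Clamping at zero would bias the calibration near the detection floor.

Pixel membership uses a centre-in convention: a pixel belongs to an ROI iff
its centre lies inside the shape, with boundary ties broken half-open
(top/left in, bottom/right out) so adjacent ROIs tile exactly. Pixel (0,0)
has its centre at coordinate (0.0, 0.0). The convention is arbitrary but
stated and deterministic; tests check it against brute-force point-in-shape
oracles.

Saturated measurements (more than 1 % of ROI pixels at full scale by
default) are excluded from calibration fits and flagged in reports; the
experimental remedy is a shorter exposure, which the exposure
normalisation in `I` makes transparent.

## Calibration

Standards are droplets of known content (`pmol = C·V·10⁻³`; µM × nL).
The relation between `I` and picomoles is summarised by `I = a·pmol^b`,
fitted by **unweighted OLS on (ln pmol, ln I)**: data spanning four decades
with multiplicative (photon/illumination) error are homoscedastic on the
log scale, where the power law is a straight line. `se_b` is the slope's
standard error; `se_a = a·se(intercept)` by the delta method. A direct
nonlinear least-squares fit on the raw scale is available
(`method="nls"`) as a sensitivity check, seeded from the log-log solution.

Two aggregation modes mirror the two experimental designs: with few
replicates per concentration the per-concentration mean intensities are
fitted (`mean-per-concentration`); with many replicates every droplet
enters individually (`all-droplets`). Blank (buffer-only) controls are
excluded from the fit — their logarithm is undefined — but summarised, as
a check that the background is near zero. Replicate spread is reported
with Tukey statistics: hinge quartiles (median included in both halves for
odd n) and fences at 1.5·IQR. Points outside the fences are flagged as
outliers but retained in the fit by default, since flagging and excluding
are different decisions and exclusion is not assumed.

Inversion is `pmol = (I/a)^{1/b}`; estimates outside the picomole range
spanned by the standards are flagged as extrapolation. Non-positive
intensities yield no estimate (below detection). Measurements taken at a
given objective must be inverted with that objective's calibration.

## Crater analysis

Crater axes come from the **moment-equivalent ellipse** of the crater ROI
mask (same centroid and second central moments as the pixel region), which
is what the familiar interactive fit-ellipse tools compute; a direct
least-squares conic fit to boundary points is also provided. Pixelation
biases the mask-based axes by ≲ 1 % for craters larger than ~20 px, which
propagates as ≲ 3 % into the cubed impactor volume.

Crater diameter is the mean of the axes. The particle–crater calibration
(scalar ratio or monotone table with linear interpolation, per target
material × velocity) is **always an input**: such calibrations come from
separate microsphere impact experiments and are not built into the
package. Out-of-table queries clamp to the table edge with a warning.

The impactor load is implemented in the general concentration-dependent
form `C·(π/6)D³·10⁻⁹` pmol; a regression test pins the standard-
concentration special case `(π/6)D³·10⁻⁷` at C = 100 µM to machine
precision. Efficiencies above 100 % are physically impossible and are
reported with a warning rather than clamped, because they diagnose a
calibration mismatch.

The dry/humid artifact screen classifies a residue as an artifact when its
dry integrated intensity exceeds `ratio_threshold` (default 0.5) of its
humid intensity. Dried tracer films retain only a few percent of their
humid emission, so genuine residues sit far below the threshold; typical
contaminants (dust, metal debris) are humidity-insensitive and sit near 1.
The threshold is configurable and logged. Image triples are assumed
co-registered (ROIs are drawn once and reused); no registration is
performed.

## Synthetic scenes

The generator emulates the two experimental designs with known ground
truth:

* droplet series — by default 10 nM, 100 nM, 1 µM, 10 µM droplets
  (3 replicates plus a blank; the high-replicate variant uses 24), 50 nL
  droplets spreading to ~500 µm spots (5 nL to ~250 µm, cube-root volume
  scaling), exposures of 10 s at ≤ 100 nM, 1 s at 1 µM and 0.1 s at 10 µM;
* crater scenes — particle diameters drawn uniformly (default 8–31 µm,
  giving ~24–93 µm craters at the default 3:1 synthetic crater:particle
  ratio), capture efficiencies uniform in a configurable range, residue
  drawn as an ellipse at 90 % of the crater outline.

Deposits are rendered with 4×4 supersampled edge coverage so the total
excess count equals `brightness_per_pmol · pmol · s / px²` exactly up to
quadrature; a parabolic "radial-falloff" profile with the same total flux
is available for robustness checks. `brightness_per_pmol`
(default 10¹⁰ counts·µm²·s⁻¹·pmol⁻¹, chosen to use the 16-bit range
without saturating at the default exposures) is an arbitrary emission
constant — the calibration workflow must estimate and cancel it, which is
what the closed-loop tests verify. The dry companion image scales each
deposit by `humidity_contrast` (default 0.02; set to 1 to emulate a
contaminant). Noise is Poisson by default (photon-limited CCD), with
Gaussian and noiseless options; all randomness flows from the scene seed
and renders are bit-reproducible.

What the generator does **not** emulate: optics (PSF, vignetting,
flat-field error), pH and photobleaching effects on the dye, humidity
kinetics (the dry/humid switch is binary), residue spreading beyond the
crater rim, and crater detection (ROIs are inputs, as in the real
workflow, where they are drawn on the bright-field image). Passing
closed-loop tests therefore demonstrates the correctness of the
quantitation chain, not robustness to those real-world effects.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data:
a 13-droplet calibration series (~560 px canvases) and 50 single-crater
scenes (~100–360 px canvases), which complete in seconds. Closed-loop
recovery on these conditions achieves a median absolute relative
efficiency error of ~0.3 % noiseless and ~0.6 % under Poisson noise —
the residual is dominated by integer pixel quantisation and mask/geometry
edge effects, not by the estimator.

Floats in output CSV/JSON are written with 9 significant digits and rows
are sorted by label, so identical inputs reproduce byte-identical outputs.
Degenerate inputs (empty masks, non-positive areas or exposures, collinear
ellipse points, fewer than two usable concentrations) raise informative
errors rather than propagating NaNs.

## Known limitations

* The mask-based ellipse axes carry a small pixelation bias (~1 % at
  20 px); sub-pixel boundary extraction is out of scope.
* The pixel scale per objective must be supplied in configuration; it
  cannot be recovered from the images.
* Re-deriving the published calibration constants requires the raw
  per-droplet measurement tables distributed as supplementary material;
  the corresponding acceptance test documents the expected file layout
  (`data/supplementary/standards_{10x,20x}.csv`) and fails until they are
  provided.
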