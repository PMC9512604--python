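# Methods

## The model

The pipeline treats mass detection as a one-dimensional problem on the
gray histogram. A mammographic mass is a bright, compact region whose
pixels form a second population high on the gray axis; because the mass
is small relative to the breast, that population is only a faint bump on
the shoulder of the parenchyma mode and cannot be found by inspecting
counts directly. What *can* be found robustly is the abrupt change of the
histogram where the new population begins — a singular point.

Singular points are localized with a wavelet constructed as the
derivative of a smoothing kernel: if `δ_s` is a lowpass kernel at scale
`s`, then `W f = s · d/dz (f ∗ δ_s)` is large exactly where the smoothed
signal turns, and strict local maxima of `|W f|` (modulus maxima) mark
transitions. The smoothing kernel is the à trous (undecimated) cascade of
a Daubechies scaling filter — order N selects how aggressively counting
noise is averaged away — followed by a central difference. Large orders
suppress spurious maxima from counting noise, which is singular
everywhere but carries little modulus at coarse scales; N = 20, scale
level 3 are the defaults, and orders 5/10/15/20 can be compared with
`compare_wavelet_orders`.

Three numerical choices make the 1-D transform behave:

- **Variance stabilization.** The transform is applied to `sqrt(counts)`.
  Histogram counting noise is Poisson — its magnitude tracks the count —
  so on raw counts the noise floor near the mode dwarfs the lump bump's
  signal far from it. The square root makes the noise level uniform
  (sd ≈ 1/2) across the gray axis, and since it is positively
  homogeneous, thresholds remain exactly invariant to uniform count
  scaling.
- **Shift calibration.** Filtering delays features by the filter's group
  delay. The correction is calibrated once per (wavelet, level) on a unit
  step and applied inside the padded support, after which a step's
  modulus maximum lands at the step's own index for every position; this
  is the operational meaning of mapping coefficient-space features back
  to signal positions.
- **Boundary extension.** Signals are extended by edge replication. The
  level-3 equivalent filters of high orders are longer than the 256-bin
  signal, so a mirrored extension would fold copies of interior structure
  into the filter support and displace maxima near the boundaries;
  constant continuation adds no structure.

The noise floor below which a local maximum is discarded is
`noise_factor · σ̂ · ‖k‖₂` (default factor 3), with `σ̂` estimated from
the median absolute first difference of the signal over nonzero
differences and `‖k‖₂` the equivalent filter norm — a three-sigma rule
propagated through the transform. A signal with fewer than 8 nonzero
differences is treated as noiseless (its few differences are edges, not
noise).

## Threshold selection

Candidate singular points are those strictly above the histogram mode
(masses are bright relative to the parenchyma bulk). Rising-edge
candidates — where counts increase with gray level, marking the onset of
a new population — are tried before falling edges, in descending modulus.
For each candidate the threshold is the modulus minimum between it and
the nearest singular point on its dark side (or the mode): the quiet
point between two transitions, which on a two-population histogram is the
inter-mode valley. Two plausibility rules guard the decision:

- a threshold is accepted only if at most `max_bright_fraction` (10%) of
  masked pixels lie above it, because a mass population is small — on an
  image with no mass, the only singular points are the mode's own
  shoulder and the walk would otherwise threshold half the breast;
- when no candidate qualifies, the decision falls back to Otsu's
  threshold restricted to levels above the mode, floored at
  mode + 3σ of the mode's half-width (a unimodal histogram would
  otherwise be split inside its own bright flank), and is flagged
  `fallback`.

On sampled two-Gaussian mixtures with ≥ 6 pooled-sd separation the
selected threshold lands within a few gray levels of the brute-force
count minimum between the modes (mean |error| ≈ 4–5 levels over seeded
draws; the test suite asserts ≤ 10).

## Preprocessing

Gray-range normalization follows `K = (P − min P)·255/(max P − min P)`
with half-up rounding; it is idempotent and invariant to positive affine
intensity changes, and a constant image is rejected as degenerate.
Texture suppression soft-thresholds all 2-D detail bands of a db4
level-2 decomposition at `threshold_scale · σ̂` with σ̂ the MAD estimate
from the finest diagonal band (defaults: scale 3.0). The breast mask is
Otsu + largest component + hole filling; pectoral removal looks for the
brightest bright-on-bright component (second Otsu inside the top quarter
of the breast) touching the breast's top corner, grows it down by
geodesic propagation, and dilates by 4 px to take the smoothing halo at
the wedge boundary. The pipeline additionally erodes the working mask by
`edge_margin` = 4 px: soft-threshold denoising overshoots at the
breast/background step, and the bright ring just inside the skin line
otherwise produces boundary candidates. Normalize-then-smooth is the
default order (configurable); smoothing first changes little because
normalization is affine.

## Rough segmentation

Masked pixels at or above the threshold are labeled with 8-connectivity.
Candidates are kept when `min_area ≤ area ≤ max_area` and the
length/width ratio of the minimum-area rotated enclosing rectangle is at
most `max_aspect` (elongated components are vessels or folds, not
masses). Defaults, quoted at 1024×1024 and scaled by image area:
min_area 600 px (admits radii ≳ 14 px, half the smallest typical
annotated mass radius, while rejecting the correlated noise specks that
survive denoising), max_area 120 000 px, max_aspect 2.5. Rejected
candidates stay in the output with status `rejected` for reporting.

## Refinement

`choose_method` routes by boundary contrast (region mean minus the mean
of a 3-px outer ring): ≥ 25 gray levels → region growing, else the
localized contour.

**Region growing** is breadth-first from the candidate centroid snapped
to the nearest member pixel: a pixel joins when 8-adjacent to the region
and within `tolerance` (25) of the running region mean, updated after
every admission. A `fixed_mean` switch tests against the seed intensity
instead, in which case the result is exactly the connected component of
the admissible set — verified bit-for-bit against an independent flood
fill.

**Localized active contour.** The energy is
`ω·length + w·area + σ₁ Σ_inside (I − j₁)² + σ₂ Σ_outside (I − j₂)²`
with `j₁(y), j₂(y)` the inside/outside means within a disk of
`local_radius` (15 px) centered at each pixel — the model parameters
change from point to point, which is what lets the curve survive
background inhomogeneity that defeats the global two-phase model. The
minimization is gradient descent on a level-set embedding φ (negative
inside, smoothed Heaviside of width ε = 1.5 px) with three properties
worth stating:

- The gradient is **exact**: the pixel-centered local means are not the
  energy's per-pixel minimizers, so their dependence on the curve is
  differentiated too (the chain terms reduce to disk convolutions), and
  the length term's discrete co-area proxy is differentiated by its
  exact adjoint (central differences; the δ′ term that cancels in the
  continuum does not cancel on the grid). With an exact gradient, the
  backtracking line search (start dt = 0.45 px, halve on uphill, reject
  after 10 halvings) guarantees the recorded energy is non-increasing
  across accepted iterations.
- φ is re-initialized to an approximate signed distance (EDT with a
  half-pixel offset so |∇φ| ≈ 1 across the zero crossing) every 20
  iterations, accepted only when it does not push the energy uphill.
- Evolution runs on a crop around the initial mask (margin
  2·local_radius + 10) — the model is local by construction and the crop
  bounds cost and wandering. The global-mean comparison variant
  (`localized=False`) sees the full frame, since its statistics are
  global by definition.

Stopping: max_iter 500, or the zero set moves less than `tol` = 0.5 px
(Hausdorff) over a 10-iteration window, or no downhill step exists. The
length weight ω defaults to 5·10⁻⁴·255² ≈ 33: sweeps on blurred-disk
phantoms (noiseless and noise sd 8) put the best overlap at ω ≈ 30–70,
with much larger weights freezing the curve. σ₁ = σ₂ = 1, w_area = 0.

## Evaluation

A candidate hits a truth circle when its centroid lies inside it
(default), or under an overlap rule (|candidate ∩ disk| / min(areas) ≥
0.3). Matching is greedy by descending candidate area, one candidate per
truth lump; unmatched surviving candidates are false positives. The
report gives the per-lump detection rate (matched / truth lumps), the
per-image rate (lump-bearing images with every lump matched), false
positives per image, and the count of matched lumps whose refinement
converged ("boundaries extracted"). Rates with an empty denominator are
reported as undefined, never as zero.

## Synthetic phantoms

`generate` renders: a half-elliptical breast (semi-axes 0.46·h, 0.78·w,
attached to the left edge) at `breast_level` 120 on background 10;
additive Gaussian noise; an optional pectoral wedge (+30) in the top-left
corner; gently curved bright polylines (+15, width 1–2 px) standing in
for vessels; and disks of +`contrast` blurred by `edge_sigma` for the
lumps, each with an exact ground-truth circle. Suites map difficulty to
(contrast, edge_sigma, noise_sd) = easy (60, 1, 4), medium (35, 3, 8),
hard (20, 5, 12); about 80% of images carry exactly one lump. The default
canvas is 256×256 so a full suite runs in seconds; area-based config
defaults scale with image size.

What the phantoms do **not** emulate: parenchymal texture (the breast
interior is flat plus white noise), spiculated or calcified lesions,
overlapping structures, scanner artifacts, and realistic skin-line
geometry. Passing the suite therefore demonstrates the mechanism —
histogram-valley thresholding, shape filtering, growth and contour
refinement behave as designed — not clinical performance; on real
mammograms the histogram is far less bimodal and detection rates will be
lower, which is why the evaluation module also ingests real MIAS-style
archives when the user supplies them.

Two generator-design notes. Vessel stand-ins use small angular diffusion
(0.05 rad/step) so they are genuinely elongated: the aspect-ratio filter
is the pipeline's defense against vessels, and a tangled random walk
would present as a compact blob no real vessel resembles. Lump placement
rejects overlaps and keeps every lump fully inside the breast, so each
ground-truth circle is unambiguous.

## Degenerate inputs and determinism

Constant images, empty masks, and single-bin histograms raise a
degenerate-input error; batch runs record the failure and continue. The
pipeline contains no randomness — identical input, config and seed give
byte-identical candidate output; the only random number generator in the
package is the phantom generator's, seeded explicitly.

## Known limitations

- The histogram method is blind to masses whose gray range overlaps the
  parenchyma bulk (no singular point exists); the hard-difficulty suite
  shows the onset of such misses.
- Thresholding is global per image: two lumps at very different
  brightness levels yield one threshold, segmenting only the brighter
  cleanly.
- The pectoral-wedge heuristic assumes a wedge touching a top corner of
  the breast; unusual positioning falls back to leaving it in place,
  where the area/aspect filters and the bright-fraction guard limit the
  damage.
- Region growing with a running mean can leak through low-contrast necks
  connecting a lump to bright tissue; `max_pixels` (4 × max_area) caps
  the leak.
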