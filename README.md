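# mammowave

Detection and segmentation of masses ("lumps") in screening mammograms by
wavelet analysis of the gray-level histogram, with boundary refinement by
seeded region growing or a localized active contour.

Masses appear in a mammogram as bright, roughly compact regions whose
pixel population forms only a small bump high on the image's gray
histogram — invisible next to the much larger parenchyma mode. The
pipeline implemented here finds that bump's onset as a *singular point* of
the histogram and thresholds at the valley below it:

1. **Preprocess** — stretch the gray range onto [0, 255]
   (`K = (P − min P)·255/(max P − min P)`), suppress fine texture
   (capillaries, skin lines) by soft-thresholding 2-D wavelet detail
   coefficients, and mask the breast, optionally removing the
   pectoral-muscle wedge.
2. **Histogram wavelet transform** — recompute the gray histogram inside
   the mask and apply an undecimated 1-D wavelet transform built as the
   *derivative of a smoothing kernel* (Daubechies scaling filter, order
   N = 20 by default, dyadic scale 3): `W f = s · d/dz (f ∗ δ_s)`. Abrupt
   changes of the histogram appear as strict local maxima of |W| (modulus
   maxima); filter-induced shift is removed by a unit-step calibration so
   a transition is localized at its own gray level.
3. **Threshold selection** — among singular points above the histogram
   mode, prefer rising edges (the onset of a bright population), walk to
   the modulus minimum on the dark side, and threshold there. If no
   plausible singular point exists, fall back to a restricted Otsu
   threshold, flagged as such.
4. **Rough segmentation** — binarize, label 8-connected components, and
   keep candidates whose pixel area and minimum-enclosing-rectangle
   length/width ratio are lump-like.
5. **Refinement** — candidates with sharp contrast are grown from a seed
   (running-mean region growing); fuzzy-edged candidates are refined by a
   localized two-phase active contour minimizing

   `G(B) = ω·length(B) + w·area(B) + σ₁∫inside (H−j₁)² + σ₂∫outside (H−j₂)²`

   where `j₁(x), j₂(x)` are inside/outside means within a disk window
   around each point, so intensity inhomogeneity that defeats the global
   two-phase model does not drag the boundary away.
6. **Evaluation** — candidates are matched to circle-style ground truth;
   the report gives the detection rate (per lump and per image) and false
   positives per image.

A seeded phantom generator (`mammowave.synthetic`) renders breast-shaped
images with known lumps, vessels, and a pectoral wedge so the whole
pipeline is testable without external data. Real MIAS-style archives
(1024×1024 PGM plus a whitespace-separated annotation file) are supported
by the same readers.

## Worked example

```python
from mammowave import detect_image, generate_suite, run_batch

# one phantom with a single lump
(image, mask, truths), = generate_suite(1, "easy", seed=3)
result = detect_image(image)
print("threshold:", result.threshold.threshold)
print("candidates:", [(c.label, c.area, round(c.boundary_contrast, 1))
                      for c in result.surviving])

# a full 20-image suite, scored against the generator's ground truth
report = run_batch(generate_suite(20, "easy", seed=42))
print("detection rate:", report.detection_rate)
print("FP/image:", report.fp_per_image)
```

prints

```
threshold: 230
candidates: [(1, 289, 50.6)]
detection rate: 1.0
FP/image: 0.0
```

The threshold (gray level 230) falls in the valley between the parenchyma
mode and the lump's histogram bump; the single surviving candidate is the
lump (289 px, boundary contrast ~51 gray levels), and over the 20-image
suite every lump is found with no false positives.

The same pipeline runs from the shell:

```sh
mammowave synth --n 20 --difficulty easy --seed 42 --outdir data/
mammowave detect data/syn000.pgm --out runs/syn000
mammowave batch list.txt --truth data/info.txt --out runs/
mammowave eval --pred runs/ --truth data/info.txt --out report.json
```

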