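"""Intensity normalization, wavelet denoising, and breast/pectoral masking.

Mammograms arrive with inconsistent dynamic range, fine bright texture
(capillaries, skin folds) and a bright pectoral-muscle wedge, all of which
disturb gray-histogram analysis. This module stretches the gray range onto
[0, 255], suppresses fine texture by soft-thresholding 2-D wavelet detail
coefficients, and builds a breast-region mask with optional pectoral
removal. Everything downstream (histogram, thresholding, candidate search)
operates inside that mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .image_io import GrayImage

__all__ = [
    "BreastMask",
    "DegenerateInputError",
    "normalize",
    "wavelet_smooth",
    "breast_mask",
]


class DegenerateInputError(ValueError):
    """Raised when an input admits no meaningful processing (e.g. constant image)."""


@dataclass
class BreastMask:
    """Binary breast-region mask; pectoral wedge excluded when removed."""

    mask: np.ndarray
    includes_pectoral: bool = True

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        frac = self.mask.mean()
        if frac < 0.01:
            raise DegenerateInputError(
                f"breast mask covers only {frac:.2%} of the image (< 1% minimum)"
            )

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def normalize(image: GrayImage) -> GrayImage:
    """Stretch intensities onto the full [0, 255] range.

    K = (P - min P) * 255 / (max P - min P), rounded half-up. Idempotent,
    and invariant to positive affine changes of the input intensities.
    A constant image leaves the stretch undefined and is rejected.
    """
    p = image.pixels.astype(np.float64)
    lo, hi = p.min(), p.max()
    if hi == lo:
        raise DegenerateInputError("constant image: gray-range normalization undefined")
    k = np.floor((p - lo) * 255.0 / (hi - lo) + 0.5).astype(np.uint8)
    return GrayImage(pixels=k, source_id=image.source_id)


def wavelet_smooth(
    image: GrayImage,
    wavelet_name: str = "db4",
    level: int = 2,
    threshold_scale: float = 3.0,
) -> GrayImage:
    """Suppress fine texture by soft-thresholding 2-D wavelet details.

    The noise scale is estimated from the finest diagonal detail band as
    sigma = median(|d|) / 0.6745 (the usual robust MAD estimator), and every
    detail coefficient is soft-thresholded at ``threshold_scale * sigma``.
    ``threshold_scale = 0`` reproduces the input up to rounding. The
    approximation band is untouched, so the image mean is essentially
    preserved.
    """
    if threshold_scale < 0:
        raise ValueError("threshold_scale must be nonnegative")
    h, w = image.pixels.shape
    if level < 1 or level > int(np.floor(np.log2(min(h, w)))):
        raise ValueError(f"decomposition level {level} invalid for a {h}x{w} image")
    data = image.pixels.astype(np.float64)
    coeffs = pywt.wavedec2(data, wavelet_name, level=level, mode="symmetric")
    finest_diag = coeffs[-1][2]
    sigma = np.median(np.abs(finest_diag)) / 0.6745
    t = threshold_scale * sigma
    out = [coeffs[0]]
    for cH, cV, cD in coeffs[1:]:
        out.append(tuple(pywt.threshold(c, t, mode="soft") for c in (cH, cV, cD)))
    rec = pywt.waverec2(out, wavelet_name, mode="symmetric")[:h, :w]
    pixels = np.floor(np.clip(rec, 0, 255) + 0.5).astype(np.uint8)
    return GrayImage(pixels=pixels, source_id=image.source_id)


def breast_mask(
    image: GrayImage,
    remove_pectoral: bool = False,
    external_mask: np.ndarray | None = None,
) -> BreastMask:
    """Segment the breast region; optionally subtract the pectoral wedge.

    Background is split off by Otsu's threshold; the largest connected
    foreground component is kept and its holes filled. The pectoral muscle —
    when requested — is found as the brightest connected bright region
    (second Otsu, within the breast and restricted to the top quarter of
    rows) that touches a top image corner, and is subtracted.

    An externally supplied mask (nonzero = breast) bypasses the Otsu step
    but still goes through pectoral removal.
    """
    px = image.pixels
    if external_mask is not None:
        fg = np.asarray(external_mask).astype(bool)
        if fg.shape != px.shape:
            raise ValueError("external mask shape differs from image shape")
    elif px.min() == px.max():
        fg = np.ones_like(px, dtype=bool)  # all-flat: everything is foreground
    else:
        thr = threshold_otsu(px)
        fg = px > thr
        if not fg.any():
            raise DegenerateInputError("empty foreground after Otsu thresholding")
        lab = label(fg, connectivity=2)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        fg = lab == sizes.argmax()
        fg = ndimage.binary_fill_holes(fg)
    includes_pectoral = True
    if remove_pectoral:
        wedge = _pectoral_wedge(px, fg)
        if wedge is not None:
            fg = fg & ~wedge
            includes_pectoral = False
    return BreastMask(mask=fg, includes_pectoral=includes_pectoral)


def _pectoral_wedge(px: np.ndarray, breast: np.ndarray) -> np.ndarray | None:
    """Locate a bright wedge touching a top corner, or None if absent."""
    h, w = px.shape
    top = np.zeros_like(breast)
    top[: h // 4, :] = True
    roi = breast & top
    vals = px[roi]
    if vals.size < 16 or vals.min() == vals.max():
        return None
    try:
        thr = threshold_otsu(vals)
    except ValueError:
        return None
    bright = np.zeros_like(breast)
    bright[roi] = px[roi] > thr
    lab = label(bright, connectivity=2)
    best, best_mean = None, -np.inf
    corner_span = max(2, w // 8)
    breast_top = int(np.nonzero(breast.any(axis=1))[0][0])  # breast may not reach row 0
    for region_id in range(1, lab.max() + 1):
        comp = lab == region_id
        rows, cols = np.nonzero(comp)
        touches = (rows.min() <= breast_top + 3) and (
            cols.min() < corner_span or cols.max() >= w - corner_span
        )
        if not touches:
            continue
        m = px[comp].mean()
        if m > best_mean:
            best, best_mean = comp, m
    if best is None:
        return None
    # grow down the full wedge: extend the bright component beyond the top
    # quarter by geodesic dilation within similarly bright breast pixels
    lo = px[best].min()
    candidate = breast & (px >= lo)
    grown = ndimage.binary_propagation(best, mask=candidate)
    # take the smoothing halo at the wedge boundary along with the wedge
    grown = ndimage.binary_dilation(grown, iterations=4)
    return grown
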