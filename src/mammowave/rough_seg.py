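"""Rough segmentation: thresholding plus shape filtering of candidates.

Binarizing the breast at the histogram-derived threshold yields bright
connected components; true lumps are compact, mid-sized blobs, whereas
vessels, skin folds and edge artifacts are small, huge, or elongated.
Candidates are therefore filtered by pixel area and by the length/width
ratio of their minimum-area enclosing rectangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint
from skimage.measure import label, regionprops

from .image_io import GrayImage
from .preprocess import BreastMask

__all__ = ["CandidateRegion", "binarize_and_label", "filter_candidates", "min_area_rect"]

# defaults quoted at the 1024x1024 reference scale; scaled by image area.
# min_area admits lumps of radius >= ~14 px at reference scale (half the
# smallest MIAS-style annotated radius of ~20 px, for margin) while
# rejecting the noise specks that survive denoising
DEFAULT_MIN_AREA = 600
DEFAULT_MAX_AREA = 120_000
DEFAULT_MAX_ASPECT = 2.5
REFERENCE_AREA = 1024 * 1024


@dataclass
class CandidateRegion:
    """A connected bright component and its shape statistics."""

    label: int
    pixel_set: np.ndarray  # (n, 2) array of (row, col)
    area: int
    centroid: tuple[float, float]
    min_rect: tuple[float, float, float]  # (length, width, angle_deg), length >= width
    aspect_ratio: float
    mean_intensity: float
    boundary_contrast: float
    status: str = "rough"  # rough | refined | rejected

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "area": self.area,
            "centroid": [float(c) for c in self.centroid],
            "min_rect": [float(v) for v in self.min_rect],
            "aspect_ratio": float(self.aspect_ratio),
            "mean_intensity": float(self.mean_intensity),
            "boundary_contrast": float(self.boundary_contrast),
            "status": self.status,
        }


def min_area_rect(points: np.ndarray, axis_aligned: bool = False) -> tuple[float, float, float]:
    """Minimum-area enclosing rectangle of pixel centers.

    Returns (length, width, angle_deg) with length >= width; the rotated
    rectangle comes from the convex hull's oriented envelope. Degenerate
    point sets (single pixel, collinear pixels) get width 0 treated as 1
    pixel so the aspect ratio stays finite for 1-pixel-wide lines.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if axis_aligned:
        span = pts.max(axis=0) - pts.min(axis=0) + 1.0
        length, width = max(span), min(span)
        return float(length), float(width), 0.0
    if len(pts) == 1:
        return 1.0, 1.0, 0.0
    geom = MultiPoint([(c, r) for r, c in pts])  # shapely uses (x, y)
    rect = shapely.oriented_envelope(geom)
    coords = np.asarray(rect.exterior.coords) if rect.geom_type == "Polygon" else None
    if coords is None:
        # collinear points: envelope degenerates to a line segment
        seg = np.asarray(rect.coords)
        length = float(np.hypot(*(seg[-1] - seg[0]))) + 1.0
        ang = float(np.degrees(np.arctan2(*(seg[-1] - seg[0])[::-1])))
        return length, 1.0, ang
    e1 = coords[1] - coords[0]
    e2 = coords[2] - coords[1]
    l1, l2 = np.hypot(*e1), np.hypot(*e2)
    # +1: pixels are unit squares, the hull of centers is 1 px short per axis
    length, width = max(l1, l2) + 1.0, min(l1, l2) + 1.0
    edge = e1 if l1 >= l2 else e2
    angle = float(np.degrees(np.arctan2(edge[1], edge[0])))
    return float(length), float(width), angle


def binarize_and_label(
    image: GrayImage,
    mask: BreastMask | np.ndarray,
    threshold: int,
    axis_aligned_rect: bool = False,
) -> list[CandidateRegion]:
    """Threshold the masked image and label 8-connected components.

    Foreground = masked pixels with intensity >= threshold. Components are
    labeled in raster-scan order of their first pixel. boundary_contrast is
    the component's mean intensity minus the mean of its 3-pixel outer
    ring, the ring restricted to the breast mask.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    m = mask.mask if isinstance(mask, BreastMask) else np.asarray(mask).astype(bool)
    if m.shape != image.pixels.shape:
        raise ValueError("mask shape differs from image shape")
    fg = m & (image.pixels >= threshold)
    lab, n = label(fg, connectivity=2, return_num=True)
    px = image.pixels.astype(np.float64)
    ring_structure = ndimage.generate_binary_structure(2, 2)
    candidates: list[CandidateRegion] = []
    for prop in regionprops(lab):
        comp = lab == prop.label
        coords = prop.coords
        ring = ndimage.binary_dilation(comp, structure=ring_structure, iterations=3) & ~comp & m
        ring_mean = px[ring].mean() if ring.any() else px[comp].mean()
        mean_int = float(px[comp].mean())
        length, width, angle = min_area_rect(coords, axis_aligned=axis_aligned_rect)
        aspect = length / width if width > 0 else float("inf")
        candidates.append(
            CandidateRegion(
                label=int(prop.label),
                pixel_set=coords,
                area=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                min_rect=(length, width, angle),
                aspect_ratio=float(aspect),
                mean_intensity=mean_int,
                boundary_contrast=float(mean_int - ring_mean),
            )
        )
    return candidates


def filter_candidates(
    candidates: list[CandidateRegion],
    min_area: float = DEFAULT_MIN_AREA,
    max_area: float = DEFAULT_MAX_AREA,
    max_aspect: float = DEFAULT_MAX_ASPECT,
) -> list[CandidateRegion]:
    """Keep compact, lump-sized candidates; mark the rest rejected.

    Bounds are interpreted at the image scale the caller chose (see
    :func:`scaled_area_bounds` for the reference-scale convention).
    Rejected candidates stay in the list with status ``rejected`` so
    reports can show what was discarded; relative order is preserved.
    """
    if min_area > max_area:
        raise ValueError("min_area must not exceed max_area")
    if max_aspect < 1:
        raise ValueError("max_aspect must be >= 1")
    out = []
    for cand in candidates:
        keep = min_area <= cand.area <= max_area and cand.aspect_ratio <= max_aspect
        cand.status = "rough" if keep else "rejected"
        out.append(cand)
    return out


def scaled_area_bounds(
    image_shape: tuple[int, int],
    min_area: float = DEFAULT_MIN_AREA,
    max_area: float = DEFAULT_MAX_AREA,
) -> tuple[float, float]:
    """Scale reference-resolution area bounds to the actual image size.

    The defaults span typical lump radii (~20-200 px) at 1024x1024 while
    rejecting vessels and edge slivers; other resolutions scale by
    image_area / 1024^2 so the bounds stay resolution-independent.
    """
    factor = (image_shape[0] * image_shape[1]) / REFERENCE_AREA
    return min_area * factor, max_area * factor
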