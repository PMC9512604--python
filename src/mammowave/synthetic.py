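"""Seeded phantom mammograms with exact ground truth.

The generator emulates the gross structure the pipeline exploits: a dark
background, a bright half-elliptical breast with additive Gaussian noise,
an optional pectoral-muscle wedge in the top corner, thin bright
random-walk polylines standing in for vessels, and one or more bright
lumps of controlled contrast, radius and edge fuzziness. It makes no
attempt at realistic parenchymal texture — the suite validates mechanism
(thresholding, growing, contour evolution), not clinical appearance.

Default canvas is 256x256 so a full suite runs in seconds; all geometry
scales linearly with image size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image_io import GrayImage, GroundTruthLump, write_pgm
from .preprocess import BreastMask

__all__ = ["LumpSpec", "PhantomSpec", "generate", "generate_suite", "DIFFICULTY_PRESETS"]

# difficulty -> (lump contrast, edge blur sigma px, noise sd)
DIFFICULTY_PRESETS = {
    "easy": (60.0, 1.0, 4.0),
    "medium": (35.0, 3.0, 8.0),
    "hard": (20.0, 5.0, 12.0),
}


@dataclass(frozen=True)
class LumpSpec:
    center: tuple[int, int]  # (row, col)
    radius: float
    contrast: float  # added gray levels
    edge_sigma: float = 0.0  # Gaussian blur of the lump edge, px


@dataclass
class PhantomSpec:
    size: tuple[int, int] = (256, 256)
    background_level: int = 10
    breast_level: int = 120
    noise_sd: float = 4.0
    pectoral: bool = False
    lumps: list[LumpSpec] = field(default_factory=list)
    n_vessels: int = 0
    vessel_contrast: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.size
        if h < 8 or w < 8:
            raise ValueError("phantom below the 8x8 pipeline minimum")
        for lump in self.lumps:
            if self.breast_level + lump.contrast > 255:
                raise ValueError("breast_level + lump contrast exceeds 255")
            if not _inside_breast_disk(lump, self.size):
                raise ValueError(f"lump at {lump.center} not fully inside the breast")
        for i, a in enumerate(self.lumps):
            for b in self.lumps[i + 1 :]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius + max(a.edge_sigma, b.edge_sigma) * 2:
                    raise ValueError("overlapping lumps are not supported")


def _breast_region(size: tuple[int, int]) -> np.ndarray:
    """Half-ellipse attached to the left edge, as in a standard MLO/CC view."""
    h, w = size
    yy, xx = np.mgrid[:h, :w]
    a, b = 0.46 * h, 0.78 * w
    return ((yy - h / 2) / a) ** 2 + (xx / b) ** 2 <= 1.0


def _inside_breast_disk(lump: LumpSpec, size: tuple[int, int]) -> bool:
    breast = _breast_region(size)
    h, w = size
    yy, xx = np.mgrid[:h, :w]
    margin = lump.radius + 2 * lump.edge_sigma
    disk = (yy - lump.center[0]) ** 2 + (xx - lump.center[1]) ** 2 <= margin**2
    return bool((disk & ~breast).sum() == 0)


def _pectoral_wedge_mask(size: tuple[int, int]) -> np.ndarray:
    h, w = size
    yy, xx = np.mgrid[:h, :w]
    # triangular wedge from the top-left corner
    return (yy * 1.6 + xx) < 0.45 * w


def _vessels(rng: np.random.Generator, breast: np.ndarray, n: int) -> np.ndarray:
    h, w = breast.shape
    out = np.zeros_like(breast, dtype=bool)
    rows, cols = np.nonzero(breast)
    for _ in range(n):
        k = rng.integers(0, len(rows))
        r, c = float(rows[k]), float(cols[k])
        angle = rng.uniform(0, 2 * np.pi)
        width = int(rng.integers(1, 3))
        # gentle curvature: vessels are elongated, not tangled — the shape
        # filter downstream relies on their high aspect ratio
        for _step in range(int(0.6 * max(h, w))):
            angle += rng.normal(0, 0.05)
            r += np.sin(angle)
            c += np.cos(angle)
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < h and 0 <= ci < w) or not breast[ri, ci]:
                break
            out[max(0, ri - width + 1) : ri + 1, max(0, ci - width + 1) : ci + 1] = True
    return out & breast


def generate(spec: PhantomSpec) -> tuple[GrayImage, BreastMask, list[GroundTruthLump]]:
    """Render a phantom; deterministic given ``spec.seed``.

    Returns the image, the exact breast mask (pectoral excluded when
    present, mirroring what preprocessing is expected to deliver), and one
    ground-truth circle per lump.
    """
    spec.validate()
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    breast = _breast_region(spec.size)
    img = np.full((h, w), float(spec.background_level))
    img[breast] = spec.breast_level
    wedge = np.zeros_like(breast)
    if spec.pectoral:
        wedge = _pectoral_wedge_mask(spec.size) & breast
        img[wedge] += 30.0
    if spec.n_vessels:
        img[_vessels(rng, breast, spec.n_vessels)] += spec.vessel_contrast
    yy, xx = np.mgrid[:h, :w]
    truths = []
    for i, lump in enumerate(spec.lumps):
        disk = (yy - lump.center[0]) ** 2 + (xx - lump.center[1]) ** 2 <= lump.radius**2
        layer = np.where(disk, lump.contrast, 0.0)
        if lump.edge_sigma > 0:
            layer = ndimage.gaussian_filter(layer, lump.edge_sigma)
        img += layer
        truths.append(
            GroundTruthLump(
                image_id=f"phantom{spec.seed:05d}",
                center=lump.center,
                radius=lump.radius,
            )
        )
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    image = GrayImage(pixels=pixels, source_id=f"phantom{spec.seed:05d}")
    mask = BreastMask(mask=breast & ~wedge, includes_pectoral=not spec.pectoral)
    return image, mask, truths


def _suite_spec(rng: np.random.Generator, index: int, difficulty: str, seed: int) -> PhantomSpec:
    contrast, edge_sigma, noise_sd = DIFFICULTY_PRESETS[difficulty]
    has_lump = rng.random() < 0.8
    lumps: list[LumpSpec] = []
    if has_lump:
        for _attempt in range(100):
            radius = float(rng.uniform(9, 18))
            r = int(rng.uniform(50, 206))
            c = int(rng.uniform(20, 150))
            lump = LumpSpec(center=(r, c), radius=radius, contrast=contrast, edge_sigma=edge_sigma)
            if _inside_breast_disk(lump, (256, 256)):
                lumps.append(lump)
                break
    return PhantomSpec(
        size=(256, 256),
        background_level=10,
        breast_level=120,
        noise_sd=noise_sd,
        pectoral=True,
        lumps=lumps,
        n_vessels=3,
        seed=seed * 100_000 + index,
    )


def generate_suite(
    n_images: int,
    difficulty: str = "easy",
    seed: int = 0,
    outdir: str | Path | None = None,
) -> list[tuple[GrayImage, BreastMask, list[GroundTruthLump]]]:
    """Generate a seeded suite of phantoms; optionally write it to disk.

    About 80% of images contain exactly one lump, the rest none. When
    ``outdir`` is given, images go out as 8-bit PGM plus one MIAS-dialect
    annotation file (``info.txt``, bottom-left-origin coordinates) and a
    JSON manifest of the true parameters.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if difficulty not in DIFFICULTY_PRESETS:
        raise ValueError(f"unknown difficulty {difficulty!r}")
    rng = np.random.default_rng(seed)
    results = []
    records = []
    for i in range(n_images):
        spec = _suite_spec(rng, i, difficulty, seed)
        image, mask, truths = generate(spec)
        image.source_id = f"syn{i:03d}"
        truths = [
            GroundTruthLump(image_id=image.source_id, center=t.center, radius=t.radius)
            for t in truths
        ]
        results.append((image, mask, truths))
        records.append((image, truths, spec))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lines = []
        manifest = []
        for image, truths, spec in records:
            write_pgm(image, outdir / f"{image.source_id}.pgm")
            h = image.height
            if truths:
                for t in truths:
                    x = t.center[1]
                    y = h - 1 - t.center[0]  # back to bottom-left origin
                    lines.append(f"{image.source_id} F CIRC B {x} {y} {t.radius:.0f}")
            else:
                lines.append(f"{image.source_id} F NORM")
            manifest.append(
                {
                    "image": f"{image.source_id}.pgm",
                    "difficulty": difficulty,
                    "noise_sd": spec.noise_sd,
                    "lumps": [
                        {
                            "center": list(t.center),
                            "radius": t.radius,
                        }
                        for t in truths
                    ],
                }
            )
        (outdir / "info.txt").write_text("\n".join(lines) + "\n")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return results
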