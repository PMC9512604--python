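"""Shared fixtures: phantoms and helpers used across the suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from mammowave.image_io import GrayImage


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0


@pytest.fixture
def disk_truth():
    """Centered disk mask (r=30) on a 128x128 canvas."""
    yy, xx = np.mgrid[:128, :128]
    return ((yy - 64) ** 2 + (xx - 64) ** 2) <= 30**2


@pytest.fixture
def blurred_disk(disk_truth):
    """Fuzzy-edged disk: contrast 60, edge blur sigma 4 px, noiseless."""
    img = ndimage.gaussian_filter(np.where(disk_truth, 160.0, 100.0), 4.0)
    return GrayImage(np.clip(np.round(img), 0, 255).astype(np.uint8), "blurred_disk")


@pytest.fixture
def ramp_disk():
    """Disk on a strong intensity ramp: globally the inside/outside means
    are close, so a global two-phase model prefers the bright/dark split
    while local statistics still separate the disk."""
    yy, xx = np.mgrid[:128, :128]
    truth = ((yy - 64) ** 2 + (xx - 40) ** 2) <= 22**2
    ramp = np.tile(np.linspace(30, 230, 128), (128, 1))
    img = ramp + np.where(truth, 45.0, 0.0)
    image = GrayImage(np.clip(np.round(img), 0, 255).astype(np.uint8), "ramp_disk")
    return image, truth


def two_gaussian_counts(
    seed: int,
    mu1: float = 90.0,
    sd1: float = 12.0,
    mu2: float = 190.0,
    sd2: float = 8.0,
    weight2: float = 0.03,
    n: int = 100_000,
) -> np.ndarray:
    """Sampled two-population gray histogram (256 bins)."""
    rng = np.random.default_rng(seed)
    n2 = int(round(n * weight2))
    vals = np.concatenate([rng.normal(mu1, sd1, n - n2), rng.normal(mu2, sd2, n2)])
    vals = np.clip(np.round(vals), 0, 255).astype(int)
    return np.bincount(vals, minlength=256)


def histogram_valley(counts: np.ndarray, mu1: float, mu2: float) -> int:
    """Brute-force valley: exhaustive count minimum between the two sample
    modes, ties resolved to the middle of the minimal plateau."""
    lo = int(mu1) - 30 + int(np.argmax(counts[int(mu1) - 30 : int(mu1) + 30]))
    hi = int(mu2) - 30 + int(np.argmax(counts[int(mu2) - 30 : int(mu2) + 30]))
    seg = counts[lo : hi + 1]
    ties = np.nonzero(seg == seg.min())[0]
    return lo + int((ties[0] + ties[-1]) // 2)
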