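"""Gray-histogram wavelet analysis and segmentation-threshold selection.

The lump population contributes only a small bump high on the gray
histogram, sitting on the shoulder of the much larger parenchyma mode and
invisible to direct inspection. Because a wavelet built as the derivative
of a smoothing kernel turns abrupt changes of a 1-D signal into modulus
maxima of its coefficients, singular points of the histogram — gray levels
where a new tissue population begins — can be localized as strict local
maxima of the undecimated wavelet detail coefficients. The nearest
coefficient-modulus minimum on the dark side of the chosen singular point
marks the valley between the parenchyma bulk and the lump population and
becomes the rough-segmentation threshold.

The primary transform is an undecimated (a trous) Daubechies detail
filter; large orders (db20 by default) suppress spurious maxima from
counting noise, which is singular everywhere and whose maxima shrink with
scale while genuine gray-level discontinuities persist. Filtering shifts
features by the filter's group delay, so coefficients are realigned by a
shift calibrated once per (wavelet, level) on a unit step: after the
correction a step edge produces its modulus maximum at the step's own
index. A derivative-of-Gaussian backend is provided behind the same
interface for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt
from scipy import ndimage
from skimage.filters import threshold_otsu

from .image_io import GrayImage
from .preprocess import BreastMask, DegenerateInputError

__all__ = [
    "GrayHistogram",
    "WaveletResponse",
    "SingularPoint",
    "ThresholdDecision",
    "compute_histogram",
    "wavelet_response",
    "find_modulus_maxima",
    "select_threshold",
]

N_LEVELS = 256


@dataclass
class GrayHistogram:
    """256-bin gray-level histogram of the masked breast pixels."""

    counts: np.ndarray
    n_pixels: int
    mode_level: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_LEVELS,):
            raise ValueError("histogram must have exactly 256 bins")

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "GrayHistogram":
        counts = np.asarray(counts, dtype=np.int64)
        # tie rule: the mode is the smallest gray level attaining the max count
        return cls(counts=counts, n_pixels=int(counts.sum()), mode_level=int(counts.argmax()))


@dataclass
class WaveletResponse:
    """Per-gray-level detail coefficients, aligned index-for-index with the signal.

    ``shift`` is the alignment correction (in samples) already applied to
    ``coeffs`` so that a step in the signal peaks at the step's own index.
    """

    signal: np.ndarray
    wavelet_name: str
    scale_level: int
    coeffs: np.ndarray
    shift: int
    rising_sign: int = 1  # sign a rising step produces at its peak coefficient


@dataclass(frozen=True)
class SingularPoint:
    """A strict local maximum of |coeffs|: an abrupt-change location."""

    gray_level: int
    modulus: float
    sign: int  # +1 rising transition (counts increasing with gray), -1 falling


@dataclass(frozen=True)
class ThresholdDecision:
    threshold: int
    chosen_singular_point: SingularPoint | None
    nearest_minimum: int | None
    scale_level: int
    fallback: bool = False


def compute_histogram(image: GrayImage, mask: BreastMask | np.ndarray) -> GrayHistogram:
    """Count masked pixels per gray level (exact integer arithmetic)."""
    m = mask.mask if isinstance(mask, BreastMask) else np.asarray(mask).astype(bool)
    if m.shape != image.pixels.shape:
        raise ValueError("mask shape differs from image shape")
    if not m.any():
        raise ValueError("mask selects no pixels")
    counts = np.bincount(image.pixels[m].ravel(), minlength=N_LEVELS)
    return GrayHistogram.from_counts(counts)


@lru_cache(maxsize=32)
def _atrous_filters(wavelet_name: str, level: int) -> tuple[np.ndarray, ...]:
    """A trous smoothing cascade plus a derivative kernel.

    The transform realizes "derivative of the signal after smoothing at
    scale 2**level": the signal is lowpass-filtered by the upsampled
    Daubechies scaling filters of levels 1..level (each normalized to unit
    sum, so constants pass unchanged), then differentiated by a central
    difference. The scaling function plays the smoothing kernel and its
    derivative is the effective single-lobe wavelet, so a step produces one
    dominant modulus maximum rather than an oscillatory train.
    """
    w = pywt.Wavelet(wavelet_name)
    lo = np.asarray(w.dec_lo, dtype=np.float64)
    lo = lo / lo.sum()
    filters = []
    for j in range(1, level + 1):
        up = 2 ** (j - 1)
        upsampled = np.zeros((len(lo) - 1) * up + 1)
        upsampled[::up] = lo
        filters.append(upsampled)
    filters.append(np.array([0.5, 0.0, -0.5]) * 2.0**level)  # s * d/dz at scale s
    return tuple(filters)


def _raw_undecimated_detail(signal: np.ndarray, wavelet_name: str, level: int) -> np.ndarray:
    """Undecimated level-`level` detail coefficients, replicate extension, no shift.

    Boundary extension replicates the edge samples (constant continuation)
    rather than mirroring: high-order filters span more than the 256-sample
    signal, and a mirrored copy of interior structure inside the filter
    support would displace modulus maxima near the boundaries, breaking
    step localization. Constant continuation adds no structure at all.
    """
    padded, pad = _padded_undecimated_detail(signal, wavelet_name, level)
    return padded[pad : pad + signal.size]


def _padded_undecimated_detail(
    signal: np.ndarray, wavelet_name: str, level: int
) -> tuple[np.ndarray, int]:
    filters = _atrous_filters(wavelet_name, level)
    pad = sum(len(f) - 1 for f in filters) + 1
    x = np.pad(signal.astype(np.float64), pad, mode="edge")
    for f in filters:
        full = np.convolve(x, f, mode="full")
        off = (len(f) - 1) // 2
        x = full[off : off + x.size]
    return x, pad


@lru_cache(maxsize=64)
def _calibration(wavelet_name: str, level: int, n: int) -> tuple[int, int]:
    """Unit-step calibration: (group-delay shift, peak-coefficient sign).

    The shift realigns coefficients so a step's modulus maximum lands at
    the step's own index; the sign records which coefficient sign a rising
    step produces, fixing the transition-direction convention.
    """
    step_at = n // 2
    step = np.zeros(n)
    step[step_at:] = 1.0
    raw = _raw_undecimated_detail(step, wavelet_name, level)
    peak = int(np.argmax(np.abs(raw)))
    return step_at - peak, int(np.sign(raw[peak]) or 1)


def wavelet_response(
    signal: np.ndarray,
    wavelet_name: str = "db20",
    scale_level: int = 3,
    backend: str = "daubechies",
) -> WaveletResponse:
    """Compute aligned undecimated detail coefficients of a 1-D signal.

    ``backend='gaussian_derivative'`` replaces the Daubechies filter bank
    with a first-derivative-of-Gaussian filter at scale 2**(level-1); its
    kernel is odd-symmetric, so no alignment shift is needed.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not 1 <= scale_level <= 6:
        raise ValueError("scale_level must be in 1..6")
    if backend == "gaussian_derivative":
        coeffs = ndimage.gaussian_filter1d(
            signal, sigma=2.0 ** (scale_level - 1), order=1, mode="reflect"
        )
        return WaveletResponse(signal, f"gaus1@{scale_level}", scale_level, coeffs, 0)
    if backend != "daubechies":
        raise ValueError(f"unknown backend {backend!r}")
    try:
        pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet_name!r}") from exc
    shift, rising = _calibration(wavelet_name, scale_level, signal.size)
    padded, pad = _padded_undecimated_detail(signal, wavelet_name, scale_level)
    # shift applied inside the padded support so realigned coefficients near
    # the boundaries come from real filter output, not wrap-around
    coeffs = padded[pad - shift : pad - shift + signal.size].copy()
    return WaveletResponse(signal, wavelet_name, scale_level, coeffs, shift, rising)


def noise_floor(response: WaveletResponse, noise_factor: float) -> float:
    """Modulus floor below which a local maximum is attributed to noise.

    The input's noise scale is estimated robustly from its first
    differences (sigma = median(|diff|) / (0.6745 * sqrt(2)), exact for
    i.i.d. Gaussian noise) and propagated through the transform by the
    equivalent filter's L2 norm. Counting noise is singular everywhere, so
    without a floor every wiggle of the coefficient sequence would count
    as a singular point; genuine gray-level transitions carry far more
    modulus than noise at coarse scales.
    """
    diffs = np.abs(np.diff(response.signal))
    diffs = diffs[diffs > 0]  # empty histogram stretches carry no noise
    if diffs.size < 8:
        return 0.0  # (near-)noiseless signal: the few nonzero diffs are edges
    sigma = float(np.median(diffs)) / (0.6745 * np.sqrt(2.0))
    if response.wavelet_name.startswith("gaus1@"):
        # ||d/dz G_s||_2 for a sampled first-derivative-of-Gaussian kernel
        s = 2.0 ** (response.scale_level - 1)
        x = np.arange(-int(8 * s), int(8 * s) + 1, dtype=np.float64)
        g = np.exp(-(x**2) / (2 * s * s))
        kernel = -x / (s * s) * g / g.sum()
        knorm = float(np.sqrt(np.sum(kernel**2)))
    else:
        filters = _atrous_filters(response.wavelet_name, response.scale_level)
        kernel = filters[0]
        for f in filters[1:]:
            kernel = np.convolve(kernel, f)
        knorm = float(np.sqrt(np.sum(kernel**2)))
    return noise_factor * sigma * knorm


def find_modulus_maxima(response: WaveletResponse, noise_factor: float = 3.0) -> list[SingularPoint]:
    """Strict local maxima of |coeffs| above the noise floor.

    A gray level g qualifies when |c[g]| strictly exceeds both neighbours
    and the floor from :func:`noise_floor`; plateaus therefore yield no
    maximum. Sign records the direction of the underlying transition.
    """
    if noise_factor < 0:
        raise ValueError("noise_factor must be nonnegative")
    c = response.coeffs
    mod = np.abs(c)
    floor = noise_floor(response, noise_factor)
    out: list[SingularPoint] = []
    for g in range(1, mod.size - 1):
        if mod[g] > mod[g - 1] and mod[g] > mod[g + 1] and mod[g] > floor:
            direction = 1 if int(np.sign(c[g]) or 1) == response.rising_sign else -1
            out.append(SingularPoint(gray_level=g, modulus=float(mod[g]), sign=direction))
    return out


def _dark_side_minimum(
    mod: np.ndarray, start: int, mode_level: int, maxima: list[SingularPoint]
) -> int | None:
    """Modulus minimum on the dark side of a singular point.

    The walk covers gray levels from ``start`` down to the nearest other
    singular point below it (or the histogram mode when none exists) and
    returns the argmin of |coeffs| there — the quiet point between the two
    transitions. Small noise wiggles create spurious local minima on the
    slope of a genuine edge, so the minimum over the inter-transition
    interval is used rather than the first local minimum encountered.
    """
    lower = mode_level
    for sp in maxima:
        if mode_level < sp.gray_level < start:
            lower = max(lower, sp.gray_level)
    if start - lower < 2:
        return None
    seg = mod[lower + 1 : start]
    return int(lower + 1 + np.argmin(seg))


def _restricted_otsu(counts: np.ndarray, mode_level: int) -> int | None:
    sub = counts[mode_level + 1 :]
    levels = np.arange(mode_level + 1, N_LEVELS)
    occupied = np.count_nonzero(sub)
    if occupied < 2:
        return None
    return int(threshold_otsu(hist=(sub.astype(np.float64), levels.astype(np.float64))))


def select_threshold(
    histogram: GrayHistogram,
    response: WaveletResponse,
    maxima: list[SingularPoint],
    max_bright_fraction: float = 0.10,
) -> ThresholdDecision:
    """Derive the rough-segmentation threshold from histogram singular points.

    Candidate singular points are those strictly above the histogram mode
    (lumps are bright relative to the parenchyma bulk). Rising-edge
    candidates — where counts increase with gray level, marking the onset
    of a new bright population — are preferred over falling edges, and
    within each group candidates are tried in descending modulus; the first
    whose dark-side walk yields a modulus minimum above the mode wins, and
    that minimum's gray level is the threshold. When no candidate yields a
    valley the decision falls back to Otsu's threshold restricted to levels
    above the mode, flagged as such.

    A lump population is small next to the parenchyma bulk, so a candidate
    threshold is only plausible when at most ``max_bright_fraction`` of the
    masked pixels lie above it; thresholds hugging the mode (as arise on
    images with no bright population at all, where the only singular
    points are the mode's own shoulder) are rejected by this guard. The
    fallback is likewise floored at the (1 - max_bright_fraction) count
    quantile.
    """
    if np.count_nonzero(histogram.counts) < 2:
        raise DegenerateInputError("histogram has a single occupied bin")
    mode = histogram.mode_level
    mod = np.abs(response.coeffs)
    above = np.cumsum(histogram.counts[::-1])[::-1]  # above[g] = count of pixels >= g

    def plausible(threshold: int) -> bool:
        return above[threshold] <= max_bright_fraction * histogram.n_pixels

    candidates = [sp for sp in maxima if sp.gray_level > mode]
    ordered = sorted(candidates, key=lambda sp: (-sp.sign, -sp.modulus))
    for sp in ordered:
        g_min = _dark_side_minimum(mod, sp.gray_level, mode, maxima)
        if g_min is not None and plausible(g_min):
            return ThresholdDecision(
                threshold=g_min,
                chosen_singular_point=sp,
                nearest_minimum=g_min,
                scale_level=response.scale_level,
                fallback=False,
            )
    if above[mode + 1] == 0:
        raise DegenerateInputError("no gray mass above the histogram mode")
    otsu = _restricted_otsu(histogram.counts, mode)
    # On a unimodal histogram the restricted Otsu splits inside the mode's
    # own bright flank; floor the fallback at mode + 3 sigma of the mode
    # (half-width estimate) so it at least clears the parenchyma noise tail.
    # half-width from the LAST bin still above half-maximum: intensity
    # normalization leaves a comb of empty bins, so the first-crossing walk
    # would stop at an interleaved gap instead of the true flank
    half = histogram.counts[mode] / 2.0
    flank = [
        g - mode
        for g in range(mode + 1, min(mode + 65, N_LEVELS))
        if histogram.counts[g] >= half
    ]
    hwhm = max(flank, default=1)
    noise_tail = mode + int(np.ceil(3.0 * hwhm / 1.177))
    threshold = max(otsu if otsu is not None else 0, noise_tail, mode + 1)
    return ThresholdDecision(
        threshold=min(threshold, 255),
        chosen_singular_point=None,
        nearest_minimum=None,
        scale_level=response.scale_level,
        fallback=True,
    )
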