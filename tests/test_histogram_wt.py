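import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.filters import threshold_otsu

from conftest import histogram_valley, two_gaussian_counts
from mammowave.histogram_wt import (
    GrayHistogram,
    SingularPoint,
    compute_histogram,
    find_modulus_maxima,
    noise_floor,
    select_threshold,
    wavelet_response,
)
from mammowave.image_io import GrayImage
from mammowave.preprocess import BreastMask, DegenerateInputError


def brute_force_maxima(response, noise_factor=3.0):
    """Independent O(n) re-scan applying the same three inequalities."""
    mod = np.abs(response.coeffs)
    floor = noise_floor(response, noise_factor)
    out = []
    for g in range(1, len(mod) - 1):
        if mod[g] > mod[g - 1] and mod[g] > mod[g + 1] and mod[g] > floor:
            out.append(g)
    return out


class TestComputeHistogram:
    def test_small_image_exact_counts(self):
        img = GrayImage(np.array([[0, 0], [255, 128]], dtype=np.uint8), "t")
        mask = np.ones((2, 2), dtype=bool)
        h = compute_histogram(img, mask)
        assert h.counts[0] == 2 and h.counts[128] == 1 and h.counts[255] == 1
        assert h.n_pixels == 4
        assert h.mode_level == 0  # smallest level attaining the max count

    def test_empty_mask_rejected(self):
        img = GrayImage(np.zeros((4, 4), dtype=np.uint8), "t")
        with pytest.raises(ValueError):
            compute_histogram(img, np.zeros((4, 4), dtype=bool))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_counts_conserve_masked_pixels(self, seed):
        rng = np.random.default_rng(seed)
        img = GrayImage(rng.integers(0, 256, (16, 16), dtype=np.uint8), "t")
        mask = rng.random((16, 16)) > 0.4
        if not mask.any():
            mask[0, 0] = True
        assert compute_histogram(img, mask).counts.sum() == mask.sum()


class TestWaveletResponse:
    @pytest.mark.parametrize("wavelet", ["db5", "db10", "db15", "db20"])
    def test_step_localizes_at_its_index(self, wavelet):
        for pos in range(10, 250, 16):
            sig = np.zeros(256)
            sig[pos:] = 1.0
            r = wavelet_response(sig, wavelet, 3)
            assert abs(int(np.argmax(np.abs(r.coeffs))) - pos) <= 1

    def test_constant_signal_annihilated(self):
        r = wavelet_response(np.full(256, 7.0), "db20", 3)
        assert np.abs(r.coeffs).max() < 1e-9

    def test_linearity(self):
        rng = np.random.default_rng(0)
        f, g = rng.normal(size=256), rng.normal(size=256)
        lhs = wavelet_response(2 * f + 3 * g, "db20", 3).coeffs
        rhs = 2 * wavelet_response(f, "db20", 3).coeffs + 3 * wavelet_response(g, "db20", 3).coeffs
        assert np.abs(lhs - rhs).max() < 1e-8

    def test_coeffs_aligned_with_signal_length(self):
        r = wavelet_response(np.arange(256.0), "db5", 2)
        assert r.coeffs.shape == r.signal.shape

    def test_gaussian_derivative_backend_localizes_steps(self):
        sig = np.zeros(256)
        sig[120:] = 1.0
        r = wavelet_response(sig, scale_level=3, backend="gaussian_derivative")
        assert abs(int(np.argmax(np.abs(r.coeffs))) - 120) <= 1

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ValueError):
            wavelet_response(np.zeros(256), "nosuchwavelet", 3)

    def test_out_of_range_level_rejected(self):
        with pytest.raises(ValueError):
            wavelet_response(np.zeros(256), "db5", 7)


class TestFindModulusMaxima:
    def test_step_dominant_maximum_at_step(self):
        sig = np.zeros(256)
        sig[100:] = 1.0
        r = wavelet_response(sig, "db20", 3)
        maxima = find_modulus_maxima(r)
        assert maxima, "step must produce singular points"
        top = max(maxima, key=lambda sp: sp.modulus)
        assert abs(top.gray_level - 100) <= 1
        assert top.sign == 1  # rising transition

    def test_constant_signal_yields_none(self):
        r = wavelet_response(np.full(256, 3.0), "db20", 3)
        assert find_modulus_maxima(r) == []

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_agrees_with_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        sig = np.abs(rng.normal(0, 1, 256)).cumsum() * rng.choice([-1, 1])
        sig += rng.normal(0, 0.5, 256)
        r = wavelet_response(sig, "db20", 3)
        got = [sp.gray_level for sp in find_modulus_maxima(r)]
        assert got == brute_force_maxima(r)

    def test_negative_noise_factor_rejected(self):
        r = wavelet_response(np.zeros(256), "db5", 1)
        with pytest.raises(ValueError):
            find_modulus_maxima(r, -1.0)


class TestSelectThreshold:
    def _decide(self, counts, **kwargs):
        h = GrayHistogram.from_counts(counts)
        r = wavelet_response(np.sqrt(counts.astype(float)), "db20", 3)
        m = find_modulus_maxima(r)
        return select_threshold(h, r, m, **kwargs)

    def test_two_gaussian_threshold_lands_in_valley(self):
        counts = two_gaussian_counts(seed=0)
        d = self._decide(counts)
        valley = histogram_valley(counts, 90, 190)
        assert 150 <= d.threshold <= 180
        assert abs(d.threshold - valley) <= 10
        assert not d.fallback
        assert d.chosen_singular_point is not None
        assert d.threshold > GrayHistogram.from_counts(counts).mode_level

    def test_single_occupied_bin_rejected(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[40] = 1000
        with pytest.raises(DegenerateInputError):
            self._decide(counts)

    def test_fallback_equals_restricted_otsu_when_otsu_dominates(self):
        # deterministic well-separated bimodal counts; an absurd noise factor
        # suppresses every singular point so the decision must fall back
        g = np.arange(256, dtype=float)
        counts = (
            20_000 * np.exp(-((g - 100) ** 2) / 18.0) + 2_000 * np.exp(-((g - 200) ** 2) / 18.0)
        ).astype(np.int64)
        h = GrayHistogram.from_counts(counts)
        r = wavelet_response(np.sqrt(counts.astype(float)), "db20", 3)
        d = select_threshold(h, r, [])
        assert d.fallback
        sub = counts[h.mode_level + 1 :].astype(float)
        levels = np.arange(h.mode_level + 1, 256, dtype=float)
        expected = int(threshold_otsu(hist=(sub, levels)))
        assert d.threshold == expected

    def test_invariant_to_uniform_count_scaling(self):
        counts = two_gaussian_counts(seed=3)
        assert self._decide(counts).threshold == self._decide(counts * 7).threshold

    def test_mode_hugging_thresholds_rejected_by_bright_fraction_guard(self):
        # unimodal histogram: every singular point is the mode's own
        # shoulder, so the decision must fall back, with a threshold that
        # keeps only a small bright fraction
        rng = np.random.default_rng(9)
        vals = np.clip(np.round(rng.normal(120, 6, 50_000)), 0, 255).astype(int)
        counts = np.bincount(vals, minlength=256)
        d = self._decide(counts)
        above = counts[d.threshold :].sum()
        assert above <= 0.10 * counts.sum()
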