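"""End-to-end detection: smooth, threshold from the histogram, refine, score.

The stage order follows the method: normalize the gray range, suppress fine
texture by wavelet filtering, mask the breast (optionally dropping the
pectoral wedge), recompute the gray histogram inside the mask, locate its
singular points by wavelet modulus maxima, threshold at the dark-side
modulus minimum, filter components by area and enclosing-rectangle aspect,
then refine each surviving candidate — region growing where the lump stands
out sharply, the localized active contour where its edge is fuzzy.

The histogram is fed to the wavelet as sqrt(counts): counting noise on a
histogram is Poisson, and the square root stabilizes its variance so one
noise floor applies across the whole gray axis. The square root is
positively homogeneous, so thresholds are invariant to uniform count
scaling, like the raw counts themselves.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import evaluate, histogram_wt, image_io, preprocess, rough_seg, refine, synthetic
from .config import PipelineConfig
from .evaluate import DetectionReport, ImageResult
from .image_io import GrayImage, GroundTruthLump
from .preprocess import BreastMask, DegenerateInputError
from .refine import ActiveContourParams, RefinedBoundary

__all__ = ["DetectionResult", "detect_image", "detect", "run_batch", "compare_wavelet_orders"]

logger = logging.getLogger("mammowave")


@dataclass
class DetectionResult:
    image: GrayImage  # normalized + smoothed working image
    mask: BreastMask
    threshold: histogram_wt.ThresholdDecision
    candidates: list[rough_seg.CandidateRegion]
    boundaries: list[RefinedBoundary] = field(default_factory=list)

    @property
    def surviving(self) -> list[rough_seg.CandidateRegion]:
        return [c for c in self.candidates if c.status != "rejected"]


def _snap_seed(cand: rough_seg.CandidateRegion) -> tuple[int, int]:
    """Candidate centroid snapped to its nearest member pixel."""
    d = np.hypot(
        cand.pixel_set[:, 0] - cand.centroid[0], cand.pixel_set[:, 1] - cand.centroid[1]
    )
    r, c = cand.pixel_set[int(np.argmin(d))]
    return int(r), int(c)


def detect_image(
    image: GrayImage,
    config: PipelineConfig | None = None,
    mask: BreastMask | None = None,
) -> DetectionResult:
    """Run the full detection pipeline on one image.

    ``mask`` overrides breast segmentation (used with phantom truth masks
    or user-supplied masks); otherwise the mask is computed from the image.
    Raises :class:`DegenerateInputError` for images the method cannot
    process (constant gray, empty foreground, single-bin histogram).
    """
    cfg = config or PipelineConfig()
    pp, wt, rough, ref = cfg.preprocess, cfg.wt, cfg.rough, cfg.refine
    if image.height < 8 or image.width < 8:
        raise DegenerateInputError(
            f"image {image.height}x{image.width} below the 8x8 pipeline minimum"
        )
    work = image
    if pp.normalize_first:
        work = preprocess.normalize(work)
        work = preprocess.wavelet_smooth(work, pp.wavelet, pp.level, pp.threshold_scale)
    else:
        work = preprocess.wavelet_smooth(work, pp.wavelet, pp.level, pp.threshold_scale)
        work = preprocess.normalize(work)
    if mask is None:
        external = None
        if pp.external_mask:
            external = image_io.read_image(pp.external_mask).pixels > 0
        mask = preprocess.breast_mask(work, remove_pectoral=pp.remove_pectoral, external_mask=external)
        if pp.edge_margin > 0:
            eroded = ndimage.binary_erosion(mask.mask, iterations=pp.edge_margin)
            mask = BreastMask(mask=eroded, includes_pectoral=mask.includes_pectoral)

    hist = histogram_wt.compute_histogram(work, mask)
    signal = np.sqrt(hist.counts.astype(np.float64))
    response = histogram_wt.wavelet_response(signal, wt.wavelet, wt.level, backend=wt.backend)
    maxima = histogram_wt.find_modulus_maxima(response, wt.noise_factor)
    decision = histogram_wt.select_threshold(hist, response, maxima)
    logger.info(
        "%s: threshold=%d (wavelet=%s level=%d singular=%s fallback=%s)",
        image.source_id,
        decision.threshold,
        wt.wavelet,
        wt.level,
        decision.chosen_singular_point.gray_level if decision.chosen_singular_point else None,
        decision.fallback,
    )

    candidates = rough_seg.binarize_and_label(
        work, mask, decision.threshold, axis_aligned_rect=rough.axis_aligned_rect
    )
    min_area, max_area = rough_seg.scaled_area_bounds(
        work.pixels.shape, rough.min_area, rough.max_area
    )
    candidates = rough_seg.filter_candidates(candidates, min_area, max_area, rough.max_aspect)

    boundaries: list[RefinedBoundary] = []
    ac_params = ActiveContourParams(
        sigma1=ref.sigma1,
        sigma2=ref.sigma2,
        omega_len=ref.omega_len,
        w_area=ref.w_area,
        local_radius=ref.local_radius,
        epsilon=ref.epsilon,
        dt=ref.dt,
        max_iter=ref.max_iter,
        reinit_every=ref.reinit_every,
        tol=ref.tol,
    )
    for cand in candidates:
        if cand.status == "rejected":
            continue
        method = refine.choose_method(cand, ref.contrast_cutoff)
        logger.info("%s: candidate %d -> %s (contrast %.1f)", image.source_id, cand.label, method, cand.boundary_contrast)
        if method == "region_growing":
            seed = _snap_seed(cand)
            boundary = refine.region_grow(
                work,
                seed,
                tolerance=ref.tolerance,
                max_pixels=int(ref.max_pixels_factor * max_area),
                mask=mask.mask,
                fixed_mean=ref.fixed_mean,
                candidate_label=cand.label,
            )
        else:
            init = np.zeros_like(mask.mask)
            init[tuple(cand.pixel_set.T)] = True
            init[0, :] = init[-1, :] = False
            init[:, 0] = init[:, -1] = False
            if not init.any():
                continue
            boundary = refine.local_active_contour(work, init, ac_params, candidate_label=cand.label)
        cand.status = "refined"
        boundaries.append(boundary)
    return DetectionResult(
        image=work, mask=mask, threshold=decision, candidates=candidates, boundaries=boundaries
    )


def detect(image_path: str | Path, config_path: str | Path | None, out_dir: str | Path) -> DetectionResult:
    """File-level front end of :func:`detect_image`; writes all artifacts.

    On failure any partial output is removed and the exception re-raised
    (the command-line wrapper maps it to a nonzero exit status).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig.from_yaml(config_path) if config_path else PipelineConfig()
    image = image_io.read_image(image_path)
    written: list[Path] = []
    try:
        result = detect_image(image, cfg)
        cfg.to_yaml(out / "config.yaml")
        written.append(out / "config.yaml")
        image_io.write_mask(result.mask.mask, out / f"{image.source_id}_breast_mask.png")
        image_io.write_pgm(result.image, out / f"{image.source_id}_normalized.pgm")
        payload = {
            "image": image.source_id,
            "threshold": result.threshold.threshold,
            "fallback": result.threshold.fallback,
            "candidates": [c.to_dict() for c in result.candidates],
        }
        (out / f"{image.source_id}_candidates.json").write_text(json.dumps(payload, indent=2))
        hist = histogram_wt.compute_histogram(result.image, result.mask)
        response = histogram_wt.wavelet_response(
            np.sqrt(hist.counts.astype(np.float64)), cfg.wt.wavelet, cfg.wt.level, backend=cfg.wt.backend
        )
        maxima = histogram_wt.find_modulus_maxima(response, cfg.wt.noise_factor)
        diagnostics = {
            "counts": hist.counts.tolist(),
            "mode_level": hist.mode_level,
            "coeffs": [round(float(c), 6) for c in response.coeffs],
            "maxima": [
                {"gray_level": sp.gray_level, "modulus": sp.modulus, "sign": sp.sign}
                for sp in maxima
            ],
            "threshold": result.threshold.threshold,
            "fallback": result.threshold.fallback,
        }
        (out / f"{image.source_id}_histogram.json").write_text(json.dumps(diagnostics))
        for b in result.boundaries:
            image_io.write_mask(b.mask, out / f"{image.source_id}_refined_{b.candidate_label}.png")
        return result
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _score_result(
    result: DetectionResult,
    truths: list[GroundTruthLump],
    cfg: PipelineConfig,
    image_id: str,
) -> ImageResult:
    matches, fps = evaluate.match_candidates(
        result.candidates, truths, rule=cfg.eval.rule, overlap_fraction=cfg.eval.overlap_fraction
    )
    by_label = {b.candidate_label: b for b in result.boundaries}
    n_bound = sum(
        1 for cand, _t in matches if by_label.get(cand.label) and by_label[cand.label].converged
    )
    return ImageResult(
        image_id=image_id,
        n_truth=len(truths),
        n_matched=len(matches),
        n_false_positives=len(fps),
        n_boundaries_extracted=n_bound,
    )


def run_batch(
    images: list[tuple[GrayImage, list[GroundTruthLump]]] | list[tuple[GrayImage, BreastMask, list[GroundTruthLump]]],
    config: PipelineConfig | None = None,
    use_truth_masks: bool = False,
) -> DetectionReport:
    """Detect on a batch of in-memory images and score against truth.

    ``images`` holds (image, truths) pairs, or (image, mask, truths)
    triples as produced by the phantom generator — the mask is only used
    when ``use_truth_masks`` is set. A hard failure on one image is
    recorded (zero matches, flagged) and the batch continues.
    """
    if not images:
        raise ValueError("empty image list")
    cfg = config or PipelineConfig()
    per_image: list[ImageResult] = []
    for item in images:
        if len(item) == 3:
            image, mask, truths = item
        else:
            image, truths = item
            mask = None
        try:
            result = detect_image(image, cfg, mask=mask if use_truth_masks else None)
            per_image.append(_score_result(result, truths, cfg, image.source_id))
        except DegenerateInputError as exc:
            logger.warning("%s failed: %s", image.source_id, exc)
            per_image.append(
                ImageResult(
                    image_id=image.source_id,
                    n_truth=len(truths),
                    n_matched=0,
                    n_false_positives=0,
                    failed=True,
                )
            )
    return evaluate.summarize(per_image)


def compare_wavelet_orders(
    n_images: int = 20,
    difficulty: str = "easy",
    seed: int = 0,
    orders: tuple[int, ...] = (5, 10, 15, 20),
    config: PipelineConfig | None = None,
) -> dict[str, DetectionReport]:
    """Detection rate and FP/image per Daubechies order on one suite.

    Mirrors the order-comparison experiment (N = 5, 10, 15, 20, with N=20
    the pipeline default): the same seeded suite is run once per order,
    varying only the histogram-transform wavelet.
    """
    suite = synthetic.generate_suite(n_images, difficulty, seed)
    out: dict[str, DetectionReport] = {}
    for order in orders:
        cfg = PipelineConfig.from_mapping((config or PipelineConfig()).to_dict())
        cfg.wt.wavelet = f"db{order}"
        out[f"db{order}"] = run_batch(suite, cfg)
    return out
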