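"""Detection scoring against circle-style ground truth.

The operating point of a lump-detection pipeline is summarized by the
detection rate (fraction of true lumps matched by any surviving candidate)
and the number of unmatched candidates per image (false positives). Both
a per-lump and a per-image detection rate are reported, since published
rates are quoted under either denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import GroundTruthLump
from .rough_seg import CandidateRegion

__all__ = ["ImageResult", "DetectionReport", "match_candidates", "summarize"]


@dataclass
class ImageResult:
    """Matching outcome for one image."""

    image_id: str
    n_truth: int
    n_matched: int
    n_false_positives: int
    n_boundaries_extracted: int = 0
    matched_labels: list[int] = field(default_factory=list)
    failed: bool = False


@dataclass
class DetectionReport:
    n_images: int
    n_truth_lumps: int
    n_rough_detected: int
    n_boundaries_extracted: int
    n_false_positives: int
    detection_rate: float | None  # per-lump; None when no truth lumps exist
    per_image_detection_rate: float | None  # lump-bearing images fully detected
    fp_per_image: float
    per_image: list[ImageResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        def fmt(x):
            return None if x is None else round(x, 4)

        return {
            "n_images": self.n_images,
            "n_truth_lumps": self.n_truth_lumps,
            "n_rough_detected": self.n_rough_detected,
            "n_boundaries_extracted": self.n_boundaries_extracted,
            "n_false_positives": self.n_false_positives,
            "detection_rate": fmt(self.detection_rate),
            "per_image_detection_rate": fmt(self.per_image_detection_rate),
            "fp_per_image": fmt(self.fp_per_image),
            "per_image": [
                {
                    "image_id": r.image_id,
                    "n_truth": r.n_truth,
                    "n_matched": r.n_matched,
                    "n_false_positives": r.n_false_positives,
                    "n_boundaries_extracted": r.n_boundaries_extracted,
                    "failed": r.failed,
                }
                for r in self.per_image
            ],
        }


def _candidate_mask_in_disk(cand: CandidateRegion, truth: GroundTruthLump) -> int:
    dr = cand.pixel_set[:, 0] - truth.center[0]
    dc = cand.pixel_set[:, 1] - truth.center[1]
    return int(np.count_nonzero(dr * dr + dc * dc <= truth.radius**2))


def match_candidates(
    candidates: list[CandidateRegion],
    truths: list[GroundTruthLump],
    rule: str = "centroid_in_circle",
    overlap_fraction: float = 0.3,
) -> tuple[list[tuple[CandidateRegion, GroundTruthLump]], list[CandidateRegion]]:
    """Greedy matching of candidates to truth circles within one image.

    ``centroid_in_circle``: a candidate hits a truth lump when its centroid
    falls inside the truth circle. ``overlap``: when the candidate/disk
    intersection covers at least ``overlap_fraction`` of the smaller of the
    two areas. Candidates are processed by descending area so each truth
    lump is claimed by its largest hit; every unmatched surviving candidate
    counts as a false positive. Rejected candidates take no part.
    """
    if rule not in ("centroid_in_circle", "overlap"):
        raise ValueError(f"unknown matching rule {rule!r}")
    surviving = [c for c in candidates if c.status != "rejected"]
    matches: list[tuple[CandidateRegion, GroundTruthLump]] = []
    claimed: set[int] = set()
    false_positives: list[CandidateRegion] = []
    for cand in sorted(surviving, key=lambda c: -c.area):
        hit = None
        for i, truth in enumerate(truths):
            if i in claimed:
                continue
            if rule == "centroid_in_circle":
                dr = cand.centroid[0] - truth.center[0]
                dc = cand.centroid[1] - truth.center[1]
                ok = dr * dr + dc * dc <= truth.radius**2
            else:
                inter = _candidate_mask_in_disk(cand, truth)
                smaller = min(cand.area, np.pi * truth.radius**2)
                ok = inter / smaller >= overlap_fraction
            if ok:
                hit = (i, truth)
                break
        if hit is None:
            false_positives.append(cand)
        else:
            claimed.add(hit[0])
            matches.append((cand, hit[1]))
    return matches, false_positives


def summarize(per_image_results: list[ImageResult]) -> DetectionReport:
    """Aggregate per-image matching outcomes into a report.

    detection_rate = matched lumps / truth lumps; fp_per_image = total
    false positives / number of images. With no truth lumps at all the
    detection rates are undefined (None), never silently zero.
    """
    if not per_image_results:
        raise ValueError("no per-image results to summarize")
    n_images = len(per_image_results)
    n_truth = sum(r.n_truth for r in per_image_results)
    n_matched = sum(r.n_matched for r in per_image_results)
    n_fp = sum(r.n_false_positives for r in per_image_results)
    n_bound = sum(r.n_boundaries_extracted for r in per_image_results)
    lump_images = [r for r in per_image_results if r.n_truth > 0]
    rate = n_matched / n_truth if n_truth else None
    img_rate = (
        sum(1 for r in lump_images if r.n_matched == r.n_truth) / len(lump_images)
        if lump_images
        else None
    )
    return DetectionReport(
        n_images=n_images,
        n_truth_lumps=n_truth,
        n_rough_detected=n_matched,
        n_boundaries_extracted=n_bound,
        n_false_positives=n_fp,
        detection_rate=rate,
        per_image_detection_rate=img_rate,
        fp_per_image=n_fp / n_images,
        per_image=list(per_image_results),
    )
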