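"""Animal detection stage: oracle detector, IoU matching, rate evaluation.

A real pipeline would run an off-the-shelf animal detector (e.g. the
MegaDetector) over camera/field images.  Here detection is emulated by an
*oracle* detector that reads ground truth from the synthetic catalog and
corrupts it at configurable error rates; any external detector can be
plugged in instead by supplying its boxes in the same COCO-style results
schema via :func:`load_detections`.

Rate conventions (matching the field-report arithmetic this stage is
evaluated with):

* ``tp_rate`` = tp / (tp + fp) — the fraction of *emitted* crops that
  contain an animal.  Note this is detection precision, not recall; the
  name follows the reporting convention of photographic-survey papers.
* ``fp_rate`` = fp / (tp + fp)
* ``fn_rate`` = fn / (tp + fn) — fraction of ground-truth animals missed.
* ``fn_rate_suitable`` = missed-and-suitable / suitable — misses among
  crops usable for identification.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .coatsim import AnnotatedImage, GroundTruthObject
from .preprocess import Crop

__all__ = [
    "Detection",
    "Assignment",
    "DetectorEvaluation",
    "iou",
    "oracle_detect",
    "match_detections",
    "evaluate_detector",
    "crop",
    "save_detections",
    "load_detections",
]


@dataclass
class Detection:
    image_id: str
    bbox: tuple[int, int, int, int]  # (x, y, w, h), 0-based half-open
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class Assignment:
    """One-to-one matching of detections to ground-truth objects."""

    pairs: list[tuple[int, int]]        # (detection index, object index)
    unmatched_detections: list[int]     # false positives
    unmatched_objects: list[int]        # false negatives
    ious: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass
class DetectorEvaluation:
    n_images: int
    n_detections: int
    tp: int
    fp: int
    fn: int
    n_suitable: int
    fn_suitable: int
    tp_rate: float | None
    fp_rate: float | None
    fn_rate: float | None
    fn_rate_suitable: float | None
    undefined_rates: list[str] = field(default_factory=list)

    def rounded(self, ndigits: int = 3) -> dict:
        out = {}
        for name in ("tp_rate", "fp_rate", "fn_rate", "fn_rate_suitable"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, ndigits)
        return out


def iou(box_a: Sequence[float], box_b: Sequence[float]) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def oracle_detect(
    image: AnnotatedImage,
    miss_rate: float = 0.0,
    false_rate: float = 0.0,
    jitter_px: int = 0,
    seed: int = 0,
) -> list[Detection]:
    """Emulated detector with configurable error rates.

    Each ground-truth object is emitted with probability ``1 - miss_rate``
    with its box corners jittered uniformly within ``±jitter_px``; spurious
    background boxes are added with Poisson rate ``false_rate`` per image.
    """
    if not (0.0 <= miss_rate <= 1.0 and 0.0 <= false_rate <= 1.0):
        raise ValueError("miss_rate and false_rate must lie in [0, 1]")
    h, w = image.pixels.shape[:2]
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(seed) & 0x7FFFFFFF, zlib.crc32(image.image_id.encode())]
        )
    )
    out: list[Detection] = []
    for obj in image.objects:
        if rng.random() < miss_rate:
            continue
        x, y, bw, bh = obj.bbox
        if jitter_px > 0:
            j = rng.integers(-jitter_px, jitter_px + 1, size=4)
            x, y = int(x + j[0]), int(y + j[1])
            bw, bh = int(bw + j[2]), int(bh + j[3])
        x, y = max(0, x), max(0, y)
        bw = max(4, min(bw, w - x))
        bh = max(4, min(bh, h - y))
        out.append(Detection(image.image_id, (x, y, bw, bh),
                             confidence=float(rng.uniform(0.8, 1.0))))
    for _ in range(rng.poisson(false_rate)):
        fw = int(rng.integers(w // 8, w // 3))
        fh = int(rng.integers(h // 8, h // 3))
        fx = int(rng.integers(0, w - fw))
        fy = int(rng.integers(0, h - fh))
        out.append(Detection(image.image_id, (fx, fy, fw, fh),
                             confidence=float(rng.uniform(0.1, 0.6))))
    return out


def match_detections(
    detections: Sequence[Detection],
    ground_truth: Sequence[GroundTruthObject],
    iou_threshold: float = 0.5,
) -> Assignment:
    """Greedy one-to-one assignment by descending IoU.

    Pairs below ``iou_threshold`` are never matched; leftover detections are
    false positives, leftover objects false negatives.  Greedy matching
    agrees with the exhaustive optimal assignment whenever boxes overlap
    unambiguously, which the test suite checks against a brute-force oracle.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must lie in (0, 1]")
    nd, ng = len(detections), len(ground_truth)
    mat = np.zeros((nd, ng))
    for i, det in enumerate(detections):
        for j, obj in enumerate(ground_truth):
            mat[i, j] = iou(det.bbox, obj.bbox)
    pairs: list[tuple[int, int]] = []
    ious: dict[tuple[int, int], float] = {}
    free_d, free_g = set(range(nd)), set(range(ng))
    work = mat.copy()
    while free_d and free_g:
        i, j = np.unravel_index(np.argmax(work), work.shape) if work.size else (0, 0)
        if work.size == 0 or work[i, j] < iou_threshold:
            break
        pairs.append((int(i), int(j)))
        ious[(int(i), int(j))] = float(mat[i, j])
        free_d.discard(int(i))
        free_g.discard(int(j))
        work[i, :] = -1.0
        work[:, j] = -1.0
    return Assignment(
        pairs=pairs,
        unmatched_detections=sorted(free_d),
        unmatched_objects=sorted(free_g),
        ious=ious,
    )


def evaluate_detector(
    assignment: Assignment,
    ground_truth: Sequence[GroundTruthObject],
    n_images: int = 0,
) -> DetectorEvaluation:
    """Confusion counts and rates from a completed assignment."""
    tp = len(assignment.pairs)
    fp = len(assignment.unmatched_detections)
    fn = len(assignment.unmatched_objects)
    suitable = [obj.is_suitable() for obj in ground_truth]
    n_suitable = int(sum(suitable))
    fn_suitable = int(sum(suitable[j] for j in assignment.unmatched_objects))
    return evaluation_from_counts(
        tp=tp, fp=fp, fn=fn, n_suitable=n_suitable, fn_suitable=fn_suitable,
        n_images=n_images,
    )


def evaluation_from_counts(
    tp: int,
    fp: int,
    fn: int,
    n_suitable: int = 0,
    fn_suitable: int = 0,
    n_images: int = 0,
) -> DetectorEvaluation:
    """Build a :class:`DetectorEvaluation` directly from confusion counts.

    Zero denominators flag the corresponding rate as undefined instead of
    raising.
    """
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    return DetectorEvaluation(
        n_images=n_images,
        n_detections=tp + fp,
        tp=tp,
        fp=fp,
        fn=fn,
        n_suitable=n_suitable,
        fn_suitable=fn_suitable,
        tp_rate=ratio(tp, tp + fp, "tp_rate"),
        fp_rate=ratio(fp, tp + fp, "fp_rate"),
        fn_rate=ratio(fn, tp + fn, "fn_rate"),
        fn_rate_suitable=ratio(fn_suitable, n_suitable, "fn_rate_suitable"),
        undefined_rates=undefined,
    )


def crop(
    image: AnnotatedImage,
    detection: Detection,
    padding_px: int = 0,
    assigned: GroundTruthObject | None = None,
    crop_id: str | None = None,
) -> Crop:
    """Extract the detection's sub-image (clipped to bounds) as a
    :class:`~patternpipe.preprocess.Crop`, carrying provenance and, when an
    assigned ground-truth object is given, its attributes and foreground
    mask."""
    if detection.image_id != image.image_id:
        raise ValueError("detection does not belong to this image")
    x, y, w, h = detection.bbox
    if w <= 0 or h <= 0:
        raise ValueError("zero-area detection box")
    H, W = image.pixels.shape[:2]
    x0 = max(0, x - padding_px)
    y0 = max(0, y - padding_px)
    x1 = min(W, x + w + padding_px)
    y1 = min(H, y + h + padding_px)
    pixels = image.pixels[y0:y1, x0:x1].copy()
    mask = None
    attributes = None
    if assigned is not None:
        attributes = {
            "individual_id": assigned.individual_id,
            "pose": assigned.pose,
            "side": assigned.side,
            "quality_score": assigned.quality_score,
            "flank_visible_frac": assigned.flank_visible_frac,
            "rotation_deg": assigned.rotation_deg,
        }
        if assigned.flank_bbox is not None:
            fx, fy, fw, fh = assigned.flank_bbox
            ix0, iy0 = max(fx, x0), max(fy, y0)
            ix1, iy1 = min(fx + fw, x1), min(fy + fh, y1)
            if ix1 > ix0 and iy1 > iy0:  # flank box in crop coordinates
                attributes["flank_bbox_crop"] = (ix0 - x0, iy0 - y0,
                                                 ix1 - ix0, iy1 - iy0)
        if assigned.mask is not None:
            full = np.zeros((H, W), dtype=bool)
            gx, gy, gw, gh = assigned.bbox
            full[gy : gy + gh, gx : gx + gw] = assigned.mask
            mask = full[y0:y1, x0:x1].copy()
    if crop_id is None:
        crop_id = f"{image.image_id}@{x0},{y0}"
    return Crop(
        crop_id=crop_id,
        pixels=pixels,
        provenance=(image.image_id, (x0, y0, x1 - x0, y1 - y0)),
        attributes=attributes,
        mask=mask,
        day=image.day,
    )


def save_detections(detections: Sequence[Detection], path: str | Path) -> None:
    recs = [
        {"image_id": d.image_id, "bbox": [int(v) for v in d.bbox],
         "score": d.confidence, "category_id": 1}
        for d in detections
    ]
    with open(path, "w") as fh:
        json.dump(recs, fh, indent=1)


def load_detections(path: str | Path) -> list[Detection]:
    """Read detections from a COCO-style results JSON; this is the adapter
    for external detectors such as MegaDetector output converted upstream."""
    with open(path) as fh:
        recs = json.load(fh)
    return [
        Detection(r["image_id"], tuple(int(v) for v in r["bbox"]),
                  float(r.get("score", 1.0)))
        for r in recs
    ]
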