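"""Feature extraction and image-matching scores.

Two scoring schemes are provided over SIFT-style scale-invariant keypoint
descriptors:

* **Pairwise goodness-of-fit** — nearest-neighbor descriptor matches pass
  a Lowe ratio test and mutual-best filtering, then a seeded
  similarity-transform RANSAC enforces geometric consistency; the score is
  the inlier count.  This is the classic per-image-pair scheme.
* **LNBNN (Local Naive Bayes Nearest Neighbor)** — a one-vs-many scheme
  that pools every database descriptor: for each query descriptor the
  ``k+1`` nearest pooled neighbors are found, and each distinct source
  crop I among the first ``k`` is credited ``max(0, d_{k+1} - d_I)`` where
  ``d_I`` is I's nearest-descriptor distance.  Crops far from every query
  descriptor receive zero, and the k+1-th distance acts as a per-descriptor
  background normalizer.

Keypoint detection and description delegate to scikit-image's SIFT;
descriptors are L2-normalized so Euclidean distance orders like cosine
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.feature import SIFT
from skimage.measure import ransac
from skimage.transform import SimilarityTransform

from .preprocess import Crop

__all__ = [
    "DescriptorSet",
    "MatchScore",
    "RankingResult",
    "extract_features",
    "pairwise_score",
    "lnbnn_scores",
    "mirror",
    "rank",
]


@dataclass
class DescriptorSet:
    crop_id: str
    keypoints: np.ndarray    # (n, 4): x, y, scale, orientation
    descriptors: np.ndarray  # (n, 128) float32, unit rows
    empty_flagged: bool = False

    def __len__(self) -> int:
        return len(self.descriptors)


@dataclass(frozen=True)
class MatchScore:
    query_id: str
    database_id: str
    score: float
    method: Literal["pairwise", "lnbnn"]

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be nonnegative")


@dataclass
class RankingResult:
    query_id: str
    ordering: list[str]               # candidate ids, best first
    scores: dict[str, float]
    true_match_rank: int | None = None  # 1-based


def _empty_set(crop_id: str) -> DescriptorSet:
    return DescriptorSet(
        crop_id=crop_id,
        keypoints=np.zeros((0, 4)),
        descriptors=np.zeros((0, 128), dtype=np.float32),
        empty_flagged=True,
    )


def extract_features(
    crop: Crop,
    upsampling: int = 1,
    suppress_boundary: bool | None = None,
    boundary_erosion_px: int = 5,
) -> DescriptorSet:
    """SIFT keypoints + unit-normalized descriptors for one crop.

    Deterministic per crop.  ``suppress_boundary`` drops keypoints whose
    center falls outside the foreground mask eroded by
    ``boundary_erosion_px``: the artificial edge left by hard background
    filling generates spurious silhouette features that would otherwise
    dominate matching.  The default (``None``) suppresses only for crops
    whose background was removed with the hard black fill; soft-filled
    crops have no artificial edge to suppress.
    """
    h, w = crop.pixels.shape[:2]
    if h < 32 or w < 32:
        raise ValueError("crop must be at least 32x32")
    if suppress_boundary is None:
        suppress_boundary = crop.background_removed and crop.fill == "black"
    gray = rgb2gray(crop.pixels)
    sift = SIFT(upsampling=upsampling)
    try:
        sift.detect_and_extract(gray)
    except RuntimeError:  # no features found
        return _empty_set(crop.crop_id)
    rows = sift.keypoints[:, 0].astype(int)
    cols = sift.keypoints[:, 1].astype(int)
    keep = np.ones(len(rows), dtype=bool)
    if suppress_boundary and crop.mask is not None and crop.mask.any():
        eroded = ndi.binary_erosion(
            crop.mask, structure=np.ones((3, 3)), iterations=boundary_erosion_px
        )
        keep = eroded[np.clip(rows, 0, h - 1), np.clip(cols, 0, w - 1)]
    if not keep.any():
        return _empty_set(crop.crop_id)
    desc = sift.descriptors[keep].astype(np.float32)
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    desc = desc / norms
    kps = np.column_stack(
        [cols[keep], rows[keep], sift.scales[keep], sift.orientations[keep]]
    ).astype(np.float64)
    return DescriptorSet(crop_id=crop.crop_id, keypoints=kps, descriptors=desc)


def _ratio_mutual_matches(
    a: DescriptorSet, b: DescriptorSet, ratio: float
) -> list[tuple[int, int]]:
    """Indices of mutual-best NN matches passing the Lowe ratio test."""
    tree_b = cKDTree(b.descriptors)
    k = min(2, len(b))
    dists, idx = tree_b.query(a.descriptors, k=k)
    if k == 1:
        dists = dists[:, None]
        idx = idx[:, None]
    tree_a = cKDTree(a.descriptors)
    _, back = tree_a.query(b.descriptors, k=1)
    matches = []
    for i in range(len(a)):
        j = int(idx[i, 0])
        if k == 2 and dists[i, 1] > 0 and dists[i, 0] / dists[i, 1] >= ratio:
            continue
        if int(back[j]) != i:  # mutual-best
            continue
        matches.append((i, j))
    return matches


def pairwise_score(
    a: DescriptorSet,
    b: DescriptorSet,
    ratio: float = 0.8,
    min_inliers: int = 3,
    residual_px: float = 5.0,
    max_trials: int = 1000,
    seed: int = 0,
) -> MatchScore:
    """Goodness-of-fit score for one image pair.

    Candidate correspondences (ratio test + mutual best) are verified by a
    seeded similarity-transform RANSAC with ``residual_px`` inlier
    tolerance; the score is the inlier count, or 0 when fewer than
    ``min_inliers`` correspondences are geometrically consistent.
    """
    if len(a) == 0 or len(b) == 0:
        return MatchScore(a.crop_id, b.crop_id, 0.0, "pairwise")
    matches = _ratio_mutual_matches(a, b, ratio)
    if len(matches) < max(2, min_inliers):
        score = float(len(matches)) if len(matches) >= min_inliers else 0.0
        return MatchScore(a.crop_id, b.crop_id, score, "pairwise")
    src = a.keypoints[[i for i, _ in matches], :2]
    dst = b.keypoints[[j for _, j in matches], :2]
    if np.allclose(src, dst):
        n_inliers = len(matches)  # identity transform, all inliers
    else:
        try:
            _, inliers = ransac(
                (src, dst),
                SimilarityTransform,
                min_samples=2,
                residual_threshold=residual_px,
                max_trials=max_trials,
                rng=seed,
            )
        except Exception:
            inliers = None
        n_inliers = int(inliers.sum()) if inliers is not None else 0
    score = float(n_inliers) if n_inliers >= min_inliers else 0.0
    return MatchScore(a.crop_id, b.crop_id, score, "pairwise")


def lnbnn_scores(
    query: DescriptorSet,
    database: Sequence[DescriptorSet],
    k: int = 5,
    exclusions: Iterable[str] = (),
) -> list[MatchScore]:
    """One-vs-many LNBNN scores of ``query`` against every database crop.

    All database descriptors (minus excluded crops) are pooled; for each
    query descriptor the ``k+1`` nearest are found by Euclidean distance,
    and each distinct source crop among the first ``k`` is credited
    ``max(0, d_{k+1} - d_I)``.  With fewer than ``k+1`` pooled descriptors
    all are used and the largest distance found serves as background.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    excl = set(exclusions)
    entries = [ds for ds in database if ds.crop_id not in excl]
    if not entries:
        raise ValueError("database is empty after exclusions")
    scores = {ds.crop_id: 0.0 for ds in entries}
    pooled = [ds.descriptors for ds in entries if len(ds)]
    if pooled and len(query):
        owners = np.concatenate(
            [np.full(len(ds), i) for i, ds in enumerate(entries) if len(ds)]
        )
        ids = [ds.crop_id for ds in entries]
        pool = np.concatenate(pooled)
        tree = cKDTree(pool)
        kq = min(k + 1, len(pool))
        dists, idx = tree.query(query.descriptors, k=kq)
        if kq == 1:
            dists, idx = dists[:, None], idx[:, None]
        for qi in range(len(query)):
            d_row, i_row = dists[qi], idx[qi]
            d_bg = d_row[-1] if kq == k + 1 else d_row.max()
            first_k = kq - 1 if kq == k + 1 else kq
            seen: dict[int, float] = {}
            for d, j in zip(d_row[:first_k], i_row[:first_k]):
                o = int(owners[j])
                if o not in seen:  # neighbors sorted: first is nearest
                    seen[o] = float(d)
            for o, d_i in seen.items():
                scores[ids[o]] += max(0.0, float(d_bg) - d_i)
    return [
        MatchScore(query.crop_id, ds.crop_id, scores[ds.crop_id], "lnbnn")
        for ds in entries
    ]


def mirror(crop: Crop, suffix: str = "~m") -> Crop:
    """Horizontal mirror of a crop (pixels and mask); an involution up to
    the id suffix."""
    new_id = crop.crop_id[: -len(suffix)] if crop.crop_id.endswith(suffix) else crop.crop_id + suffix
    return dc_replace(
        crop,
        crop_id=new_id,
        pixels=crop.pixels[:, ::-1].copy(),
        mask=None if crop.mask is None else crop.mask[:, ::-1].copy(),
    )


def rank(
    query: DescriptorSet,
    database: Sequence[DescriptorSet],
    method: Literal["lnbnn", "pairwise"] = "lnbnn",
    k: int = 5,
    exclusions: Iterable[str] = (),
    true_id: str | None = None,
    k_report: int | None = None,
    seed: int = 0,
) -> RankingResult:
    """Rank database crops against a query by descending score.

    Ties break by ascending crop id so rankings are deterministic.  The
    query itself and any ids in ``exclusions`` never appear.  When
    ``true_id`` is given the 1-based rank of the true match is recorded.
    """
    excl = set(exclusions) | {query.crop_id}
    entries = [ds for ds in database if ds.crop_id not in excl]
    if not entries:
        raise ValueError("database is empty after exclusions")
    if method == "lnbnn":
        ms = lnbnn_scores(query, entries, k=k)
    elif method == "pairwise":
        ms = [pairwise_score(query, ds, seed=seed) for ds in entries]
    else:
        raise ValueError(f"unknown method {method!r}")
    ordered = sorted(ms, key=lambda m: (-m.score, m.database_id))
    ordering = [m.database_id for m in ordered]
    if k_report is not None:
        ordering_view = ordering[:k_report]
    else:
        ordering_view = ordering
    true_rank = None
    if true_id is not None and true_id in ordering:
        true_rank = ordering.index(true_id) + 1
    return RankingResult(
        query_id=query.crop_id,
        ordering=ordering_view,
        scores={m.database_id: m.score for m in ms},
        true_match_rank=true_rank,
    )
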