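"""Synthetic coat-pattern photo catalogs with ground truth.

Generates seeded catalogs of quadruped "photos" that carry the statistical
structure an individual re-identification pipeline assumes:

* each individual bears a persistent three-tone (black / tan / white) blotch
  pattern, generated independently for the left and right flank;
* two population regimes differ in pattern contrast through the proportion
  of white and tan fur (the low-contrast default has ~7x less white and
  ~1.5x less tan fur than the high-contrast one);
* photos vary in pose (standing / lying), body rotation out of the image
  plane, occlusion, image quality (1-3 degradation ladder) and background
  (plain or cluttered), across "days".

All randomness flows from integer seeds through ``numpy.random.SeedSequence``
so catalogs are bit-reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize

__all__ = [
    "PopulationParams",
    "SyntheticIndividual",
    "GroundTruthObject",
    "AnnotatedImage",
    "kenya_like",
    "zimbabwe_like",
    "generate_pattern",
    "render_photo",
    "generate_catalog",
    "save_catalog",
    "load_catalog",
    "pose_dataset",
    "flank_dataset",
]

# tone labels -> RGB; tones chosen for strong gradient contrast at blotch edges
TONE_RGB = np.array(
    [
        [45, 40, 36],     # 0: black
        [176, 124, 66],   # 1: tan
        [238, 232, 220],  # 2: white
    ],
    dtype=np.uint8,
)

TEXTURE_HW = (96, 160)  # (rows, cols) of the flank texture map


@dataclass
class PopulationParams:
    """Parameters of one synthetic population / catalog regime.

    ``frac_white`` and ``frac_tan`` are the target proportions of white and
    tan fur in each individual's pattern (remainder is black), the knob that
    realizes the between-population contrast difference.  ``blotch_scale``
    is the correlation length of the pattern in texture pixels.
    """

    name: str = "population"
    frac_white: float = 0.05
    frac_tan: float = 0.25
    blotch_scale: float = 6.0
    n_individuals: int = 20
    photos_per_individual: int = 2
    p_lying: float = 0.0
    rotation_sd: float = 12.0
    occlusion_prob: float = 0.3
    quality_mix: tuple[float, float, float] = (0.25, 0.40, 0.35)
    background: Literal["plain", "cluttered"] = "plain"
    seed: int = 0
    image_hw: tuple[int, int] = (192, 256)
    n_sites: int = 6  # camera stations; each has a fixed background scene

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_white <= 1.0 and 0.0 <= self.frac_tan <= 1.0):
            raise ValueError("frac_white and frac_tan must lie in [0, 1]")
        if self.frac_white + self.frac_tan > 1.0 + 1e-12:
            raise ValueError("frac_white + frac_tan must not exceed 1")
        if self.blotch_scale <= 0:
            raise ValueError("blotch_scale must be positive")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for p in (self.p_lying, self.occlusion_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        q = np.asarray(self.quality_mix, dtype=float)
        if q.shape != (3,) or np.any(q < 0) or not np.isclose(q.sum(), 1.0):
            raise ValueError("quality_mix must be 3 nonnegative weights summing to 1")
        if self.background not in ("plain", "cluttered"):
            raise ValueError("background must be 'plain' or 'cluttered'")


def kenya_like(**overrides) -> PopulationParams:
    """Low-contrast regime: dark coats, little white or tan fur."""
    base = dict(name="kenya-like", frac_white=0.05, frac_tan=0.25)
    base.update(overrides)
    return PopulationParams(**base)


def zimbabwe_like(**overrides) -> PopulationParams:
    """High-contrast regime: ~7x the white and ~1.5x the tan fur of
    :func:`kenya_like`."""
    base = dict(name="zimbabwe-like", frac_white=0.35, frac_tan=0.38)
    base.update(overrides)
    return PopulationParams(**base)


@dataclass
class SyntheticIndividual:
    """An identity with two independent persistent flank patterns."""

    individual_id: str
    left_pattern: np.ndarray   # int8 tone labels, TEXTURE_HW
    right_pattern: np.ndarray
    population: str = ""

    def pattern(self, side: str) -> np.ndarray:
        if side == "left":
            return self.left_pattern
        if side == "right":
            return self.right_pattern
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")


@dataclass
class GroundTruthObject:
    individual_id: str
    bbox: tuple[int, int, int, int]  # (x, y, w, h), 0-based, half-open
    pose: Literal["standing", "lying"]
    side: Literal["left", "right"]
    flank_visible_frac: float
    rotation_deg: float
    quality_score: int
    mask: np.ndarray | None = None  # bool, aligned to bbox (h, w)
    flank_bbox: tuple[int, int, int, int] | None = None  # torso box, image coords

    def is_suitable(self) -> bool:
        """Suitability for matching: >=80% of the flank visible, body
        rotation under ~30 degrees, standing."""
        return (
            self.flank_visible_frac >= 0.8
            and self.rotation_deg < 30.0
            and self.pose == "standing"
        )


@dataclass
class AnnotatedImage:
    image_id: str
    day: int
    pixels: np.ndarray  # uint8 H x W x 3
    objects: list[GroundTruthObject] = field(default_factory=list)


# ---------------------------------------------------------------------------
# pattern generation
# ---------------------------------------------------------------------------

def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def _rng_for(seed: int, *tokens) -> np.random.Generator:
    entropy = [int(seed) & 0x7FFFFFFF]
    for t in tokens:
        entropy.append(_stable_hash(str(t)))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def generate_pattern(
    params: PopulationParams,
    individual_id: str,
    side: Literal["left", "right"],
    seed: int | None = None,
) -> np.ndarray:
    """Generate one flank's three-tone blotch pattern.

    A seeded white-noise field is smoothed with a Gaussian kernel of width
    ``blotch_scale`` and thresholded at the ``1 - frac_white - frac_tan``
    and ``1 - frac_white`` quantiles, so realized tone proportions track the
    population targets closely.  Deterministic in ``(seed, id, side)``;
    left and right patterns are independent draws.

    Returns an int8 array of tone labels (0 black, 1 tan, 2 white) of shape
    ``TEXTURE_HW``.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if params.blotch_scale <= 0:
        raise ValueError("blotch_scale must be positive")
    if seed is None:
        seed = params.seed
    rng = _rng_for(seed, "pattern", individual_id, side)
    noise = rng.standard_normal(TEXTURE_HW)
    fld = ndi.gaussian_filter(noise, sigma=params.blotch_scale, mode="wrap")
    labels = np.zeros(TEXTURE_HW, dtype=np.int8)
    fw, ft = params.frac_white, params.frac_tan
    if ft > 0 or fw > 0:
        q_lo = np.quantile(fld, 1.0 - fw - ft)
        labels[fld > q_lo] = 1
    if fw > 0:
        q_hi = np.quantile(fld, 1.0 - fw)
        labels[fld > q_hi] = 2
    return labels


def make_individual(
    params: PopulationParams, individual_id: str, seed: int | None = None
) -> SyntheticIndividual:
    return SyntheticIndividual(
        individual_id=individual_id,
        left_pattern=generate_pattern(params, individual_id, "left", seed),
        right_pattern=generate_pattern(params, individual_id, "right", seed),
        population=params.name,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _plain_background(hw: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = hw
    base = np.array([150, 142, 110], dtype=float)  # dry grass
    grad = np.linspace(-12, 12, h)[:, None, None]
    noise = ndi.gaussian_filter(rng.standard_normal((h, w)), 18)[..., None] * 10
    img = base[None, None, :] + grad + noise
    return np.clip(img, 0, 255).astype(np.uint8)


def _cluttered_background(hw: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = hw
    img = _plain_background(hw, rng).astype(float)
    # sharp-edged vegetation/rock blobs -> genuine background keypoints
    for _ in range(25):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        ry, rx = rng.integers(4, h // 5), rng.integers(4, w // 5)
        color = rng.uniform(30, 225, size=3)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rng.uniform(0, np.pi))
        img[rr, cc] = color
    # branch-like strokes
    for _ in range(12):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        ang = rng.uniform(0, np.pi)
        length = rng.integers(w // 6, w // 2)
        t = np.arange(length)
        rr = np.clip((r0 + t * np.sin(ang)).astype(int), 0, h - 1)
        cc = np.clip((c0 + t * np.cos(ang)).astype(int), 0, w - 1)
        shade = rng.uniform(20, 90)
        for dr in (-1, 0, 1):
            img[np.clip(rr + dr, 0, h - 1), cc] = shade
    return np.clip(img, 0, 255).astype(np.uint8)


def _quadruped_mask(
    hw: tuple[int, int],
    pose: str,
    fore: float,
    jitter: tuple[int, int],
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[float, float, float, float]]:
    """Binary silhouette (head at right) + torso region + head region +
    torso bbox.

    ``fore`` is the horizontal foreshortening factor cos(rotation); all x
    coordinates scale toward the body center.  Returns (body_mask,
    torso_mask, head_mask, torso bbox (x0, y0, x1, y1)) in canvas
    coordinates.  The coat pattern covers the whole body except the head,
    which stays dark (as on real wild dogs); the torso box is the "flank
    crop" a user would draw by hand.
    """
    h, w = hw
    h, w = h * scale, w * scale  # camera distance scales every body part
    dy, dx = jitter
    cx, cy = w * 0.46 + dx + (hw[1] - w) / 2, h * 0.44 + dy + (hw[0] - h) / 2
    hw = tuple(hw)

    def fx(x):  # foreshorten about body center
        return cx + (x - cx) * fore

    body = np.zeros(hw, dtype=bool)
    torso = np.zeros(hw, dtype=bool)
    head = np.zeros(hw, dtype=bool)

    if pose == "standing":
        ax, ay = w * 0.30, h * 0.17
        t_cy = cy
    else:  # lying: squat, wide, low
        ax, ay = w * 0.36, h * 0.115
        t_cy = cy + h * 0.18
    rr, cc = draw_ellipse(t_cy, cx, ay, ax * fore, shape=hw)
    body[rr, cc] = True
    torso[rr, cc] = True
    x0, x1 = fx(cx - ax), fx(cx + ax)
    y0, y1 = t_cy - ay, t_cy + ay

    # head + neck (right end), drawn for both poses
    neck_x = cx + ax * 0.92
    head_cy = t_cy - ay * (1.5 if pose == "standing" else 1.1)
    head_cx = fx(neck_x + w * 0.07)
    rr, cc = draw_polygon(
        [t_cy, head_cy - h * 0.03, head_cy + h * 0.02, t_cy + ay * 0.5],
        [fx(neck_x - w * 0.05), fx(neck_x + w * 0.05), fx(neck_x + w * 0.09), fx(neck_x + w * 0.02)],
        shape=hw,
    )
    body[rr, cc] = True
    rr, cc = draw_ellipse(head_cy, head_cx, h * 0.055, w * 0.055 * fore, shape=hw)
    body[rr, cc] = True
    head[rr, cc] = True
    # snout
    rr, cc = draw_polygon(
        [head_cy - h * 0.02, head_cy + h * 0.025, head_cy + h * 0.01],
        [fx(neck_x + w * 0.09), fx(neck_x + w * 0.09), fx(neck_x + w * 0.16)],
        shape=hw,
    )
    body[rr, cc] = True
    head[rr, cc] = True
    # rounded ears
    rr, cc = draw_ellipse(head_cy - h * 0.065, head_cx - w * 0.015 * fore, h * 0.035, w * 0.022 * fore, shape=hw)
    body[rr, cc] = True
    head[rr, cc] = True

    # tail (left end, drooping)
    rr, cc = draw_polygon(
        [t_cy - ay * 0.3, t_cy - ay * 0.1, t_cy + ay * 1.6, t_cy + ay * 1.8],
        [fx(cx - ax * 1.02), fx(cx - ax * 0.85), fx(cx - ax * 1.18), fx(cx - ax * 1.28)],
        shape=hw,
    )
    body[rr, cc] = True

    if pose == "standing":
        # four legs to ~0.85 H
        leg_bottom = cy + h * 0.40
        for lx in (cx - ax * 0.75, cx - ax * 0.55, cx + ax * 0.55, cx + ax * 0.78):
            half = w * 0.017
            rr, cc = draw_polygon(
                [t_cy, t_cy, leg_bottom, leg_bottom],
                [fx(lx - half), fx(lx + half), fx(lx + half * 0.8), fx(lx - half * 0.8)],
                shape=hw,
            )
            body[rr, cc] = True

    return body, torso, head, (x0, y0, x1, y1)


def _texture_body(
    canvas: np.ndarray,
    region: np.ndarray,
    torso_bbox: tuple[float, float, float, float],
    pattern: np.ndarray,
) -> None:
    """Paint the flank pattern onto the body in place.

    Texture coordinates are anchored to the torso box and wrap beyond it,
    so legs and tail carry the individual's pattern consistently across
    renders while the torso shows it exactly once.
    """
    ys, xs = np.nonzero(region)
    x0, y0, x1, y1 = torso_bbox
    th, tw = pattern.shape
    u = ((xs - x0) / max(x1 - x0, 1e-9)) % 1.0
    v = ((ys - y0) / max(y1 - y0, 1e-9)) % 1.0
    tones = pattern[(v * th).astype(int), (u * tw).astype(int)]
    canvas[ys, xs] = TONE_RGB[tones]


def _elastic_warp(
    canvas: np.ndarray, visible: np.ndarray, rng: np.random.Generator,
    amplitude_px: float | None = None, field_sigma: float = 24.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded smooth elastic deformation of the whole frame.

    Emulates body articulation, perspective and small camera shifts between
    photos: the same individual is never seen in pixel-identical geometry
    twice.  Deformation strength varies photo to photo (drawn uniformly
    from 3-12 px RMS, i.e. up to ~18% of torso height).  The visibility
    mask is warped with the same field.
    """
    h, w = visible.shape
    if amplitude_px is None:
        amplitude_px = float(rng.uniform(3.0, 12.0))
    dy = ndi.gaussian_filter(rng.standard_normal((h, w)), field_sigma)
    dx = ndi.gaussian_filter(rng.standard_normal((h, w)), field_sigma)
    for d in (dy, dx):
        rms = np.sqrt(np.mean(d ** 2))
        d *= amplitude_px / max(rms, 1e-9)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.array([np.clip(rr + dy, 0, h - 1), np.clip(cc + dx, 0, w - 1)])
    warped = np.stack(
        [ndi.map_coordinates(canvas[..., ch].astype(float), coords, order=1)
         for ch in range(canvas.shape[2])], axis=-1,
    )
    vis = ndi.map_coordinates(visible.astype(np.uint8), coords, order=0).astype(bool)
    return np.clip(warped, 0, 255).astype(np.uint8), vis


def _photometric_variation(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-photo illumination (brightness + gamma) and sensor noise.

    Day-to-day lighting differences and sensor noise are what erode
    low-contrast patterns in the field, so they are always on; all draws
    come from the photo's seeded generator.
    """
    out = img.astype(float) / 255.0
    gain = rng.uniform(0.65, 1.25)
    gamma = rng.uniform(0.8, 1.25)
    out = np.clip(out * gain, 0, 1) ** gamma
    out = out * 255.0 + rng.normal(0.0, 5.0, size=img.shape)
    return np.clip(out, 0, 255).astype(np.uint8)


def _degrade_quality(img: np.ndarray, quality_score: int) -> np.ndarray:
    """Monotone degradation ladder: 3 untouched, 2 mild blur, 1 heavy blur +
    horizontal motion streak + halved contrast."""
    if quality_score == 3:
        return img
    out = img.astype(float)
    if quality_score == 2:
        out = ndi.gaussian_filter(out, sigma=(1.0, 1.0, 0))
    elif quality_score == 1:
        out = ndi.gaussian_filter(out, sigma=(3.0, 3.0, 0))
        out = ndi.uniform_filter1d(out, size=9, axis=1)
        out = out.mean() + 0.5 * (out - out.mean())
    else:
        raise ValueError("quality_score must be 1, 2 or 3")
    return np.clip(out, 0, 255).astype(np.uint8)


def render_photo(
    individual: SyntheticIndividual,
    pose: Literal["standing", "lying"] = "standing",
    side: Literal["left", "right"] = "right",
    rotation_deg: float = 0.0,
    occlusion_frac: float = 0.0,
    quality_score: int = 3,
    background: Literal["plain", "cluttered"] = "plain",
    day: int = 0,
    seed: int = 0,
    image_hw: tuple[int, int] = (192, 256),
    image_id: str | None = None,
    background_seed: int | None = None,
    scale: float | None = None,
) -> AnnotatedImage:
    """Render one annotated photo of ``individual``.

    The silhouette is a fixed polygonal quadruped, foreshortened horizontally
    by cos(rotation_deg); the flank texture is the side's persistent pattern.
    Left-flank views are the horizontal mirror of the canonical head-right
    geometry.  Occlusion covers ``occlusion_frac`` of the torso with a
    background-toned block, and ground-truth fields are populated exactly.

    ``background_seed`` decouples the background scene from the photo:
    photos taken at the same camera station share it, so cluttered scenes
    recur across days the way fixed-station backgrounds do in the field.
    """
    if not 0.0 <= rotation_deg < 90.0:
        raise ValueError("rotation_deg must lie in [0, 90)")
    if not 0.0 <= occlusion_frac <= 1.0:
        raise ValueError("occlusion_frac must lie in [0, 1]")
    if pose not in ("standing", "lying"):
        raise ValueError("pose must be 'standing' or 'lying'")

    rng = _rng_for(seed, "photo", individual.individual_id, side, day)
    bg_rng = rng if background_seed is None else _rng_for(background_seed, "scene")
    h, w = image_hw
    if background == "cluttered":
        canvas = _cluttered_background(image_hw, bg_rng).copy()
    else:
        canvas = _plain_background(image_hw, bg_rng).copy()

    jitter = (int(rng.integers(-8, 9)), int(rng.integers(-10, 11)))
    if scale is None:
        scale = float(rng.uniform(0.7, 1.15))  # camera distance varies
    fore = float(np.cos(np.deg2rad(rotation_deg)))
    body, torso, head, torso_bbox = _quadruped_mask(image_hw, pose, fore, jitter, scale)

    # head stays dark; the rest of the body carries the coat pattern
    canvas[body] = TONE_RGB[0]
    _texture_body(canvas, body & ~head, torso_bbox, individual.pattern(side))

    visible = body.copy()
    if occlusion_frac > 0:
        x0, y0, x1, y1 = torso_bbox
        occ_x1 = x0 + occlusion_frac * (x1 - x0)
        xs = np.arange(w)
        strip = (xs >= x0 - 2) & (xs <= occ_x1)
        cols = np.nonzero(strip)[0]
        occ_color = np.array([96, 110, 60], dtype=np.uint8)  # vegetation block
        r0 = max(int(y0) - 6, 0)
        r1 = min(int(y1) + (int(0.45 * h) if pose == "standing" else 10), h)
        canvas[r0:r1, cols] = occ_color
        visible[r0:r1, cols] = False

    if side == "left":
        canvas = canvas[:, ::-1].copy()
        visible = visible[:, ::-1].copy()

    canvas, visible = _elastic_warp(canvas, visible, rng)  # articulation
    canvas = _degrade_quality(canvas, quality_score)       # then optics,
    canvas = _photometric_variation(canvas, rng)           # then sensor

    ys, xs = np.nonzero(visible)
    if ys.size == 0:  # fully occluded: degenerate but legal
        bbox = (0, 0, 1, 1)
        mask = np.zeros((1, 1), dtype=bool)
    else:
        x0i, x1i = int(xs.min()), int(xs.max()) + 1
        y0i, y1i = int(ys.min()), int(ys.max()) + 1
        bbox = (x0i, y0i, x1i - x0i, y1i - y0i)
        mask = visible[y0i:y1i, x0i:x1i]

    vis_frac = 1.0 - occlusion_frac
    if pose == "lying":
        vis_frac *= 0.35  # folded posture hides most of the flank

    tx0, ty0, tx1, ty1 = torso_bbox
    if side == "left":
        tx0, tx1 = w - tx1, w - tx0
    tx0, ty0 = max(0, int(tx0)), max(0, int(ty0))
    tx1, ty1 = min(w, int(np.ceil(tx1))), min(h, int(np.ceil(ty1)))
    flank_bbox = (tx0, ty0, max(1, tx1 - tx0), max(1, ty1 - ty0))

    obj = GroundTruthObject(
        individual_id=individual.individual_id,
        bbox=bbox,
        pose=pose,
        side=side,
        flank_visible_frac=vis_frac,
        rotation_deg=float(rotation_deg),
        quality_score=int(quality_score),
        mask=mask,
        flank_bbox=flank_bbox,
    )
    if image_id is None:
        image_id = f"{individual.individual_id}_d{day}_{side}_{seed}"
    return AnnotatedImage(image_id=image_id, day=day, pixels=canvas, objects=[obj])


# ---------------------------------------------------------------------------
# catalogs
# ---------------------------------------------------------------------------

def generate_catalog(params: PopulationParams) -> list[AnnotatedImage]:
    """Generate a full seeded catalog for one population.

    Every individual receives ``photos_per_individual`` photos on distinct
    days.  The first two photos per individual are guaranteed suitable
    right-flank standing views so a two-crop different-day matching task is
    always constructible; if four or more photos are requested, photos 3-4
    are the same guarantee for the left flank.  Remaining photos sample
    pose, rotation, occlusion and side freely from the population mix.
    """
    if params.photos_per_individual < 2:
        raise ValueError("photos_per_individual must be >= 2")
    rng = _rng_for(params.seed, "catalog", params.name)
    images: list[AnnotatedImage] = []
    qmix = np.asarray(params.quality_mix, dtype=float)
    for i in range(params.n_individuals):
        ind_id = f"{params.name}-{i:03d}"
        ind = make_individual(params, ind_id)
        for j in range(params.photos_per_individual):
            quality = int(rng.choice([1, 2, 3], p=qmix))
            if j < 2 or (j < 4 and params.photos_per_individual >= 4):
                # guaranteed-suitable photos still span the full suitability
                # envelope: rotation under ~30 deg, >=80% of flank visible
                side = "right" if j < 2 else "left"
                pose = "standing"
                rot = float(min(abs(rng.normal(0.0, params.rotation_sd)), 28.0))
                occ = (float(rng.uniform(0.05, 0.20))
                       if rng.random() < params.occlusion_prob else 0.0)
            else:
                side = "right" if rng.random() < 0.5 else "left"
                pose = "lying" if rng.random() < params.p_lying else "standing"
                rot = float(min(abs(rng.normal(0.0, params.rotation_sd)), 85.0))
                occ = float(rng.uniform(0.25, 0.6)) if rng.random() < params.occlusion_prob else 0.0
            site = int(rng.integers(params.n_sites))
            img = render_photo(
                ind,
                pose=pose,
                side=side,
                rotation_deg=rot,
                occlusion_frac=occ,
                quality_score=quality,
                background=params.background,
                day=j,
                seed=int(rng.integers(0, 2**31 - 1)),
                image_hw=params.image_hw,
                image_id=f"{ind_id}_p{j}",
                background_seed=int(_rng_for(params.seed, "site", site).integers(0, 2**31 - 1)),
            )
            images.append(img)
    return images


def _mask_to_rle(mask: np.ndarray) -> dict:
    """Uncompressed COCO-style RLE (column-major counts)."""
    flat = np.asarray(mask, dtype=np.uint8).flatten(order="F")
    # counts alternate runs of 0s and 1s, starting with 0s
    change = np.nonzero(np.diff(flat))[0] + 1
    runs = np.diff(np.concatenate([[0], change, [flat.size]])).tolist()
    if flat.size and flat[0] == 1:
        runs = [0] + runs
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": runs}


def _rle_to_mask(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for run in rle["counts"]:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape((h, w), order="F")


def save_catalog(images: Sequence[AnnotatedImage], out_dir: str | Path) -> Path:
    """Write PNGs plus a COCO-style ``annotations.json``.

    Boxes are ``(x, y, w, h)``, 0-based and half-open; per-object foreground
    masks are stored as uncompressed RLE aligned to the box.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coco = {
        "images": [],
        "annotations": [],
        "categories": [{"id": 1, "name": "animal"}],
    }
    ann_id = 1
    for k, img in enumerate(images):
        fname = f"{img.image_id}.png"
        iio.imwrite(out_dir / fname, img.pixels)
        h, w = img.pixels.shape[:2]
        coco["images"].append(
            {"id": k, "file_name": fname, "width": w, "height": h,
             "image_id": img.image_id, "day": img.day}
        )
        for obj in img.objects:
            entry = {
                "id": ann_id,
                "image_id": k,
                "category_id": 1,
                "bbox": [int(v) for v in obj.bbox],
                "area": int(obj.bbox[2] * obj.bbox[3]),
                "iscrowd": 0,
                "attributes": {
                    "individual_id": obj.individual_id,
                    "pose": obj.pose,
                    "side": obj.side,
                    "flank_visible_frac": obj.flank_visible_frac,
                    "rotation_deg": obj.rotation_deg,
                    "quality_score": obj.quality_score,
                    "flank_bbox": None if obj.flank_bbox is None else [int(v) for v in obj.flank_bbox],
                },
            }
            if obj.mask is not None:
                entry["segmentation"] = _mask_to_rle(obj.mask)
            coco["annotations"].append(entry)
            ann_id += 1
    with open(out_dir / "annotations.json", "w") as fh:
        json.dump(coco, fh, indent=1, sort_keys=True)
    return out_dir / "annotations.json"


def load_catalog(in_dir: str | Path) -> list[AnnotatedImage]:
    in_dir = Path(in_dir)
    with open(in_dir / "annotations.json") as fh:
        coco = json.load(fh)
    by_idx: dict[int, AnnotatedImage] = {}
    for rec in coco["images"]:
        pixels = iio.imread(in_dir / rec["file_name"])
        by_idx[rec["id"]] = AnnotatedImage(
            image_id=rec.get("image_id", rec["file_name"]),
            day=rec.get("day", 0),
            pixels=np.asarray(pixels)[..., :3],
        )
    for ann in coco["annotations"]:
        attrs = ann.get("attributes", {})
        mask = _rle_to_mask(ann["segmentation"]) if "segmentation" in ann else None
        by_idx[ann["image_id"]].objects.append(
            GroundTruthObject(
                individual_id=attrs.get("individual_id", "unknown"),
                bbox=tuple(int(v) for v in ann["bbox"]),
                pose=attrs.get("pose", "standing"),
                side=attrs.get("side", "right"),
                flank_visible_frac=float(attrs.get("flank_visible_frac", 1.0)),
                rotation_deg=float(attrs.get("rotation_deg", 0.0)),
                quality_score=int(attrs.get("quality_score", 3)),
                mask=mask,
                flank_bbox=None if attrs.get("flank_bbox") is None
                else tuple(int(v) for v in attrs["flank_bbox"]),
            )
        )
    return [by_idx[k] for k in sorted(by_idx)]


# ---------------------------------------------------------------------------
# classifier task datasets
# ---------------------------------------------------------------------------

def _crop_resize_gray(img: AnnotatedImage, size: int) -> np.ndarray:
    x, y, w, h = img.objects[0].bbox
    patch = img.pixels[y : y + h, x : x + w].astype(np.float32) / 255.0
    gray = patch @ np.array([0.299, 0.587, 0.114], dtype=np.float32)
    return resize(gray, (size, size), anti_aliasing=True).astype(np.float32)


def pose_dataset(
    n: int, size: int = 64, seed: int = 0, params: PopulationParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Standing (label 1) vs lying (label 0) crops, ``n`` per class,
    returned as ``(X, y)`` with X of shape (2n, size, size, 1)."""
    params = params or PopulationParams(name="posetask", seed=seed)
    rng = _rng_for(seed, "pose_dataset")
    X, y = [], []
    for i in range(n):
        ind = make_individual(params, f"pose-{i:04d}", seed)
        for pose, label in (("standing", 1), ("lying", 0)):
            img = render_photo(
                ind,
                pose=pose,
                side="right" if rng.random() < 0.5 else "left",
                rotation_deg=float(min(abs(rng.normal(0, 10.0)), 40.0)),
                quality_score=int(rng.choice([2, 3])),
                background=params.background,
                day=0,
                seed=int(rng.integers(0, 2**31 - 1)),
                image_hw=params.image_hw,
            )
            X.append(_crop_resize_gray(img, size))
            y.append(label)
    X = np.stack(X)[..., None]
    y = np.array(y, dtype=np.int64)
    order = _rng_for(seed, "pose_shuffle").permutation(len(y))
    return X[order], y[order]


def flank_dataset(
    n: int, size: int = 64, seed: int = 0, params: PopulationParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Left (label 0) vs right (label 1) standing flank crops, ``n`` per
    class."""
    params = params or PopulationParams(name="flanktask", seed=seed)
    rng = _rng_for(seed, "flank_dataset")
    X, y = [], []
    for i in range(n):
        ind = make_individual(params, f"flank-{i:04d}", seed)
        for side, label in (("left", 0), ("right", 1)):
            img = render_photo(
                ind,
                pose="standing",
                side=side,
                rotation_deg=float(min(abs(rng.normal(0, 10.0)), 28.0)),
                quality_score=int(rng.choice([2, 3])),
                background=params.background,
                day=0,
                seed=int(rng.integers(0, 2**31 - 1)),
                image_hw=params.image_hw,
            )
            X.append(_crop_resize_gray(img, size))
            y.append(label)
    X = np.stack(X)[..., None]
    y = np.array(y, dtype=np.int64)
    order = _rng_for(seed, "flank_shuffle").permutation(len(y))
    return X[order], y[order]
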