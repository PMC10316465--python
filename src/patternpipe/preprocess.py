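"""Crop suitability filtering and background removal.

Two cheap preprocessing stages sit between detection and matching:

1. **Aspect-ratio filtering.**  Crops where the flank is rotated away from
   the camera or partly occluded are narrower than suitable crops, while
   lying animals produce much wider crops, so the width/height ratio is a
   usable proxy for suitability.  The operating range is derived as the
   [min, max] of the ratios of crops labelled suitable (the canonical field
   value is [0.65, 2.25]); bounds are inclusive so the defining crops keep
   themselves in range.

2. **Background removal.**  Matching should key on the coat pattern, not
   the background or the silhouette edge.  Masks come either from ground
   truth (oracle mode, available for synthetic catalogs) or from a
   classical seeded estimator: pixels are scored by color distance to the
   border's background estimate, thresholded by Otsu, and cleaned
   morphologically.  When an estimated mask is degenerate the crop falls
   back to its unmasked state with a failure flag, mirroring how a real
   matting network occasionally crops out foreground vegetation instead of
   the animal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "Crop",
    "AspectRange",
    "derive_aspect_range",
    "aspect_filter",
    "estimate_mask",
    "remove_background",
    "flank_crop",
    "DEFAULT_ASPECT_RANGE",
]

BACKGROUND_FILL = (0, 0, 0)


@dataclass
class Crop:
    """A detector-produced sub-image with provenance and optional ground
    truth attributes / foreground mask."""

    crop_id: str
    pixels: np.ndarray  # uint8 h x w x 3
    provenance: tuple[str, tuple[int, int, int, int]] | None = None
    attributes: dict | None = None
    mask: np.ndarray | None = None  # bool, same h x w as pixels
    day: int = 0
    background_removed: bool = False
    mask_failed: bool = False
    fill: Literal["soft", "black"] | None = None  # set by remove_background

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be h x w x 3")
        if self.mask is not None and self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask shape must match pixels")

    @property
    def aspect_ratio(self) -> float:
        h, w = self.pixels.shape[:2]
        return w / h

    @property
    def individual_id(self) -> str | None:
        return (self.attributes or {}).get("individual_id")


@dataclass(frozen=True)
class AspectRange:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo <= self.hi:
            raise ValueError("require 0 < lo <= hi")

    def __contains__(self, ratio: float) -> bool:
        return self.lo <= ratio <= self.hi


DEFAULT_ASPECT_RANGE = AspectRange(0.65, 2.25)


def derive_aspect_range(
    crops: Sequence[Crop], suitable: Sequence[bool]
) -> AspectRange:
    """Operating range = exact [min, max] aspect ratio over crops labelled
    suitable.  Raises ``ValueError`` when no crop is labelled suitable."""
    ratios = [c.aspect_ratio for c, s in zip(crops, suitable) if s]
    if not ratios:
        raise ValueError("no suitable crops: aspect range is empty")
    return AspectRange(min(ratios), max(ratios))


def aspect_filter(
    crops: Iterable[Crop], range_: AspectRange = DEFAULT_ASPECT_RANGE
) -> tuple[list[Crop], list[Crop]]:
    """Partition crops into (kept, removed) by inclusive aspect-ratio range."""
    kept, removed = [], []
    for c in crops:
        (kept if c.aspect_ratio in range_ else removed).append(c)
    return kept, removed


def flank_crop(crop: Crop) -> Crop:
    """Cut the rectangular flank-only sub-crop (the box a user would draw
    by hand around the torso) from a full-animal crop.

    Requires the crop to carry a ``flank_bbox_crop`` attribute; returns the
    crop unchanged when it does not.  This is the unmasked baseline that
    background removal of the full individual is compared against.
    """
    fb = (crop.attributes or {}).get("flank_bbox_crop")
    if fb is None:
        return crop
    fx, fy, fw, fh = fb
    pixels = crop.pixels[fy : fy + fh, fx : fx + fw].copy()
    if pixels.shape[0] < 1 or pixels.shape[1] < 1:
        return crop
    mask = None
    if crop.mask is not None:
        mask = crop.mask[fy : fy + fh, fx : fx + fw].copy()
    attrs = dict(crop.attributes or {})
    attrs.pop("flank_bbox_crop", None)
    return replace(crop, crop_id=crop.crop_id + "~f", pixels=pixels,
                   mask=mask, attributes=attrs)


def estimate_mask(
    crop: Crop, mode: Literal["oracle", "estimate"] = "estimate"
) -> tuple[np.ndarray, bool]:
    """Estimate the animal's foreground mask for one crop.

    Returns ``(mask, degenerate)`` where ``degenerate`` is set when the
    estimate covers (almost) none or all of the crop.  In oracle mode the
    ground-truth mask is returned when present.
    """
    if crop.pixels.size == 0:
        raise ValueError("empty crop")
    if mode == "oracle" and crop.mask is not None:
        frac = crop.mask.mean()
        return crop.mask.copy(), bool(frac < 0.01 or frac > 0.99)

    img = ndi.gaussian_filter(crop.pixels.astype(float), sigma=(1.5, 1.5, 0))
    h, w = img.shape[:2]
    # corner patches: a tight box around a roughly elliptical animal leaves
    # the corners as the cleanest background samples
    ph, pw = max(2, h // 8), max(2, w // 8)
    corners = np.concatenate([
        img[:ph, :pw].reshape(-1, 3), img[:ph, -pw:].reshape(-1, 3),
        img[-ph:, :pw].reshape(-1, 3), img[-ph:, -pw:].reshape(-1, 3),
    ])
    bg = np.median(corners, axis=0)
    dist = np.linalg.norm(img - bg, axis=2)
    if dist.max() - dist.min() < 1e-6:
        return np.zeros((h, w), dtype=bool), True  # uniform crop
    try:
        thr = threshold_otsu(dist)
    except ValueError:
        return np.zeros((h, w), dtype=bool), True
    # Otsu over-segments here: within-animal color variance (three-tone
    # coat) is large, so relax the cut to keep dark limbs and coat borders
    fg = dist > 0.7 * thr
    fg = ndi.binary_closing(fg, structure=np.ones((9, 9)))
    fg = ndi.binary_fill_holes(fg)
    lab = cc_label(fg)
    if lab.max() > 0:
        sizes = np.bincount(lab.ravel())[1:]
        fg = lab == (1 + int(np.argmax(sizes)))
    frac = fg.mean()
    return fg, bool(frac < 0.01 or frac > 0.99)


def remove_background(
    crop: Crop,
    mask: np.ndarray | None = None,
    min_fg: float = 0.05,
    max_fg: float = 0.95,
    mode: Literal["oracle", "estimate"] = "estimate",
    fill: Literal["soft", "black"] = "soft",
    soft_sigma: float = 8.0,
) -> Crop:
    """Return a copy of ``crop`` with background pixels suppressed.

    ``fill="soft"`` (default) replaces the background with a strongly
    low-passed version of the scene: background gradients — and hence
    spurious keypoints — vanish, while no artificial silhouette edge is
    introduced (a hard edge on a blurred photo would otherwise dominate
    the scale space and contaminate nearby pattern descriptors).
    ``fill="black"`` zeroes the background outright; feature extraction
    then suppresses keypoints near the mask boundary.

    A mask whose foreground fraction lies outside ``[min_fg, max_fg]`` is
    judged failed; the crop is then returned unmasked with ``mask_failed``
    set (fallback to the rectangular crop).  Pixels under the mask are
    never altered.
    """
    if mask is None:
        mask, _ = estimate_mask(crop, mode=mode)
    if mask.shape != crop.pixels.shape[:2]:
        raise ValueError("mask shape must match crop")
    frac = float(mask.mean())
    if frac < min_fg or frac > max_fg:
        return replace(crop, mask_failed=True)
    pixels = crop.pixels.copy()
    if fill == "soft":
        blurred = ndi.gaussian_filter(crop.pixels.astype(float),
                                      sigma=(soft_sigma, soft_sigma, 0))
        pixels[~mask] = np.clip(blurred, 0, 255).astype(np.uint8)[~mask]
    elif fill == "black":
        pixels[~mask] = BACKGROUND_FILL
    else:
        raise ValueError("fill must be 'soft' or 'black'")
    return replace(
        crop, pixels=pixels, mask=mask.copy(), background_removed=True,
        mask_failed=False, fill=fill,
    )
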