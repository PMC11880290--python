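"""Label-mask and radiograph I/O with orientation canonicalization.

Masks are 8-bit indexed PNGs in the VOC palette convention
(background = 0).  Every mask read through :func:`read_label_mask` is
normalized so the distal direction points up (smaller row index) and,
for left wrists, mirrored so downstream sign conventions can assume a
right wrist.
"""

from __future__ import annotations

import enum
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

log = logging.getLogger(__name__)


class View(str, enum.Enum):
    AP = "AP"
    LAT = "LAT"


class Laterality(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


#: Part-name -> palette index, per view.
AP_LABELS = {"background": 0, "distal_radius": 1, "proximal_radius": 2, "ulna": 3}
LAT_LABELS = {"background": 0, "distal_radius": 1, "proximal_radius": 2}


def labels_for_view(view: View) -> dict[str, int]:
    return dict(AP_LABELS if View(view) is View.AP else LAT_LABELS)


def voc_palette(n: int = 256) -> np.ndarray:
    """Deterministic VOC color map as an (n, 3) uint8 array."""
    cmap = np.zeros((n, 3), dtype=np.uint8)
    for i in range(n):
        r = g = b = 0
        cid = i
        for j in range(8):
            r |= ((cid >> 0) & 1) << (7 - j)
            g |= ((cid >> 1) & 1) << (7 - j)
            b |= ((cid >> 2) & 1) << (7 - j)
            cid >>= 3
        cmap[i] = (r, g, b)
    return cmap


@dataclass
class LabelMask:
    """A per-view semantic label image plus acquisition metadata."""

    pixels: np.ndarray
    view: View
    labels: dict[str, int]
    pixel_spacing: float = 1.0
    laterality: Laterality = Laterality.UNKNOWN
    mirrored: bool = False  # set when a left wrist was mirrored at read time
    flipped: bool = False   # set when orientation was corrected at read time

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.view = View(self.view)
        self.laterality = Laterality(self.laterality)
        if self.pixels.ndim != 2:
            raise ValueError("mask pixels must be a 2D array")
        rows, cols = self.pixels.shape
        if rows < 64 or cols < 64:
            raise ValueError(f"mask too small: {rows}x{cols}, need at least 64x64")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        codes = set(self.labels.values())
        present = set(np.unique(self.pixels).tolist())
        unknown = sorted(present - codes)
        if unknown:
            raise ValueError(f"unknown label {unknown[0]}")

    def part_pixels(self, part: str) -> np.ndarray:
        if part not in self.labels:
            raise KeyError(f"part {part!r} not declared for view {self.view.value}")
        return self.pixels == self.labels[part]

    def part_count(self, part: str) -> int:
        return int(self.part_pixels(part).sum())


def _centroid_row(mask: np.ndarray) -> float:
    rows = np.nonzero(mask)[0]
    return float(rows.mean())


def normalize_orientation(mask: LabelMask) -> LabelMask:
    """Flip the mask vertically if the distal radius sits below the proximal.

    Idempotent: a canonical mask passes through unchanged, so applying
    the normalizer twice equals applying it once.
    """
    dr = mask.pixels == mask.labels["distal_radius"]
    pr = mask.pixels == mask.labels["proximal_radius"]
    if not dr.any() or not pr.any():
        return mask
    if _centroid_row(dr) > _centroid_row(pr):
        return replace(mask, pixels=np.flipud(mask.pixels).copy(), flipped=True)
    return mask


def canonicalize_laterality(mask: LabelMask) -> LabelMask:
    """Mirror left-wrist masks horizontally so all code assumes a right wrist."""
    if mask.laterality is Laterality.LEFT and not mask.mirrored:
        return replace(mask, pixels=np.fliplr(mask.pixels).copy(), mirrored=True)
    return mask


def read_metadata(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_label_mask(path, view: View, meta: dict | None = None) -> LabelMask:
    """Read an indexed-PNG label mask and canonicalize its orientation.

    ``meta`` is the sidecar record ``{pixel_spacing_mm, laterality, view}``;
    missing fields fall back to spacing 1.0 (reported in px) and unknown
    laterality.
    """
    meta = meta or {}
    img = Image.open(path)
    if img.mode == "P":
        arr = np.asarray(img, dtype=np.int64)
    elif img.mode in ("L", "I", "I;16"):
        arr = np.asarray(img.convert("I"), dtype=np.int64)
    else:
        raise ValueError(f"unsupported mask image mode {img.mode!r}")
    spacing = meta.get("pixel_spacing_mm")
    if spacing is None:
        spacing = 1.0
        log.warning("no pixel spacing in metadata for %s; reporting lengths in px", path)
    mask = LabelMask(
        pixels=arr,
        view=view,
        labels=labels_for_view(view),
        pixel_spacing=float(spacing),
        laterality=Laterality(meta.get("laterality", "unknown")),
    )
    mask = normalize_orientation(mask)
    mask = canonicalize_laterality(mask)
    return mask


def write_label_mask(mask: LabelMask, path) -> Path:
    """Write the mask as an 8-bit indexed PNG with the VOC palette."""
    path = Path(path)
    img = Image.fromarray(mask.pixels.astype(np.uint8), mode="P")
    img.putpalette(voc_palette().ravel().tolist())
    img.save(path, format="PNG")
    return path


@dataclass
class GrayImage:
    """An 8-bit grayscale radiograph."""

    pixels: np.ndarray = field()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("expected a non-empty 2D image")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")


def read_gray(path) -> GrayImage:
    return GrayImage(np.asarray(Image.open(path).convert("L"), dtype=np.int64))


def write_gray(img: GrayImage, path) -> Path:
    path = Path(path)
    Image.fromarray(img.pixels.astype(np.uint8), mode="L").save(path, format="PNG")
    return path


def equalize_histogram(img: GrayImage) -> GrayImage:
    """Global histogram equalization by cumulative-distribution mapping.

    The classic mapping ``round((cdf(v) - cdf_min) / (N - cdf_min) * 255)``
    stretches intensities toward the full 0..255 range while preserving
    the rank order of distinct input levels.  A constant image (degenerate
    histogram) is returned unchanged.
    """
    pix = img.pixels
    hist = np.bincount(pix.ravel().astype(np.int64), minlength=256)
    cdf = np.cumsum(hist)
    n = cdf[-1]
    occupied = hist > 0
    cdf_min = int(cdf[occupied][0])
    if n == cdf_min:  # single gray level
        return GrayImage(pix.copy())
    lut = np.rint((cdf - cdf_min) / (n - cdf_min) * 255.0).astype(np.int64)
    lut = np.clip(lut, 0, 255)
    return GrayImage(lut[pix])
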