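"""ECG-scan front-end: view cropping, bilinear resizing and horizontal
shift augmentation.

Coordinate convention: row 0 is the top of the page, indices are 0-based,
slices half-open. The 12-lead ("all12") view is a full-height square; the
limb view comes from the upper half and the precordial view from the lower
half of the page. Crops are anchored at a configurable leftmost column
(default 0) and shifted right by ``shift_offset`` pixels per iteration; the
number of crops per scan follows the per-grade multiplying factors
(base x3; severe AS x20, MR x44, LVD x42).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from cardiostack.synthetic import GRADES, EcgScan

__all__ = ["VIEWS", "EcgCropParams", "DEFAULT_SHIFT_COUNTS", "crop_view", "resize_view", "shift_augment", "max_feasible_shifts"]

VIEWS = ("all12", "limb", "precordial")

DEFAULT_SHIFT_COUNTS: dict[str, dict[str, int]] = {
    "AS": {"none": 3, "mild": 3, "moderate": 3, "severe": 20},
    "MR": {"none": 3, "mild": 3, "moderate": 3, "severe": 44},
    "LVD": {"none": 3, "mild": 3, "moderate": 3, "severe": 42},
}

# Default per-view offsets guarantee the largest published factor (x44) fits
# a 3187-px-wide page: floor((3187 - side) / 43).
_DEFAULT_CROP = {"all12": 1840, "limb": 960, "precordial": 960}
_DEFAULT_RESIZE = {"all12": 512, "limb": 256, "precordial": 256}
_DEFAULT_OFFSET = {"all12": 31, "limb": 51, "precordial": 51}


@dataclass
class EcgCropParams:
    view: str
    crop_side: int = 0
    resize_to: int = 0
    shift_offset: int = 0
    origin: int = 0  # leftmost column of the first crop
    shift_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}; expected one of {VIEWS}")
        if self.crop_side <= 0:
            self.crop_side = _DEFAULT_CROP[self.view]
        if self.resize_to <= 0:
            self.resize_to = _DEFAULT_RESIZE[self.view]
        if self.shift_offset <= 0:
            self.shift_offset = _DEFAULT_OFFSET[self.view]
        if not self.shift_counts:
            self.shift_counts = dict(DEFAULT_SHIFT_COUNTS["AS"])
        if self.shift_counts.get("severe", 1) < self.shift_counts.get("none", 1):
            raise ValueError("shift_counts[severe] must be >= shift_counts[none]")

    @classmethod
    def for_view(cls, view: str, disease: str = "AS", scale: float = 1.0, **kw) -> "EcgCropParams":
        """Defaults for one view, optionally geometrically scaled for small pages."""
        counts = kw.pop("shift_counts", dict(DEFAULT_SHIFT_COUNTS[disease]))
        p = cls(view=view, shift_counts=counts, **kw)
        if scale != 1.0:
            p.crop_side = max(2, round(p.crop_side * scale))
            p.resize_to = max(2, round(p.resize_to * scale))
            p.shift_offset = max(1, round(p.shift_offset * scale))
        return p


def crop_view(scan: EcgScan, params: EcgCropParams) -> np.ndarray:
    """Extract the square region for one view as an array slice."""
    h, w = scan.pixels.shape
    side = params.crop_side
    # A 960-px side exceeds the 920-px half of a full page, so half crops are
    # aligned to the page edge of their half: limb hugs the top, precordial
    # the bottom. When the side fits within a half they are centered in it.
    if params.view == "all12":
        top = 0
    elif params.view == "limb":
        top = max(0, h // 2 - side) // 2
    else:
        top = min(h - side, h // 2 + max(0, h // 2 - side) // 2)
    left = params.origin
    if top + side > h or left + side > w:
        raise ValueError(
            f"{params.view} crop of side {side} at (row {top}, col {left}) "
            f"exceeds page bounds {h} x {w}"
        )
    return scan.pixels[top : top + side, left : left + side]


def resize_view(image: np.ndarray, params: EcgCropParams) -> np.ndarray:
    """Bilinear downscale of a square crop to resize_to x resize_to."""
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"expected a square 2-D image, got shape {image.shape}")
    if image.shape[0] == params.resize_to:
        return image.copy()
    pil = Image.fromarray(image.astype(np.uint8), mode="L")
    out = pil.resize((params.resize_to, params.resize_to), Image.BILINEAR)
    return np.asarray(out)


def max_feasible_shifts(page_width: int, params: EcgCropParams) -> int:
    """Largest crop count fitting the page: floor((W - origin - side)/offset) + 1."""
    return (page_width - params.origin - params.crop_side) // params.shift_offset + 1


def shift_augment(scan: EcgScan, params: EcgCropParams, grade: str) -> list[np.ndarray]:
    """Produce ``shift_counts[grade]`` crops shifted right by ``shift_offset`` each,
    every crop resized per :func:`resize_view`."""
    if grade not in GRADES:
        raise ValueError(f"unknown grade {grade!r}")
    k = params.shift_counts.get(grade, params.shift_counts["none"])
    w = scan.pixels.shape[1]
    feasible = max_feasible_shifts(w, params)
    if k > feasible:
        raise ValueError(
            f"cannot fit {k} crops of side {params.crop_side} with offset "
            f"{params.shift_offset} on a {w}-px-wide page; maximal feasible count is {feasible}"
        )
    out = []
    for i in range(k):
        shifted = EcgCropParams(
            view=params.view,
            crop_side=params.crop_side,
            resize_to=params.resize_to,
            shift_offset=params.shift_offset,
            origin=params.origin + i * params.shift_offset,
            shift_counts=params.shift_counts,
        )
        out.append(resize_view(crop_view(scan, shifted), shifted))
    return out
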