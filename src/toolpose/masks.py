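"""Instance segmentation mask I/O, instance removal, pose-mask QC.

Masks are single-channel PNG images (``instrument_instances.png``): pixel
value 0 is background, value ``k > 0`` is instance ``k``.  Files are
written 8-bit when all labels fit in 255 and 16-bit otherwise; reading is
lossless either way.

The refinement operation mirrors the dataset's trocar-cannula cleanup:
selected instance ids are erased to background (surviving ids keep their
values — no re-indexing — so identity is stable across files).  A frame
whose only instances are removed becomes a completely empty (black) label
image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from PIL import Image

from .schema import ToolPose, Visibility

__all__ = [
    "InstanceMask",
    "MaskFormatError",
    "read_mask",
    "write_mask",
    "remove_instances",
    "pose_mask_consistency",
]


class MaskFormatError(ValueError):
    """The file on disk is not a single-channel integer-label PNG."""


@dataclass
class InstanceMask:
    """Integer-labelled instance mask: 0 = background, k > 0 = instance k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise MaskFormatError("mask must be a 2D label grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise MaskFormatError("mask labels must be integers")
        if self.labels.size and self.labels.min() < 0:
            raise MaskFormatError("mask labels must be non-negative")

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def instance_ids(self) -> list[int]:
        """Sorted nonzero instance ids present in the mask."""
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


def read_mask(path: str | Path) -> InstanceMask:
    """Read a single-channel integer PNG into an instance mask."""
    with Image.open(path) as img:
        if img.mode in ("L", "P"):
            arr = np.asarray(img.convert("L"), dtype=np.uint16)
        elif img.mode in ("I", "I;16", "I;16B"):
            arr = np.asarray(img.convert("I"), dtype=np.int64)
            if arr.size and arr.min() < 0:
                raise MaskFormatError(f"{path}: negative label values")
            arr = arr.astype(np.uint16)
        else:
            raise MaskFormatError(
                f"{path}: expected single-channel PNG, got mode {img.mode!r}")
    return InstanceMask(arr)


def write_mask(mask: InstanceMask, path: str | Path) -> None:
    """Write a mask as single-channel PNG (8-bit if labels <= 255, else 16-bit)."""
    labels = mask.labels
    high = int(labels.max()) if labels.size else 0
    if high > np.iinfo(np.uint16).max:
        raise MaskFormatError("labels exceed the 16-bit PNG range")
    if high <= 255:
        Image.fromarray(labels.astype(np.uint8), mode="L").save(path)
    else:
        # uint16 arrays map to true 16-bit greyscale PNG
        Image.fromarray(labels.astype(np.uint16)).save(path)


def remove_instances(mask: InstanceMask, ids: Iterable[int]) -> InstanceMask:
    """Erase the given instance ids to background, leaving the rest intact.

    Returns a new mask; the input is not modified.  Absent ids are no-ops,
    so the operation is idempotent and commutes over disjoint id sets.
    Pixel counts are conserved: every erased pixel becomes background.
    """
    ids = set(int(i) for i in ids)
    out = mask.labels.copy()
    if ids:
        out[np.isin(out, list(ids))] = 0
    return InstanceMask(out)


def pose_mask_consistency(pose: ToolPose, mask: InstanceMask,
                          radius: float) -> float:
    """Fraction of visible keypoints with instrument pixels within ``radius``.

    A quality-control heuristic: each visible keypoint should sit on (or
    near) some instrument instance in the paired mask.  Returns NaN for a
    pose without visible keypoints.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    visible = [kp for _, kp in pose.slots() if kp.tag is Visibility.VISIBLE]
    if not visible:
        return float("nan")
    h, w = mask.labels.shape
    r = int(np.ceil(radius))
    hits = 0
    for kp in visible:
        cx, cy = kp.x, kp.y
        x0, x1 = max(0, int(np.floor(cx - r))), min(w, int(np.ceil(cx + r)) + 1)
        y0, y1 = max(0, int(np.floor(cy - r))), min(h, int(np.ceil(cy + r)) + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        window = mask.labels[y0:y1, x0:x1]
        yy, xx = np.mgrid[y0:y1, x0:x1]
        near = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
        if np.any(window[near] > 0):
            hits += 1
    return hits / len(visible)
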