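"""Conversion between the pose data model and the COCO-style keypoint schema.

The export groups all instruments under a single category whose keypoint
order is fixed: EntryPoint, HingePoint, Tip1, Tip2.  Each annotation stores
twelve numbers as four ``(x, y, v)`` triplets with visibility codes

* ``v = 2`` — annotated and visible,
* ``v = 1`` — annotated and occluded, with both coordinates inside the frame,
* ``v = 0`` — not annotated: missing, or occluded outside the frame.

``num_keypoints`` counts triplets with ``v > 0``.  The bounding box is
derived from the keypoints with ``v > 0``: their axis-aligned extent,
expanded by a 20-pixel margin on every side, then clipped to the image
boundaries.  The stored ``area`` is the square of the box diagonal,
``w**2 + h**2`` — deliberately *not* the conventional COCO ``w*h`` — because
the evaluation scale is defined from the diagonal (see
:func:`toolpose.metrics.scale_factor`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

from .schema import (
    SLOT_ROLES,
    FrameAnnotation,
    Keypoint,
    Role,
    SchemaError,
    ToolPose,
    Visibility,
    validate_pose,
)

__all__ = [
    "BoundingBox",
    "CocoImage",
    "CocoAnnotation",
    "CocoDataset",
    "DEFAULT_MARGIN",
    "INSTRUMENT_CATEGORY",
    "visibility_code",
    "keypoint_bbox",
    "pose_to_coco",
    "coco_to_pose",
    "frames_to_coco",
    "coco_to_frames",
]

DEFAULT_MARGIN = 20.0

#: The single instrument category of the export, with the canonical
#: keypoint-name list and 1-based skeleton edges (E-H, H-T1, H-T2).
INSTRUMENT_CATEGORY: dict[str, Any] = {
    "id": 1,
    "name": "instrument",
    "supercategory": "tool",
    "keypoints": ["EntryPoint", "HingePoint", "Tip1", "Tip2"],
    "skeleton": [[1, 2], [2, 3], [2, 4]],
}


class EmptyExtentError(ValueError):
    """No keypoint with v > 0 is available to derive a bounding box from."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box ``[xmin, ymin, w, h]`` in pixels."""

    xmin: float
    ymin: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w < 0 or self.h < 0:
            raise ValueError("bounding box width/height must be >= 0")

    @property
    def xmax(self) -> float:
        return self.xmin + self.w

    @property
    def ymax(self) -> float:
        return self.ymin + self.h

    @property
    def diagonal_sq(self) -> float:
        """Square of the diagonal, ``w**2 + h**2`` (the stored COCO area)."""
        return self.w ** 2 + self.h ** 2

    def as_list(self) -> list[float]:
        return [self.xmin, self.ymin, self.w, self.h]


@dataclass(frozen=True)
class CocoImage:
    id: int
    file_name: str
    width: int = 960
    height: int = 540


@dataclass
class CocoAnnotation:
    """One instrument instance in the COCO-style export."""

    image_id: int
    id: int
    keypoints: list[float]  # 12 numbers: (x, y, v) for E, H, T1, T2
    num_keypoints: int
    bbox: BoundingBox
    area: float
    category_id: int = 1

    def __post_init__(self) -> None:
        if len(self.keypoints) != 12:
            raise SchemaError("keypoints must hold exactly 4 (x, y, v) triplets")
        for v in self.keypoints[2::3]:
            if v not in (0, 1, 2):
                raise SchemaError(f"visibility code {v!r} outside {{0, 1, 2}}")

    def triplets(self) -> list[tuple[float, float, int]]:
        k = self.keypoints
        return [(k[3 * i], k[3 * i + 1], int(k[3 * i + 2])) for i in range(4)]


@dataclass
class CocoDataset:
    """images/annotations/categories containers of the COCO-style export."""

    images: list[CocoImage] = field(default_factory=list)
    annotations: list[CocoAnnotation] = field(default_factory=list)
    categories: list[dict[str, Any]] = field(
        default_factory=lambda: [dict(INSTRUMENT_CATEGORY)])

    def __post_init__(self) -> None:
        image_ids = {im.id for im in self.images}
        if len(image_ids) != len(self.images):
            raise SchemaError("image ids are not unique")
        ann_ids = {a.id for a in self.annotations}
        if len(ann_ids) != len(self.annotations):
            raise SchemaError("annotation ids are not unique")
        for a in self.annotations:
            if a.image_id not in image_ids:
                raise SchemaError(
                    f"annotation {a.id} references unknown image {a.image_id}")

    def annotations_for(self, image_id: int) -> list[CocoAnnotation]:
        return [a for a in self.annotations if a.image_id == image_id]

    def to_dict(self) -> dict[str, Any]:
        return {
            "images": [vars(im).copy() for im in self.images],
            "annotations": [
                {
                    "image_id": a.image_id,
                    "id": a.id,
                    "category_id": a.category_id,
                    "keypoints": list(a.keypoints),
                    "num_keypoints": a.num_keypoints,
                    "bbox": a.bbox.as_list(),
                    "area": a.area,
                    "iscrowd": 0,
                }
                for a in self.annotations
            ],
            "categories": [dict(c) for c in self.categories],
        }

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "CocoDataset":
        try:
            images = [CocoImage(id=im["id"], file_name=im.get("file_name", ""),
                                width=im.get("width", 960),
                                height=im.get("height", 540))
                      for im in doc["images"]]
            annotations = [
                CocoAnnotation(
                    image_id=a["image_id"],
                    id=a["id"],
                    category_id=a.get("category_id", 1),
                    keypoints=[float(v) for v in a["keypoints"]],
                    num_keypoints=int(a["num_keypoints"]),
                    bbox=BoundingBox(*[float(v) for v in a["bbox"]]),
                    area=float(a["area"]),
                )
                for a in doc["annotations"]
            ]
            categories = [dict(c) for c in doc.get(
                "categories", [INSTRUMENT_CATEGORY])]
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"invalid COCO document: {exc}") from exc
        return cls(images=images, annotations=annotations,
                   categories=categories)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CocoDataset":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed COCO JSON: {exc}") from exc
        return cls.from_dict(doc)


# ---------------------------------------------------------------------------
# conversion primitives
# ---------------------------------------------------------------------------

def visibility_code(kp: Keypoint, width: int = 960, height: int = 540) -> int:
    """COCO visibility code of one keypoint.

    visible -> 2; occluded with both coordinates inside the frame -> 1;
    occluded outside the frame -> 0; missing -> 0.  An occluded point in
    the corner region outside the circular field of view but inside the
    rectangular frame still codes as 1.
    """
    if kp.tag is Visibility.VISIBLE:
        return 2
    if kp.tag is Visibility.OCCLUDED:
        return 1 if (0 <= kp.x < width and 0 <= kp.y < height) else 0
    return 0


def keypoint_bbox(
    pose: ToolPose,
    width: int = 960,
    height: int = 540,
    margin: float = DEFAULT_MARGIN,
) -> BoundingBox:
    """Bounding box of the keypoints with v > 0, margin-expanded and clipped.

    The extent is the min/max of the contributing coordinates; a margin
    (default 20 px) is added on all four sides; where the expanded box
    exceeds the image boundaries, the image boundaries are used as the
    limit.  Keypoints coding v = 0 (missing, or occluded out of frame) are
    excluded.

    Raises
    ------
    EmptyExtentError
        If no keypoint codes v > 0.
    """
    pts = [(kp.x, kp.y) for _, kp in pose.slots()
           if visibility_code(kp, width, height) > 0]
    if not pts:
        raise EmptyExtentError("pose has no keypoint with v > 0")
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    x0 = max(0.0, min(xs) - margin)
    y0 = max(0.0, min(ys) - margin)
    x1 = min(float(width), max(xs) + margin)
    y1 = min(float(height), max(ys) + margin)
    return BoundingBox(x0, y0, x1 - x0, y1 - y0)


def pose_to_coco(
    pose: ToolPose,
    image_id: int,
    ann_id: int,
    width: int = 960,
    height: int = 540,
    margin: float = DEFAULT_MARGIN,
) -> CocoAnnotation:
    """Convert one pose to a COCO-style annotation.

    Keypoints are serialized in the canonical slot order; triplets coding
    v = 0 store the placeholder coordinates (0, 0).  Transition points are
    dropped (they exist only in the raw dialect).  The stored ``area`` is
    the squared box diagonal.
    """
    violations = validate_pose(pose, width, height)
    if violations:
        raise SchemaError("pose does not validate: "
                          + "; ".join(str(v) for v in violations[:3]))
    flat: list[float] = []
    n_labelled = 0
    for _, kp in pose.slots():
        v = visibility_code(kp, width, height)
        if v > 0:
            flat.extend([float(kp.x), float(kp.y), float(v)])
            n_labelled += 1
        else:
            flat.extend([0.0, 0.0, 0.0])
    box = keypoint_bbox(pose, width, height, margin)
    return CocoAnnotation(image_id=image_id, id=ann_id, keypoints=flat,
                          num_keypoints=n_labelled, bbox=box,
                          area=box.diagonal_sq)


_V_TO_TAG = {2: Visibility.VISIBLE, 1: Visibility.OCCLUDED, 0: Visibility.MISSING}


def coco_to_pose(ann: CocoAnnotation) -> ToolPose:
    """Lossy inverse of :func:`pose_to_coco`.

    v = 2 -> visible, v = 1 -> occluded, v = 0 -> missing sentinel.
    Transition points cannot be recovered.  A second conversion with
    :func:`pose_to_coco` reproduces keypoints, visibility codes and
    ``num_keypoints`` exactly.
    """
    kwargs: dict[str, Keypoint] = {}
    for (x, y, v), role, slot in zip(
            ann.triplets(), SLOT_ROLES, ("entry", "hinge", "tip1", "tip2")):
        if v not in _V_TO_TAG:
            raise SchemaError(f"visibility code {v} outside {{0, 1, 2}}")
        tag = _V_TO_TAG[v]
        kwargs[slot] = (Keypoint.missing(role) if tag is Visibility.MISSING
                        else Keypoint(x, y, role, tag))
    return ToolPose(instance_id=ann.id, **kwargs)


# ---------------------------------------------------------------------------
# dataset-level conversion
# ---------------------------------------------------------------------------

def frames_to_coco(
    frames: Sequence[FrameAnnotation],
    margin: float = DEFAULT_MARGIN,
) -> CocoDataset:
    """Consolidate per-frame annotations into one COCO-style dataset.

    Image ids are assigned 1..n in input order; annotation ids run 1..m in
    (image, instance) order.
    """
    images: list[CocoImage] = []
    annotations: list[CocoAnnotation] = []
    ann_id = 1
    for i, frame in enumerate(frames, start=1):
        images.append(CocoImage(id=i, file_name=frame.frame_id or f"frame_{i}",
                                width=frame.width, height=frame.height))
        for pose in sorted(frame.poses, key=lambda p: p.instance_id):
            annotations.append(pose_to_coco(pose, i, ann_id, frame.width,
                                            frame.height, margin))
            ann_id += 1
    return CocoDataset(images=images, annotations=annotations)


def coco_to_frames(dataset: CocoDataset) -> list[FrameAnnotation]:
    """Split a COCO-style dataset back into per-frame annotations."""
    frames = []
    for im in dataset.images:
        poses = [coco_to_pose(a) for a in dataset.annotations_for(im.id)]
        frames.append(FrameAnnotation(frame_id=im.file_name, width=im.width,
                                      height=im.height, poses=poses))
    return frames
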