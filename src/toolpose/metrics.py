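"""Modified Object Keypoint Similarity and COCO-protocol AP/AR evaluation.

Object Keypoint Similarity (OKS) between a predicted and a ground-truth
skeleton is the visibility-weighted mean of Gaussian kernels::

    OKS = sum_i exp(-d_i^2 / (2 s^2 k_i^2)) [v_i > 0] / sum_i [v_i > 0]

where ``d_i`` is the Euclidean distance between predicted and ground-truth
keypoint ``i``, ``v_i`` the *ground-truth* visibility code (predicted
visibility tags are never used), ``k_i = 2 sigma_i`` the per-keypoint
falloff, and ``s`` the object scale.  Two modifications adapt the metric to
slender, symmetric surgical instruments:

1. **Tip-permutation invariance.**  Tip1/Tip2 are an unordered pair, so the
   OKS is evaluated against both the original ground truth and a copy with
   the two tip triplets exchanged, and the better value is reported
   (equivalent to a bipartite matching of the tips).

2. **Rotation-invariant scale.**  Instead of ``s = sqrt(w*h)`` — which
   collapses for an axis-aligned elongated tool — the scale is the root
   mean square of the box dimensions::

       s = sqrt((w^2 + h^2) / 2)

   By the AM-GM inequality ``s^2 >= w*h`` with equality iff ``w == h``, so
   the metric reduces to the standard definition for square-like objects
   while staying dominated by the tool's length under rotation.

All keypoints share ``sigma_i = 0.107``, the most permissive value of the
human-pose keypoint table (the 'hips' entry), reflecting the annotation
ambiguity of smooth metallic instruments.

AP/AR follow the COCO evaluation protocol: greedy score-ordered matching
per image at each threshold in 0.50:0.05:0.95, 101-point interpolated
precision, average recall at 20 detections per image.  Ground-truth
instances with ``num_keypoints == 0`` are ignore-instances: detections
matched to them count neither as true nor as false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .coco import BoundingBox, CocoAnnotation, CocoDataset

__all__ = [
    "OksParams",
    "ScoredDetection",
    "EvalSummary",
    "scale_factor",
    "oks",
    "oks_tip_swap",
    "iou",
    "greedy_match",
    "evaluate_pose",
    "evaluate_bbox",
    "detections_from_coco_results",
    "detections_to_coco_results",
]

TIP1, TIP2 = 2, 3  # slot indices of the unordered tip pair

OKS_THRESHOLDS = np.round(np.arange(0.50, 1.00, 0.05), 2)
RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class OksParams:
    """Parameters of the modified OKS metric and its AP/AR summary.

    Attributes
    ----------
    sigmas : np.ndarray
        Per-keypoint scale-normalised standard deviations (4 values,
        default 0.107 everywhere).  The falloff constants are
        ``kappa = 2 * sigmas``.
    oks_thresholds : np.ndarray
        Similarity thresholds for the AP/AR sweep, default 0.50:0.05:0.95.
    max_detections : int
        Detections kept per image (score-ordered), default 20.
    tip_swap : bool
        Evaluate against both tip orderings and keep the better OKS.
    """

    sigmas: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.107))
    oks_thresholds: np.ndarray = field(
        default_factory=lambda: OKS_THRESHOLDS.copy())
    max_detections: int = 20
    tip_swap: bool = True

    def __post_init__(self) -> None:
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.oks_thresholds = np.asarray(self.oks_thresholds, dtype=float)
        if self.sigmas.shape != (4,) or np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be 4 positive values")
        t = self.oks_thresholds
        if np.any(t <= 0) or np.any(t >= 1) or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing in (0,1)")
        if self.max_detections < 1:
            raise ValueError("max_detections must be >= 1")

    @property
    def kappas(self) -> np.ndarray:
        """Per-keypoint falloff constants, ``kappa_i = 2 sigma_i``."""
        return 2.0 * self.sigmas


@dataclass
class ScoredDetection:
    """One predicted instrument instance with a confidence score."""

    image_id: int
    keypoints: list[float]  # 12 numbers, same layout as CocoAnnotation
    score: float
    bbox: BoundingBox | None = None
    category_id: int = 1

    def __post_init__(self) -> None:
        if len(self.keypoints) != 12:
            raise ValueError("keypoints must hold exactly 4 (x, y, v) triplets")
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")

    def kp_array(self) -> np.ndarray:
        return np.asarray(self.keypoints, dtype=float).reshape(4, 3)


# ---------------------------------------------------------------------------
# similarity primitives
# ---------------------------------------------------------------------------

def scale_factor(box: BoundingBox) -> float:
    """Rotation-invariant object scale ``s = sqrt((w^2 + h^2) / 2)``.

    Symmetric in ``(w, h)`` and never smaller than ``sqrt(w*h)``; equals the
    side length for a square box.  Note ``s**2 == area / 2`` with the stored
    diagonal-squared area.
    """
    if box.w == 0 and box.h == 0:
        raise ValueError("degenerate box: w = h = 0 has no scale")
    return float(np.sqrt((box.w ** 2 + box.h ** 2) / 2.0))


def _as_triplets(kpts: Any) -> np.ndarray:
    arr = np.asarray(kpts, dtype=float).reshape(4, 3)
    return arr


def oks(pred: Any, gt: Any, s: float, params: OksParams | None = None) -> float:
    """Plain OKS of predicted vs ground-truth keypoints at scale ``s``.

    ``pred`` and ``gt`` are 12 flat numbers or (4, 3) arrays of (x, y, v)
    triplets.  Only ground-truth triplets with v > 0 enter the sum; the
    predicted v values are ignored.

    Raises
    ------
    ValueError
        If ``s <= 0`` or the ground truth has no labelled keypoint.
    """
    params = params or OksParams()
    if not s > 0:
        raise ValueError("scale s must be > 0")
    p = _as_triplets(pred)
    g = _as_triplets(gt)
    labelled = g[:, 2] > 0
    if not labelled.any():
        raise ValueError("ground truth has no keypoint with v > 0")
    d2 = (p[:, 0] - g[:, 0]) ** 2 + (p[:, 1] - g[:, 1]) ** 2
    e = d2 / (2.0 * s ** 2 * params.kappas ** 2)
    return float(np.mean(np.exp(-e[labelled])))


def swap_tips(kpts: Any) -> np.ndarray:
    """Return the (4, 3) keypoint array with the tip triplets exchanged."""
    arr = _as_triplets(kpts).copy()
    arr[[TIP1, TIP2]] = arr[[TIP2, TIP1]]
    return arr


def oks_tip_swap(pred: Any, gt: Any, s: float,
                 params: OksParams | None = None) -> float:
    """Tip-permutation-invariant OKS: best of the two tip orderings.

    The ground truth is evaluated as given and with Tip1/Tip2 exchanged
    (coordinates and visibility codes move together); the larger OKS is
    returned, so the value is never below the plain OKS.
    """
    plain = oks(pred, gt, s, params)
    swapped_gt = swap_tips(gt)
    if not (swapped_gt[:, 2] > 0).any():  # pragma: no cover - same labels
        return plain
    return max(plain, oks(pred, swapped_gt, s, params))


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes (conventional w*h areas)."""
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    union = a.w * a.h + b.w * b.h - inter
    if union <= 0:
        return 0.0
    return float(inter / union)


def _oks_ignore_region(det_kpts: np.ndarray, gt: CocoAnnotation,
                       s: float, params: OksParams) -> float:
    """Similarity of a detection to an ignore-instance (num_keypoints = 0).

    Mirrors the COCO keypoint protocol: distances are measured from each
    predicted keypoint to a ground-truth box region expanded by twice its
    width/height on every side, so detections loitering near an unlabelled
    instance can be matched to it (and then discounted) rather than counted
    as false positives.
    """
    b = gt.bbox
    x0, x1 = b.xmin - 2 * b.w, b.xmin + 3 * b.w
    y0, y1 = b.ymin - 2 * b.h, b.ymin + 3 * b.h
    dx = np.maximum(0.0, x0 - det_kpts[:, 0]) \
        + np.maximum(0.0, det_kpts[:, 0] - x1)
    dy = np.maximum(0.0, y0 - det_kpts[:, 1]) \
        + np.maximum(0.0, det_kpts[:, 1] - y1)
    d2 = dx ** 2 + dy ** 2
    e = d2 / (2.0 * s ** 2 * params.kappas ** 2)
    return float(np.mean(np.exp(-e)))


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def greedy_match(
    similarity: np.ndarray,
    det_scores: Sequence[float],
    gt_ignore: Sequence[bool],
    threshold: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedy score-ordered detection/ground-truth assignment (COCO protocol).

    Parameters
    ----------
    similarity : (n_det, n_gt) array
        Precomputed similarity (tip-swap OKS or IoU); rows must already be
        truncated to the per-image detection budget.
    det_scores : confidences, used to process detections best-first.
    gt_ignore : flags marking ignore-instances.
    threshold : minimal similarity for a match.

    Returns
    -------
    det_match, gt_match, det_ignore
        ``det_match[i]`` / ``gt_match[j]`` give the matched counterpart
        index or -1; ``det_ignore[i]`` marks detections matched to an
        ignore-instance (excluded from the precision denominator).

    Each detection, in descending score order (ties broken by input
    order), takes the still-unmatched ground truth of maximal similarity
    at or above the threshold; non-ignore ground truths are preferred
    over ignore ones regardless of similarity.
    """
    n_det, n_gt = similarity.shape
    gt_ignore = np.asarray(gt_ignore, dtype=bool)
    det_match = np.full(n_det, -1, dtype=int)
    gt_match = np.full(n_gt, -1, dtype=int)
    det_ignore = np.zeros(n_det, dtype=bool)
    order = np.argsort(-np.asarray(det_scores, dtype=float), kind="mergesort")
    gt_order = np.argsort(gt_ignore, kind="mergesort")  # non-ignore first
    for di in order:
        best = threshold  # a similarity equal to the threshold matches
        match = -1
        for gj in gt_order:
            if gt_match[gj] >= 0 and not gt_ignore[gj]:
                continue
            # once matched to a real gt, never downgrade to an ignore one
            if match >= 0 and not gt_ignore[match] and gt_ignore[gj]:
                break
            if similarity[di, gj] < best:
                continue
            best = similarity[di, gj]
            match = gj
        if match >= 0:
            det_match[di] = match
            det_ignore[di] = gt_ignore[match]
            if gt_match[match] < 0:
                gt_match[match] = di
            if not gt_ignore[match]:
                gt_match[match] = di
    return det_match, gt_match, det_ignore


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------

@dataclass
class EvalSummary:
    """AP/AR at fixed thresholds plus threshold-averaged values.

    ``precision`` has shape (n_thresholds, 101): interpolated precision on
    the recall grid 0:0.01:1 per similarity threshold.  ``recall`` is the
    maximal recall per threshold at the detection budget.  All headline
    values lie in [0, 1], or are -1 when the ground truth holds no
    evaluable instance (COCO convention).
    """

    ap_mean: float
    ap_050: float
    ap_075: float
    ar_mean: float
    ar_050: float
    ar_075: float
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    recall_grid: np.ndarray = field(default_factory=lambda: RECALL_GRID.copy())

    def headline(self) -> dict[str, float]:
        return {
            "ap_mean": self.ap_mean, "ap_050": self.ap_050,
            "ap_075": self.ap_075, "ar_mean": self.ar_mean,
            "ar_050": self.ar_050, "ar_075": self.ar_075,
        }

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = dict(self.headline())
        out["thresholds"] = self.thresholds.tolist()
        out["precision"] = self.precision.tolist()
        out["recall"] = self.recall.tolist()
        return out

    def summary(self, label: str = "OKS") -> str:
        """Plain-text table in the conventional benchmark column layout."""
        cols = [f"AP({label})", f"AP_{label}=0.5", f"AP_{label}=0.75",
                f"AR({label})", f"AR_{label}=0.5", f"AR_{label}=0.75"]
        vals = [self.ap_mean, self.ap_050, self.ap_075,
                self.ar_mean, self.ar_050, self.ar_075]
        widths = [max(len(c), 6) for c in cols]
        head = "  ".join(c.ljust(w) for c, w in zip(cols, widths))
        row = "  ".join(f"{v:.3f}".ljust(w) for v, w in zip(vals, widths))
        return head + "\n" + row


def _threshold_index(thresholds: np.ndarray, value: float) -> int | None:
    idx = np.where(np.isclose(thresholds, value))[0]
    return int(idx[0]) if idx.size else None


def _accumulate(
    per_image: list[dict[str, np.ndarray]],
    n_thresholds: int,
    thresholds: np.ndarray,
) -> EvalSummary:
    """Build precision/recall curves from per-image match outcomes.

    ``per_image`` entries carry ``scores`` (kept detections, score order),
    ``matched`` and ``ignored`` boolean arrays of shape (T, n_det), and the
    scalar ``n_pos`` count of non-ignore ground truths.
    """
    n_pos = int(sum(e["n_pos"] for e in per_image))
    T, R = n_thresholds, len(RECALL_GRID)
    precision = -np.ones((T, R))
    recall = -np.ones(T)
    if n_pos > 0:
        scores = np.concatenate([e["scores"] for e in per_image]) \
            if per_image else np.empty(0)
        order = np.argsort(-scores, kind="mergesort")
        for t in range(T):
            matched = np.concatenate(
                [e["matched"][t] for e in per_image])[order] \
                if per_image else np.empty(0, bool)
            ignored = np.concatenate(
                [e["ignored"][t] for e in per_image])[order] \
                if per_image else np.empty(0, bool)
            keep = ~ignored
            tp = np.cumsum(matched[keep].astype(float))
            fp = np.cumsum((~matched[keep]).astype(float))
            if tp.size == 0:
                precision[t] = 0.0
                recall[t] = 0.0
                continue
            rc = tp / n_pos
            pr = tp / np.maximum(tp + fp, np.finfo(float).eps)
            recall[t] = rc[-1]
            # precision envelope, monotone non-increasing from the right
            env = np.maximum.accumulate(pr[::-1])[::-1]
            idx = np.searchsorted(rc, RECALL_GRID, side="left")
            q = np.zeros(R)
            valid = idx < len(env)
            q[valid] = env[idx[valid]]
            precision[t] = q
    ap_per_t = precision.mean(axis=1) if n_pos > 0 else -np.ones(T)
    i50 = _threshold_index(thresholds, 0.50)
    i75 = _threshold_index(thresholds, 0.75)
    pick = (lambda arr, i: float(arr[i]) if i is not None else -1.0)
    return EvalSummary(
        ap_mean=float(ap_per_t.mean()),
        ap_050=pick(ap_per_t, i50),
        ap_075=pick(ap_per_t, i75),
        ar_mean=float(recall.mean()),
        ar_050=pick(recall, i50),
        ar_075=pick(recall, i75),
        thresholds=thresholds.copy(),
        precision=precision,
        recall=recall,
    )


def _evaluate(
    gt: CocoDataset,
    dets: Sequence[ScoredDetection],
    thresholds: np.ndarray,
    max_detections: int,
    sim_fn,
) -> EvalSummary:
    by_image: dict[int, list[ScoredDetection]] = {im.id: [] for im in gt.images}
    for d in dets:
        if d.image_id not in by_image:
            raise ValueError(f"detection references unknown image {d.image_id}")
        by_image[d.image_id].append(d)

    per_image: list[dict[str, np.ndarray]] = []
    T = len(thresholds)
    for im in gt.images:
        gts = gt.annotations_for(im.id)
        img_dets = by_image[im.id]
        scores = np.array([d.score for d in img_dets], dtype=float)
        order = np.argsort(-scores, kind="mergesort")[:max_detections]
        img_dets = [img_dets[i] for i in order]
        scores = scores[order]
        n_det, n_gt = len(img_dets), len(gts)
        ignore = np.array([g.num_keypoints == 0 for g in gts], dtype=bool)
        sim = np.zeros((n_det, n_gt))
        for i, d in enumerate(img_dets):
            for j, g in enumerate(gts):
                sim[i, j] = sim_fn(d, g)
        matched = np.zeros((T, n_det), dtype=bool)
        ignored = np.zeros((T, n_det), dtype=bool)
        for t, thr in enumerate(thresholds):
            det_match, _, det_ign = greedy_match(sim, scores, ignore, thr)
            matched[t] = (det_match >= 0) & ~det_ign
            ignored[t] = det_ign
        per_image.append({
            "scores": scores,
            "matched": matched,
            "ignored": ignored,
            "n_pos": np.int64((~ignore).sum()),
        })
    return _accumulate(per_image, T, thresholds)


def evaluate_pose(
    gt: CocoDataset,
    dets: Sequence[ScoredDetection],
    params: OksParams | None = None,
) -> EvalSummary:
    """COCO-protocol keypoint AP/AR with the modified OKS.

    The similarity between a detection and a ground-truth instance is the
    tip-permutation-invariant OKS (plain OKS when ``params.tip_swap`` is
    off) at the scale derived from the instance's stored bounding box via
    ``s = sqrt((w^2 + h^2)/2)``.  Instances with ``num_keypoints == 0`` are
    ignore-instances.  When the ground truth holds no evaluable instance at
    all, every summary field is -1.
    """
    params = params or OksParams()

    def sim(d: ScoredDetection, g: CocoAnnotation) -> float:
        s = scale_factor(g.bbox)
        kp = d.kp_array()
        if g.num_keypoints == 0:
            return _oks_ignore_region(kp, g, s, params)
        if params.tip_swap:
            return oks_tip_swap(kp, g.keypoints, s, params)
        return oks(kp, g.keypoints, s, params)

    return _evaluate(gt, dets, params.oks_thresholds,
                     params.max_detections, sim)


def evaluate_bbox(
    gt: CocoDataset,
    dets: Sequence[ScoredDetection],
    iou_thresholds: np.ndarray | None = None,
    max_detections: int = 20,
) -> EvalSummary:
    """COCO-protocol box AP/AR over IoU thresholds (default 0.50:0.05:0.95).

    Every detection must carry a bounding box.  The same ignore rule as the
    pose evaluator applies (instances without labelled keypoints).
    """
    thresholds = (OKS_THRESHOLDS.copy() if iou_thresholds is None
                  else np.asarray(iou_thresholds, dtype=float))
    for d in dets:
        if d.bbox is None:
            raise ValueError("box evaluation requires detections with a bbox")

    def sim(d: ScoredDetection, g: CocoAnnotation) -> float:
        return iou(d.bbox, g.bbox)

    return _evaluate(gt, dets, thresholds, max_detections, sim)


# ---------------------------------------------------------------------------
# results-file plumbing (COCO keypoint results format)
# ---------------------------------------------------------------------------

def detections_from_coco_results(results: list[dict[str, Any]],
                                 margin: float | None = None,
                                 width: int = 960,
                                 height: int = 540) -> list[ScoredDetection]:
    """Read a COCO keypoint results list into scored detections.

    Each entry holds ``image_id``, ``category_id``, ``keypoints`` (12
    floats) and ``score``; an optional ``bbox`` is honoured.  When
    ``margin`` is given and no bbox is present, a box is derived from the
    predicted keypoints with v > 0 (extent + margin, clipped) so the same
    file can feed the box evaluator.
    """
    from .coco import BoundingBox as BB

    out = []
    for r in results:
        bbox = None
        if "bbox" in r:
            bbox = BB(*[float(v) for v in r["bbox"]])
        elif margin is not None:
            arr = np.asarray(r["keypoints"], dtype=float).reshape(4, 3)
            pts = arr[arr[:, 2] > 0, :2]
            if len(pts):
                x0 = max(0.0, pts[:, 0].min() - margin)
                y0 = max(0.0, pts[:, 1].min() - margin)
                x1 = min(float(width), pts[:, 0].max() + margin)
                y1 = min(float(height), pts[:, 1].max() + margin)
                bbox = BB(x0, y0, x1 - x0, y1 - y0)
        out.append(ScoredDetection(
            image_id=int(r["image_id"]),
            keypoints=[float(v) for v in r["keypoints"]],
            score=float(r["score"]),
            bbox=bbox,
            category_id=int(r.get("category_id", 1)),
        ))
    return out


def detections_to_coco_results(dets: Sequence[ScoredDetection]) -> list[dict[str, Any]]:
    """Serialize detections to the COCO keypoint results list format."""
    out = []
    for d in dets:
        entry: dict[str, Any] = {
            "image_id": d.image_id,
            "category_id": d.category_id,
            "keypoints": list(d.keypoints),
            "score": d.score,
        }
        if d.bbox is not None:
            entry["bbox"] = d.bbox.as_list()
        out.append(entry)
    return out
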