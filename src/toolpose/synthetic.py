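"""Seeded synthetic endoscopic scenes for offline testing of every module.

The generator emulates the geometry of a laparoscopic frame: a 960x540
image whose informative content sits inside a circular field of view
(FoV).  Each scene holds one to three instruments; an instrument is a
straight shaft entering at the FoV boundary (the EntryPoint), running to a
HingePoint inside the FoV, and continuing into one or two tips —
articulated jaws opened by a sampled angle, or a single rigid tip.  Paired
instance masks are drawn as thick capsule strokes along the skeleton
edges, and a flat-colour placeholder image stands in for the endoscopic
frame.

Visibility scenarios cover the six canonical states of the labelling
protocol (four articulated, two rigid):

====================== ==============================================
``articulated_visible``   all four keypoints visible
``articulated_occluded``  hinge or one tip occluded; transition points
                          inserted on the affected chain edges
``articulated_closed``    jaws closed: Tip2 missing, Tip1 visible
``articulated_shaft``     only the shaft in the FoV: both tips missing
``rigid_visible``         Entry, Hinge, Tip1 visible; Tip2 missing
``rigid_shaft``           only the shaft in the FoV: both tips missing
====================== ==============================================

Scenario frequencies default to uniform (the real-data frequencies are
not published) and are configurable.  All randomness flows from a single
explicit seed; identical seeds give bit-identical scenes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
from PIL import Image

from .coco import DEFAULT_MARGIN, BoundingBox
from .masks import InstanceMask, write_mask
from .metrics import ScoredDetection
from .schema import (
    FrameAnnotation,
    Keypoint,
    Role,
    ToolPose,
    Transition,
    Visibility,
    serialize_raw_json,
)

__all__ = [
    "SCENARIOS",
    "SceneConfig",
    "GenerationError",
    "gen_scene",
    "perturb_predictions",
    "gen_dataset_tree",
]

SCENARIOS = (
    "articulated_visible",
    "articulated_occluded",
    "articulated_closed",
    "articulated_shaft",
    "rigid_visible",
    "rigid_shaft",
)

_ARTICULATED = tuple(s for s in SCENARIOS if s.startswith("articulated"))
_RIGID = tuple(s for s in SCENARIOS if s.startswith("rigid"))


class GenerationError(RuntimeError):
    """Scene geometry could not be satisfied within the retry budget."""


@dataclass
class SceneConfig:
    """Study conditions for one synthetic scene.

    Defaults mirror the source imagery: 960x540 frames, a centred circular
    content area, and 1-3 instruments per frame.  ``scenario_weights``
    (mapping scenario name to probability) defaults to ``None``, meaning
    the weights are derived from ``articulated_fraction``: the articulated
    scenarios share that mass uniformly, the rigid ones share the rest —
    at the default 2/3 this is uniform over all six scenarios.
    """

    width: int = 960
    height: int = 540
    fov_center: tuple[float, float] = (480.0, 270.0)
    fov_radius: float = 260.0
    n_tools: tuple[int, int] = (1, 3)
    articulated_fraction: float = 2.0 / 3.0
    scenario_weights: dict[str, float] | None = None
    shaft_thickness: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        cx, cy = self.fov_center
        if not (-self.fov_radius < cx < self.width + self.fov_radius
                and -self.fov_radius < cy < self.height + self.fov_radius):
            raise ValueError("FoV circle must intersect the frame")
        if not 0 <= self.articulated_fraction <= 1:
            raise ValueError("articulated_fraction must be in [0, 1]")
        lo, hi = self.n_tools
        if not 1 <= lo <= hi:
            raise ValueError("n_tools must be a range with 1 <= lo <= hi")
        if self.scenario_weights is not None:
            unknown = set(self.scenario_weights) - set(SCENARIOS)
            if unknown:
                raise ValueError(f"unknown scenarios: {sorted(unknown)}")
            total = sum(self.scenario_weights.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError("scenario weights must sum to 1")

    def weights(self) -> np.ndarray:
        """Scenario probabilities in :data:`SCENARIOS` order."""
        if self.scenario_weights is not None:
            return np.array([self.scenario_weights.get(s, 0.0)
                             for s in SCENARIOS])
        a = self.articulated_fraction / len(_ARTICULATED)
        r = (1.0 - self.articulated_fraction) / len(_RIGID)
        return np.array([a if s in _ARTICULATED else r for s in SCENARIOS])


def _rot(vec: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def _in_frame(p: np.ndarray, w: int, h: int, margin: float = 0.0) -> bool:
    return margin <= p[0] < w - margin and margin <= p[1] < h - margin


def _sample_tool(cfg: SceneConfig, rng: np.random.Generator,
                 instance_id: int) -> tuple[ToolPose, list[tuple[np.ndarray, np.ndarray]]]:
    """Sample one tool; returns the pose and the mask stroke segments."""
    w, h = cfg.width, cfg.height
    center = np.asarray(cfg.fov_center, dtype=float)
    scenario = rng.choice(len(SCENARIOS), p=cfg.weights())
    scenario = SCENARIOS[scenario]

    for _ in range(200):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        entry = center + cfg.fov_radius * np.array([math.cos(theta),
                                                    math.sin(theta)])
        if not _in_frame(entry, w, h):
            continue
        inward = -np.array([math.cos(theta), math.sin(theta)])
        direction = _rot(inward, rng.uniform(-0.7, 0.7))
        shaft_len = rng.uniform(0.45, 1.1) * cfg.fov_radius
        hinge = entry + shaft_len * direction
        if not _in_frame(hinge, w, h, margin=25.0):
            continue
        if np.linalg.norm(hinge - center) > cfg.fov_radius - 15.0:
            continue
        tip_len = rng.uniform(40.0, 90.0)
        if scenario in ("articulated_visible", "articulated_occluded"):
            half = rng.uniform(math.radians(8.0), math.radians(35.0))
            t1 = hinge + tip_len * _rot(direction, half)
            t2 = hinge + tip_len * _rot(direction, -half)
            if not (_in_frame(t1, w, h, 5.0) and _in_frame(t2, w, h, 5.0)):
                continue
            tip_pts: list[np.ndarray | None] = [t1, t2]
        elif scenario in ("articulated_closed", "rigid_visible"):
            t1 = hinge + tip_len * direction
            if not _in_frame(t1, w, h, 5.0):
                continue
            tip_pts = [t1, None]
        else:  # shaft-only states
            tip_pts = [None, None]
        return _assemble_pose(scenario, entry, hinge, tip_pts, rng,
                              instance_id), \
            _strokes(entry, hinge, tip_pts)
    raise GenerationError(
        f"could not place a {scenario} tool within the retry budget")


def _assemble_pose(scenario: str, entry: np.ndarray, hinge: np.ndarray,
                   tips: list[np.ndarray | None], rng: np.random.Generator,
                   instance_id: int) -> ToolPose:
    vis = Visibility.VISIBLE
    kp = {
        "entry": Keypoint(float(entry[0]), float(entry[1]), Role.ENTRY, vis),
        "hinge": Keypoint(float(hinge[0]), float(hinge[1]), Role.HINGE, vis),
        "tip1": (Keypoint(float(tips[0][0]), float(tips[0][1]), Role.TIP1, vis)
                 if tips[0] is not None else Keypoint.missing(Role.TIP1)),
        "tip2": (Keypoint(float(tips[1][0]), float(tips[1][1]), Role.TIP2, vis)
                 if tips[1] is not None else Keypoint.missing(Role.TIP2)),
    }
    transitions: list[Transition] = []
    if scenario == "articulated_occluded":
        # hide the hinge or one tip; the hidden point keeps its coordinates
        target = ("hinge", "tip1", "tip2")[rng.integers(3)]
        old = kp[target]
        kp[target] = Keypoint(old.x, old.y, old.role, Visibility.OCCLUDED)
        # transitions: farthest visible point along each affected chain edge
        for a, b in (("entry", "hinge"), ("hinge", "tip1"), ("hinge", "tip2")):
            va, vb = kp[a].tag, kp[b].tag
            if (va is Visibility.VISIBLE) == (vb is Visibility.VISIBLE):
                continue
            if rng.random() > 0.7:
                continue
            vis_end, hid_end = (kp[a], kp[b]) if va is Visibility.VISIBLE \
                else (kp[b], kp[a])
            u = rng.uniform(0.3, 0.7)
            tx = vis_end.x + u * (hid_end.x - vis_end.x)
            ty = vis_end.y + u * (hid_end.y - vis_end.y)
            transitions.append(Transition(
                Keypoint(tx, ty, Role.TRANSITION, Visibility.VISIBLE), (a, b)))
    return ToolPose(entry=kp["entry"], hinge=kp["hinge"], tip1=kp["tip1"],
                    tip2=kp["tip2"], transitions=transitions,
                    instance_id=instance_id)


def _strokes(entry: np.ndarray, hinge: np.ndarray,
             tips: list[np.ndarray | None]) -> list[tuple[np.ndarray, np.ndarray]]:
    segs = [(entry, hinge)]
    for t in tips:
        if t is not None:
            segs.append((hinge, t))
    return segs


def _draw_capsule(labels: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                  radius: float, value: int) -> None:
    """Rasterise a thick line segment (capsule) into the label grid."""
    h, w = labels.shape
    x0 = max(0, int(math.floor(min(p0[0], p1[0]) - radius - 1)))
    x1 = min(w, int(math.ceil(max(p0[0], p1[0]) + radius + 2)))
    y0 = max(0, int(math.floor(min(p0[1], p1[1]) - radius - 1)))
    y1 = min(h, int(math.ceil(max(p0[1], p1[1]) + radius + 2)))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = p1 - p0
    len2 = float(d @ d)
    px = xx - p0[0]
    py = yy - p0[1]
    if len2 == 0:
        d2 = px ** 2 + py ** 2
    else:
        t = np.clip((px * d[0] + py * d[1]) / len2, 0.0, 1.0)
        d2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2
    labels[y0:y1, x0:x1][d2 <= radius ** 2] = value


def gen_scene(config: SceneConfig | None = None,
              seed: int | None = None) -> tuple[FrameAnnotation, InstanceMask]:
    """Generate one synthetic frame: tool poses plus paired instance mask.

    ``seed`` overrides ``config.seed`` (convenient when drawing many scenes
    from one configuration).  Instance ids are 1-based and match the mask
    label values.  Deterministic: the same seed yields a bit-identical
    annotation and mask.
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = int(rng.integers(cfg.n_tools[0], cfg.n_tools[1] + 1))
    labels = np.zeros((cfg.height, cfg.width), dtype=np.uint16)
    poses = []
    for k in range(1, n + 1):
        pose, segs = _sample_tool(cfg, rng, k)
        poses.append(pose)
        for p0, p1 in segs:
            _draw_capsule(labels, p0, p1, cfg.shaft_thickness, k)
    frame = FrameAnnotation(
        frame_id=f"synthetic_{cfg.seed if seed is None else seed}",
        width=cfg.width, height=cfg.height, poses=poses)
    return frame, InstanceMask(labels)


# ---------------------------------------------------------------------------
# prediction perturbation
# ---------------------------------------------------------------------------

def perturb_predictions(
    frame: FrameAnnotation,
    noise_sd: float = 0.0,
    drop_prob: float = 0.0,
    swap_prob: float = 0.0,
    score_model: Callable[[np.random.Generator], float] | None = None,
    seed: int = 0,
    image_id: int = 1,
    margin: float = DEFAULT_MARGIN,
) -> list[ScoredDetection]:
    """Turn ground-truth poses into noisy scored detections.

    Per tool: every labelled keypoint is jittered with isotropic Gaussian
    noise of standard deviation ``noise_sd`` pixels; with probability
    ``swap_prob`` the Tip1/Tip2 triplets are exchanged; with probability
    ``drop_prob`` the detection is omitted altogether.  Scores come from
    ``score_model`` (default: uniform on [0.5, 1)).  A detection box is
    derived from the perturbed keypoints (extent + margin, clipped), so the
    same detections feed both evaluators.  Deterministic given ``seed``.
    """
    from .coco import pose_to_coco

    if noise_sd < 0 or not 0 <= drop_prob <= 1 or not 0 <= swap_prob <= 1:
        raise ValueError("noise_sd >= 0 and probabilities in [0, 1] required")
    rng = np.random.default_rng(seed)
    out: list[ScoredDetection] = []
    for pose in sorted(frame.poses, key=lambda p: p.instance_id):
        dropped = rng.random() < drop_prob
        swapped = rng.random() < swap_prob
        jitter = rng.normal(0.0, noise_sd, size=(4, 2)) if noise_sd > 0 \
            else np.zeros((4, 2))
        score = score_model(rng) if score_model else float(rng.uniform(0.5, 1.0))
        if dropped:
            continue
        ann = pose_to_coco(pose, image_id, pose.instance_id,
                           frame.width, frame.height, margin)
        kpts = np.asarray(ann.keypoints, dtype=float).reshape(4, 3)
        labelled = kpts[:, 2] > 0
        kpts[labelled, :2] += jitter[labelled]
        if swapped:
            kpts[[2, 3]] = kpts[[3, 2]]
        pts = kpts[kpts[:, 2] > 0, :2]
        x0 = max(0.0, pts[:, 0].min() - margin)
        y0 = max(0.0, pts[:, 1].min() - margin)
        x1 = min(float(frame.width), pts[:, 0].max() + margin)
        y1 = min(float(frame.height), pts[:, 1].max() + margin)
        out.append(ScoredDetection(
            image_id=image_id,
            keypoints=[float(v) for v in kpts.ravel()],
            score=score,
            bbox=BoundingBox(x0, y0, x1 - x0, y1 - y0)))
    return out


# ---------------------------------------------------------------------------
# dataset tree
# ---------------------------------------------------------------------------

_SPLIT_SURGERIES = {
    "Training": ("Proctocolectomy", "Rectal_resection"),
    "Validation": ("Proctocolectomy", "Rectal_resection"),
    # the testing split adds a surgery type held out from training
    "Testing": ("Proctocolectomy", "Rectal_resection", "Sigmoid_resection"),
}


def _render_placeholder(mask: InstanceMask, cfg: SceneConfig,
                        path: Path) -> None:
    """Flat-colour stand-in for the endoscopic frame (never used by metrics)."""
    h, w = mask.labels.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = cfg.fov_center
    img = np.zeros((h, w, 3), dtype=np.uint8)
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= cfg.fov_radius ** 2
    img[inside] = (70, 35, 30)
    palette = [(200, 200, 210), (160, 180, 210), (210, 190, 150),
               (150, 210, 170)]
    for k in mask.instance_ids():
        img[mask.labels == k] = palette[(k - 1) % len(palette)]
    Image.fromarray(img, mode="RGB").save(path)


def gen_dataset_tree(
    root: str | Path,
    split_counts: dict[str, tuple[int, int]] | None = None,
    config: SceneConfig | None = None,
    force: bool = False,
) -> dict[str, Any]:
    """Write a synthetic dataset tree in the release layout.

    Layout: ``<split>/<Surgery_type>/<Procedure_ID>/<Frame_ID>/`` with
    three files per frame: ``raw.png`` (placeholder render),
    ``instrument_instances.png`` and ``raw.json``.  ``split_counts`` maps a
    split name to ``(n_procedures, n_frames_per_procedure)``; procedures
    are distributed round-robin over the split's surgery types (the testing
    split includes a surgery type absent from training, mirroring the
    held-out-domain evaluation design).  Returns a manifest listing every
    frame; re-running with the same seed reproduces it exactly.

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    cfg = config or SceneConfig()
    counts = split_counts or {"Training": (2, 4), "Validation": (1, 2),
                              "Testing": (3, 2)}
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not force:
        raise FileExistsError(
            f"{root} exists and is not empty (use force=True to overwrite)")
    root.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {"root": str(root), "seed": cfg.seed,
                                "frames": []}
    frame_seed = cfg.seed
    for split, (n_proc, n_frames) in counts.items():
        surgeries = _SPLIT_SURGERIES.get(split,
                                         _SPLIT_SURGERIES["Training"])
        for p in range(n_proc):
            surgery = surgeries[p % len(surgeries)]
            proc_dir = root / split / surgery / f"{p + 1:02d}"
            for f in range(n_frames):
                frame_seed += 1
                frame_dir = proc_dir / f"frame_{f:03d}"
                frame_dir.mkdir(parents=True, exist_ok=True)
                frame, mask = gen_scene(replace(cfg, seed=frame_seed))
                frame.frame_id = str(frame_dir.relative_to(root))
                (frame_dir / "raw.json").write_text(serialize_raw_json(frame))
                write_mask(mask, frame_dir / "instrument_instances.png")
                _render_placeholder(mask, cfg, frame_dir / "raw.png")
                manifest["frames"].append({
                    "split": split,
                    "surgery": surgery,
                    "procedure": p + 1,
                    "frame": str(frame_dir.relative_to(root)),
                    "seed": frame_seed,
                    "n_tools": len(frame.poses),
                })
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
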