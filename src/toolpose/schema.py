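"""Domain types and raw-JSON I/O for skeletal surgical-tool poses.

A surgical instrument is annotated as a four-keypoint skeleton:

* ``EntryPoint`` — where the shaft crosses the circular endoscopic
  field-of-view boundary (dynamic, not a physical tool landmark),
* ``HingePoint`` — shaft/tip junction (rigid tools) or articulation joint
  (articulated tools),
* ``Tip1`` / ``Tip2`` — instrument end points, semantically an *unordered*
  pair for symmetric jaws.

Each keypoint carries one of three visibility states: ``visible`` (seen in
the image), ``occluded`` (hidden but reliably inferable, possibly outside
the frame), or ``missing`` (physically absent, e.g. the second tip of a
rigid tool, or not inferable).  The skeleton chain is EntryPoint–HingePoint,
HingePoint–Tip1 and HingePoint–Tip2.  When one endpoint of a chain edge is
visible and the other is not, the farthest visible point along that edge may
be recorded as a *transition* point.

Coordinates are continuous pixels, origin at the top-left corner of the
top-left pixel; a visible point satisfies ``0 <= x < W`` and ``0 <= y < H``
(half-open).  Occluded points may lie in a padding area outside the frame
(negative or beyond-frame coordinates).  Missing keypoints store the
sentinel ``(0, 0)`` and are excluded from all arithmetic by their tag,
never by coordinate value.

The on-disk dialect (one ``raw.json`` per frame) has four top-level fields:
``nodes`` (list of ``[x, y]``), ``tags`` (parallel list of strings of the
form ``"<ROLE>_<visibility>"`` with role abbreviations ``E``, ``H``, ``T1``,
``T2`` and ``TR`` for transition points), ``edges`` (list of ``[i, j]``
node-index pairs) and ``transitions`` (list of node indices).  Skeletons are
the connected components of the edge graph; a transition node subdivides the
chain edge it lies on.  Unknown top-level fields are preserved opaquely.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any, Iterator

__all__ = [
    "Visibility",
    "Role",
    "Keypoint",
    "Transition",
    "ToolPose",
    "FrameAnnotation",
    "Violation",
    "SchemaError",
    "CHAIN_EDGES",
    "parse_raw_json",
    "serialize_raw_json",
    "validate_pose",
    "validate_frame",
]


class SchemaError(ValueError):
    """Raised when a document violates the annotation schema."""


class Visibility(str, Enum):
    """Visibility state of one keypoint."""

    VISIBLE = "visible"
    OCCLUDED = "occluded"
    MISSING = "missing"


class Role(str, Enum):
    """Semantic role of a keypoint within the skeleton."""

    ENTRY = "EntryPoint"
    HINGE = "HingePoint"
    TIP1 = "Tip1"
    TIP2 = "Tip2"
    TRANSITION = "Transition"


#: Abbreviations used in raw-JSON tag strings, e.g. ``"E_visible"``.
ROLE_ABBR = {
    Role.ENTRY: "E",
    Role.HINGE: "H",
    Role.TIP1: "T1",
    Role.TIP2: "T2",
    Role.TRANSITION: "TR",
}
ABBR_ROLE = {v: k for k, v in ROLE_ABBR.items()}

#: Slot attribute names of :class:`ToolPose`, in canonical order.
SLOT_NAMES = ("entry", "hinge", "tip1", "tip2")
SLOT_ROLES = (Role.ENTRY, Role.HINGE, Role.TIP1, Role.TIP2)

#: Legal chain edges as pairs of slot names.
CHAIN_EDGES = (("entry", "hinge"), ("hinge", "tip1"), ("hinge", "tip2"))


@dataclass(frozen=True)
class Keypoint:
    """One skeletal landmark: continuous pixel coordinates, role, visibility."""

    x: float
    y: float
    role: Role
    tag: Visibility

    @classmethod
    def missing(cls, role: Role) -> "Keypoint":
        """Sentinel keypoint for an absent landmark (coords never used)."""
        return cls(0.0, 0.0, role, Visibility.MISSING)

    @property
    def is_missing(self) -> bool:
        return self.tag is Visibility.MISSING


@dataclass(frozen=True)
class Transition:
    """A visible point on a chain edge whose far endpoint is not visible.

    ``edge`` is a pair of slot names from :data:`CHAIN_EDGES`,
    e.g. ``("hinge", "tip1")``.
    """

    point: Keypoint
    edge: tuple[str, str]


@dataclass
class ToolPose:
    """One instrument's four canonical keypoint slots plus transition points."""

    entry: Keypoint
    hinge: Keypoint
    tip1: Keypoint
    tip2: Keypoint
    transitions: list[Transition] = field(default_factory=list)
    instance_id: int = 0

    def slots(self) -> Iterator[tuple[str, Keypoint]]:
        """Yield ``(slot_name, keypoint)`` in canonical order E, H, T1, T2."""
        for name in SLOT_NAMES:
            yield name, getattr(self, name)

    def keypoints(self) -> list[Keypoint]:
        return [kp for _, kp in self.slots()]

    def swap_tips(self) -> "ToolPose":
        """Return a copy with the Tip1/Tip2 slots exchanged."""
        t1 = replace(self.tip1, role=Role.TIP2)
        t2 = replace(self.tip2, role=Role.TIP1)
        swapped = {("hinge", "tip1"): ("hinge", "tip2"),
                   ("hinge", "tip2"): ("hinge", "tip1")}
        trans = [Transition(t.point, swapped.get(t.edge, t.edge))
                 for t in self.transitions]
        return ToolPose(entry=self.entry, hinge=self.hinge, tip1=t2, tip2=t1,
                        transitions=trans, instance_id=self.instance_id)


@dataclass
class FrameAnnotation:
    """All tool poses of one frame, with frame geometry and provenance."""

    frame_id: str = ""
    width: int = 960
    height: int = 540
    poses: list[ToolPose] = field(default_factory=list)
    mask_path: str | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise SchemaError("frame dimensions must be positive")


@dataclass(frozen=True)
class Violation:
    """One protocol violation found by :func:`validate_pose`."""

    rule: str
    role: str | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - display convenience
        where = f" [{self.role}]" if self.role else ""
        return f"{self.rule}{where}: {self.message}"


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_tag(tag: str, index: int) -> tuple[Role, Visibility]:
    try:
        abbr, _, vis = tag.partition("_")
        return ABBR_ROLE[abbr], Visibility(vis)
    except (KeyError, ValueError):
        raise SchemaError(f"node {index}: unknown tag string {tag!r}") from None


def _components(n: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    """Connected components of the node graph, ordered by smallest member."""
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def parse_raw_json(
    text: str,
    frame_id: str = "",
    width: int = 960,
    height: int = 540,
) -> FrameAnnotation:
    """Parse a per-frame raw-JSON annotation document.

    Node tags are mapped to keypoint roles by their semantic abbreviation
    (``E``/``H``/``T1``/``T2``), never by list order.  Each connected
    component of the edge graph becomes one :class:`ToolPose`; transition
    nodes (abbreviation ``TR``, listed in ``transitions``) are contracted
    onto the chain edge they subdivide.

    Raises
    ------
    SchemaError
        On malformed JSON, unknown tag strings, edges referencing
        nonexistent nodes, illegal chain edges, or duplicate roles within
        one skeleton.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("document root must be an object")
    for key in ("nodes", "tags", "edges", "transitions"):
        if key not in doc or not isinstance(doc[key], list):
            raise SchemaError(f"missing or non-list field {key!r}")

    nodes_raw = doc["nodes"]
    tags_raw = doc["tags"]
    if len(nodes_raw) != len(tags_raw):
        raise SchemaError("nodes and tags must be parallel lists")
    n = len(nodes_raw)

    coords: list[tuple[float, float]] = []
    for i, xy in enumerate(nodes_raw):
        if not (isinstance(xy, (list, tuple)) and len(xy) == 2):
            raise SchemaError(f"node {i}: expected [x, y]")
        coords.append((float(xy[0]), float(xy[1])))
    parsed_tags = [_parse_tag(t, i) for i, t in enumerate(tags_raw)]

    trans_set = set()
    for i in doc["transitions"]:
        if not isinstance(i, int) or not 0 <= i < n:
            raise SchemaError(f"transition index {i!r} out of range")
        trans_set.add(i)
    for i, (role, vis) in enumerate(parsed_tags):
        if (role is Role.TRANSITION) != (i in trans_set):
            raise SchemaError(
                f"node {i}: transition tag and transitions list disagree")
        if role is Role.TRANSITION and vis is not Visibility.VISIBLE:
            raise SchemaError(f"node {i}: transition points must be visible")

    edges: list[tuple[int, int]] = []
    for e in doc["edges"]:
        if not (isinstance(e, (list, tuple)) and len(e) == 2):
            raise SchemaError(f"edge {e!r}: expected [i, j]")
        i, j = e
        if not (isinstance(i, int) and isinstance(j, int)
                and 0 <= i < n and 0 <= j < n):
            raise SchemaError(f"edge {e!r} references a nonexistent node")
        edges.append((i, j))

    extras = {k: v for k, v in doc.items()
              if k not in ("nodes", "tags", "edges", "transitions")}

    poses = []
    for inst, comp in enumerate(_components(n, edges)):
        poses.append(_component_to_pose(comp, coords, parsed_tags, edges, inst))
    return FrameAnnotation(frame_id=frame_id, width=width, height=height,
                           poses=poses, extras=extras)


def _component_to_pose(
    comp: list[int],
    coords: list[tuple[float, float]],
    tags: list[tuple[Role, Visibility]],
    edges: list[tuple[int, int]],
    instance_id: int,
) -> ToolPose:
    comp_set = set(comp)
    role_of: dict[int, Role] = {}
    slot_node: dict[Role, int] = {}
    for i in comp:
        role, _ = tags[i]
        role_of[i] = role
        if role is Role.TRANSITION:
            continue
        if role in slot_node:
            raise SchemaError(f"duplicate role {role.value} within one skeleton")
        slot_node[role] = i

    # Contract transition nodes: each must sit between exactly two role nodes.
    adj: dict[int, list[int]] = {i: [] for i in comp}
    for i, j in edges:
        if i in comp_set:
            adj[i].append(j)
            adj[j].append(i)
    contracted: list[tuple[int, int, int | None]] = []  # (role_i, role_j, tr)
    seen_pairs: set[frozenset[int]] = set()
    for i in comp:
        if role_of[i] is Role.TRANSITION:
            nbrs = adj[i]
            if len(nbrs) != 2 or any(role_of[v] is Role.TRANSITION for v in nbrs):
                raise SchemaError(
                    f"transition node {i} must subdivide one edge between "
                    "two keypoints")
            contracted.append((nbrs[0], nbrs[1], i))
    for i, j in edges:
        if i in comp_set and role_of[i] is not Role.TRANSITION \
                and role_of[j] is not Role.TRANSITION:
            contracted.append((i, j, None))
    slot_of_role = {Role.ENTRY: "entry", Role.HINGE: "hinge",
                    Role.TIP1: "tip1", Role.TIP2: "tip2"}
    legal = {frozenset(e) for e in CHAIN_EDGES}
    transitions: list[Transition] = []
    for a, b, tr in contracted:
        pair = frozenset((a, b))
        if pair in seen_pairs:
            raise SchemaError("duplicate chain edge in skeleton")
        seen_pairs.add(pair)
        sa, sb = slot_of_role[role_of[a]], slot_of_role[role_of[b]]
        if frozenset((sa, sb)) not in legal:
            raise SchemaError(f"illegal chain edge {sa}-{sb}")
        if tr is not None:
            edge = (sa, sb) if (sa, sb) in CHAIN_EDGES else (sb, sa)
            x, y = coords[tr]
            transitions.append(Transition(
                Keypoint(x, y, Role.TRANSITION, Visibility.VISIBLE), edge))

    kwargs: dict[str, Keypoint] = {}
    for role, slot in slot_of_role.items():
        if role in slot_node:
            i = slot_node[role]
            x, y = coords[i]
            vis = tags[i][1]
            kwargs[slot] = (Keypoint.missing(role) if vis is Visibility.MISSING
                            else Keypoint(x, y, role, vis))
        else:
            kwargs[slot] = Keypoint.missing(role)
    transitions.sort(key=lambda t: CHAIN_EDGES.index(t.edge))
    return ToolPose(transitions=transitions, instance_id=instance_id, **kwargs)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def serialize_raw_json(frame: FrameAnnotation) -> str:
    """Serialize a frame back to the raw-JSON dialect.

    All four slots of every pose are emitted (missing slots as sentinel
    ``[0.0, 0.0]`` nodes) together with the three chain edges, each split in
    two where a transition point subdivides it.  Key and node order are
    deterministic, so two round trips are byte-identical.

    Raises
    ------
    SchemaError
        If any pose violates the protocol (serialization is refused).
    """
    violations = validate_frame(frame)
    if violations:
        raise SchemaError(
            "refusing to serialize invalid frame: "
            + "; ".join(str(v) for v in violations[:5]))

    nodes: list[list[float]] = []
    tags: list[str] = []
    edges: list[list[int]] = []
    transitions: list[int] = []
    for pose in sorted(frame.poses, key=lambda p: p.instance_id):
        idx: dict[str, int] = {}
        for slot, kp in pose.slots():
            idx[slot] = len(nodes)
            nodes.append([float(kp.x), float(kp.y)])
            tags.append(f"{ROLE_ABBR[kp.role]}_{kp.tag.value}")
        by_edge = {t.edge: t for t in pose.transitions}
        for a, b in CHAIN_EDGES:
            t = by_edge.get((a, b))
            if t is None:
                edges.append([idx[a], idx[b]])
            else:
                ti = len(nodes)
                nodes.append([float(t.point.x), float(t.point.y)])
                tags.append(f"TR_{t.point.tag.value}")
                transitions.append(ti)
                edges.append([idx[a], ti])
                edges.append([ti, idx[b]])
    doc: dict[str, Any] = {"nodes": nodes, "tags": tags, "edges": edges,
                           "transitions": transitions}
    for k in sorted(frame.extras):
        doc[k] = frame.extras[k]
    return json.dumps(doc, separators=(", ", ": "))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_pose(pose: ToolPose, width: int = 960, height: int = 540) -> list[Violation]:
    """Check one pose against the labelling protocol.

    Returns an empty list iff the pose satisfies every rule: at least one
    annotated slot, visible keypoints inside the frame, occluded keypoints
    finite, and each transition on a legal chain edge whose two endpoints
    fall in differing visibility classes (one visible, the other
    occluded or missing).
    """
    out: list[Violation] = []
    if all(kp.is_missing for _, kp in pose.slots()):
        out.append(Violation("empty-pose", None,
                             "all four keypoint slots are missing"))
    for slot, kp in pose.slots():
        if kp.tag is Visibility.VISIBLE:
            if not (0 <= kp.x < width and 0 <= kp.y < height):
                out.append(Violation(
                    "visible-out-of-bounds", slot,
                    f"visible keypoint at ({kp.x}, {kp.y}) outside "
                    f"[0, {width}) x [0, {height})"))
        elif kp.tag is Visibility.OCCLUDED:
            if not (math.isfinite(kp.x) and math.isfinite(kp.y)):
                out.append(Violation("occluded-nonfinite", slot,
                                     "occluded keypoint must have finite "
                                     "coordinates"))
    seen_edges: set[tuple[str, str]] = set()
    for t in pose.transitions:
        if t.edge not in CHAIN_EDGES:
            out.append(Violation("transition-bad-edge", "transition",
                                 f"transition attached to unknown edge {t.edge}"))
            continue
        if t.edge in seen_edges:
            out.append(Violation("transition-duplicate", "transition",
                                 f"more than one transition on edge {t.edge}"))
        seen_edges.add(t.edge)
        a, b = t.edge
        va = getattr(pose, a).tag
        vb = getattr(pose, b).tag
        vis_a = va is Visibility.VISIBLE
        vis_b = vb is Visibility.VISIBLE
        if vis_a == vis_b:
            out.append(Violation(
                "transition-misplaced", "transition",
                f"edge {a}-{b} endpoints are both "
                f"{'visible' if vis_a else 'non-visible'}; a transition "
                "requires exactly one visible endpoint"))
        if not (0 <= t.point.x < width and 0 <= t.point.y < height):
            out.append(Violation("transition-out-of-bounds", "transition",
                                 "transition points are visible and must lie "
                                 "inside the frame"))
    return out


def validate_frame(frame: FrameAnnotation) -> list[Violation]:
    """Validate every pose of a frame; also checks instance-id uniqueness."""
    out: list[Violation] = []
    ids = [p.instance_id for p in frame.poses]
    if len(set(ids)) != len(ids):
        out.append(Violation("duplicate-instance-id", None,
                             f"instance ids {ids} are not unique"))
    for pose in frame.poses:
        out.extend(validate_pose(pose, frame.width, frame.height))
    return out
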