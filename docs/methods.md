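# Methods

## Data model

An instrument skeleton has four canonical slots — EntryPoint, HingePoint,
Tip1, Tip2 — connected as the chain E–H, H–T1, H–T2. Every slot is always
present in serialized form; absence is expressed through the visibility
tag, not by omitting the slot. The three visibility states are:

* `visible` — seen in the image; coordinates must satisfy `0 ≤ x < W`,
  `0 ≤ y < H` (continuous pixels, origin at the top-left corner of the
  top-left pixel, half-open bounds to avoid off-by-one ambiguity);
* `occluded` — hidden but reliably inferable; coordinates may lie inside
  the frame (e.g. under tissue, or in the frame corner outside the
  circular field of view) or in a padding area outside the frame
  (negative or beyond-frame values are legal and preserved);
* `missing` — physically absent (a rigid tool's second tip, closed jaws)
  or not inferable. Missing keypoints store the sentinel `(0, 0)` and are
  excluded from all arithmetic *by tag*, never by coordinate value.

Closed articulated jaws are encoded as Tip2 = missing, not as two
coincident tips; duplicate roles within one skeleton are a schema error.
A *transition* point is the farthest visible point along a chain edge
whose other endpoint is not visible; it is kept in the raw dialect for
annotation fidelity but carries no semantics downstream (it is not
exported to the COCO schema).

### Raw-JSON dialect

One document per frame with top-level `nodes` (list of `[x, y]`), `tags`
(parallel strings `"<ROLE>_<visibility>"`, roles abbreviated `E`, `H`,
`T1`, `T2`, `TR`), `edges` (`[i, j]` index pairs) and `transitions` (node
indices). Skeletons are the connected components of the edge graph;
a transition node subdivides the chain edge it lies on (`H–t`, `t–T1`).
Only the three chain edges are legal after contraction; anything else is
rejected. Unknown top-level fields are preserved opaquely through a round
trip. Serialization is deterministic (poses by instance id, slots in
canonical order, transitions in chain-edge order), so
serialize∘parse∘serialize is byte-identical.

## COCO export

Keypoints are flattened in the fixed order E, H, T1, T2 as `(x, y, v)`
triplets: `v = 2` visible, `v = 1` occluded with both coordinates inside
the frame, `v = 0` otherwise (missing, or occluded outside the frame).
Triplets with `v = 0` store placeholder coordinates `(0, 0)`; this makes
the COCO→pose→COCO half-round-trip exact at the cost of dropping
out-of-frame occluded coordinates, which only exist in the raw dialect.
`num_keypoints` counts triplets with `v > 0`.

The bounding box is the axis-aligned extent of the keypoints with
`v > 0`, expanded by a 20 px margin on all four sides, then clipped to the
image boundaries (worked example: extent (100,200)–(400,300) with margin
20 → `[80, 180, 340, 140]`). The stored `area` is the **squared diagonal**
`w² + h²`, not the conventional `w·h`: the evaluation scale is defined
from the diagonal (below), and storing its square keeps the two
representations consistent (`s² = area/2` exactly). All instruments share
a single category whose entry documents the keypoint order and skeleton.

## The modified OKS

Plain OKS is the mean over labelled ground-truth keypoints of
`exp(−d²/(2s²κ²))`; predicted visibility codes are accepted in input but
never used. The two modifications:

* **Tip permutation.** `oks_tip_swap = max(OKS(pred, gt),
  OKS(pred, swap(gt)))` where `swap` exchanges the Tip1/Tip2 triplets,
  coordinates and visibility codes together. Applied per detection–ground
  truth pair inside the similarity matrix, which is equivalent to a
  bipartite matching over the two-element tip set. It never decreases the
  score, and it recovers 1.0 for a prediction whose only error is tip
  order — including the rigid case where the single labelled tip sits in
  the wrong slot.
* **Scale.** `s = √((w²+h²)/2)` from the annotation's *stored* (i.e.
  margin-expanded, clipped) box. `s` is invariant under `(w,h)→(h,w)` —
  the rotation robustness the redefinition exists for — and `s² ≥ wh`
  prevents the scale collapse of axis-aligned slender tools.

`σᵢ = 0.107` uniformly (the most permissive human-pose value, matching
the annotation ambiguity of smooth instrument surfaces), `κᵢ = 2σᵢ`.
Under isotropic Gaussian perturbation of a labelled keypoint with
standard deviation `σₙ` per axis, the per-keypoint term has expectation
`1/(1 + σₙ²/(s²κ²))`; the test suite checks the Monte-Carlo mean against
this closed form.

## AP/AR protocol

The evaluator mirrors the COCO protocol: per image, detections are
truncated to the 20 best by score, then matched greedily in descending
score order (ties by input order); each detection takes the unmatched
ground truth of maximal similarity at or above the threshold, preferring
non-ignore instances. Ground truths with `num_keypoints = 0` are
ignore-instances: their similarity is computed as distance to a
2×-expanded box region, and detections matched to them are excluded from
the precision denominator. Per threshold, precision–recall is accumulated
over globally score-sorted detections; AP is the mean of the interpolated
precision (envelope maximum) on the 101-point recall grid, AR is the
maximal recall. Headline values are reported at 0.50, 0.75 and averaged
over 0.50:0.05:0.95. A ground truth with no evaluable instance yields the
sentinel −1. The box evaluator is identical with IoU (conventional `w·h`
areas) as similarity.

An independent plain-loop implementation of the same protocol lives in
`tests/reference_cocoeval.py`, written separately (scalar loops, explicit
precision envelope, its own similarity code); the test suite requires the
two routes to agree to 1e-6 on 100 seeded scenes with noisy, dropped and
tip-swapped detections, for both the OKS and IoU routes, and with
tip-swap on and off.

## Masks

Instance masks are single-channel PNGs, pixel value = instance id
(8-bit up to 255 instances, 16-bit beyond); reading and writing are
lossless. `remove_instances` erases chosen ids to background without
re-indexing survivors — mirroring the removal of static trocar-cannula
instances from segmentation labels, which can legitimately leave a
completely black mask. `pose_mask_consistency` is a QC heuristic: the
fraction of visible keypoints with instrument pixels within a radius.
Mask instance ids and pose instance ids are independent namespaces; the
synthetic generator happens to align them, real data need not.

## Synthetic scenes

The generator emulates the source imagery's geometry, not its appearance:
960×540 frames, a circular field of view of radius 260 px centred at
(480, 270), 1–3 straight-shafted tools per frame. Each tool's EntryPoint
lies on the FoV circle (within 0.5 px by construction); the shaft runs
inward (direction jittered ±40°, length 0.45–1.1 FoV radii) to a
HingePoint kept inside frame and FoV; tips extend 40–90 px beyond, opened
8–35° per side for articulated jaws. The six visibility scenarios
(articulated: all-visible, occluded-with-transitions, closed,
shaft-only; rigid: visible, shaft-only) default to equal probability —
their real-data frequencies are unpublished — and are configurable via
`scenario_weights`. Masks are capsule strokes of radius 12 px along the
skeleton edges; `raw.png` placeholders are flat-colour renders, since no
metric consumes pixels. Everything derives from one explicit seed;
identical seeds give bit-identical scenes.

What the generator does *not* emulate: tissue appearance, smoke, blood,
specular reflections, curved shafts (skeleton edges are straight by
design, mirroring a known limitation of the representation), instrument
texture, or annotation noise. Passing tests therefore demonstrate the
correctness of the data model, conversions and metric computation — not
robustness of any pose estimator to real surgical imagery.

`perturb_predictions` produces controlled detections from ground truth:
isotropic Gaussian jitter on labelled keypoints, tip-swap and drop events
with given probabilities, scores uniform on [0.5, 1) by default, and a
detection box re-derived from the perturbed keypoints. Because the
underlying standard normal draws are seed-determined, jitter scales
linearly with `noise_sd`, making AP exactly non-increasing across noise
levels at a fixed seed — the property the monotonicity test asserts over
50 scenes per level at noise 0–20 px.

`gen_dataset_tree` writes the release layout
`<split>/<Surgery_type>/<Procedure_ID>/<Frame_ID>/{raw.png,
instrument_instances.png, raw.json}`; the Testing split includes a surgery
type absent from Training/Validation, mirroring the held-out-domain
evaluation design.

## Numerical and design choices

* Matching: a similarity exactly equal to the threshold matches; among
  equal similarities the last ground truth in preference order wins
  (measure-zero with continuous similarities); score ties are broken by
  input order via stable sorts.
* Degenerate inputs: a box with `w = h = 0` has no scale (error); a
  ground truth with no labelled keypoint cannot be scored by `oks`
  directly (error) and is an ignore-instance in batch evaluation; an
  all-missing pose is refused by conversion and flagged by validation.
* Problem sizes in the test and acceptance runs (100 scenes for
  equivalence checks, 50 per noise level, 10⁴ random pairs for the scale
  and tip-swap laws, 10⁵ Monte-Carlo draws) were chosen to keep the full
  suite under ten seconds while leaving the statistical checks
  well-powered; all are trivially scalable.
* CLI exit codes: 0 success, 1 validation findings, 2 I/O or schema
  failure; JSON output carries a schema version.

## Known limitations

* The raw-JSON dialect's tag spelling is this package's own convention;
  only the four field names and the role abbreviations are fixed by the
  annotation tooling it models. Files from other writers may need a
  thin tag-mapping shim.
* The evaluator is single-category by design; multi-class evaluation and
  segmentation metrics (per-instance Dice/IoU) are out of scope.
* Tip-swap invariance is handled at evaluation time; nothing here helps a
  model learn tip-order equivalence during training.
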