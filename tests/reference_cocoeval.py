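"""Independent plain-loop reference of the COCO evaluation protocol.

Used only as a test oracle: written separately from the package's
vectorised evaluator, with scalar loops, an explicit precision-envelope
maximum per recall grid point, and its own similarity code.  It follows
the published COCO matching and accumulation rules:

* detections processed in descending score order (stable),
* each takes the unmatched ground truth of maximal similarity >= the
  threshold, preferring non-ignore instances,
* detections matched to ignore instances leave the precision denominator,
* AP = mean over the 101-point recall grid of the best precision at
  recall >= r, AR = maximal recall, both per threshold then averaged.
"""

from __future__ import annotations

import math


def ref_oks(pred12, gt12, s, kappas, tip_swap=False):
    """Scalar OKS; optionally best-of-both tip orderings."""

    def plain(gt):
        num, den = 0.0, 0
        for i in range(4):
            v = gt[3 * i + 2]
            if v <= 0:
                continue
            dx = pred12[3 * i] - gt[3 * i]
            dy = pred12[3 * i + 1] - gt[3 * i + 1]
            num += math.exp(-(dx * dx + dy * dy)
                            / (2.0 * s * s * kappas[i] ** 2))
            den += 1
        return num / den

    value = plain(gt12)
    if tip_swap:
        swapped = list(gt12[:6]) + list(gt12[9:12]) + list(gt12[6:9])
        value = max(value, plain(swapped))
    return value


def ref_oks_ignore(pred12, bbox, s, kappas):
    """Similarity to an unlabelled instance: distance to 2x-expanded box."""
    x, y, w, h = bbox
    x0, x1 = x - 2 * w, x + 3 * w
    y0, y1 = y - 2 * h, y + 3 * h
    num = 0.0
    for i in range(4):
        px, py = pred12[3 * i], pred12[3 * i + 1]
        dx = max(0.0, x0 - px) + max(0.0, px - x1)
        dy = max(0.0, y0 - py) + max(0.0, py - y1)
        num += math.exp(-(dx * dx + dy * dy) / (2.0 * s * s * kappas[i] ** 2))
    return num / 4.0


def ref_iou(a, b):
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def _match_image(sims, scores, ignore, threshold, max_dets):
    """Greedy per-image matching; returns per-detection (kept-order)
    lists of (score, is_tp, is_ignored)."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])[:max_dets]
    gt_taken = [False] * len(ignore)
    out = []
    gt_pref = sorted(range(len(ignore)), key=lambda j: ignore[j])
    for di in order:
        best = threshold
        match = -1
        for gj in gt_pref:
            if gt_taken[gj] and not ignore[gj]:
                continue
            if match >= 0 and not ignore[match] and ignore[gj]:
                break
            if sims[di][gj] < best:
                continue
            best = sims[di][gj]
            match = gj
        if match >= 0 and not ignore[match]:
            gt_taken[match] = True
            out.append((scores[di], True, False))
        elif match >= 0:
            out.append((scores[di], False, True))
        else:
            out.append((scores[di], False, False))
    return out


def ref_evaluate(images, thresholds, max_dets=20, recall_points=101):
    """Evaluate per-image data and return the six headline numbers.

    ``images`` is a list of dicts with keys ``sims`` (n_det x n_gt nested
    lists, full similarity in detection input order), ``scores`` (n_det)
    and ``ignore`` (n_gt booleans).
    """
    n_pos = sum(sum(0 if ig else 1 for ig in im["ignore"]) for im in images)
    grid = [r / (recall_points - 1) for r in range(recall_points)]
    ap_per_t, ar_per_t = [], []
    for t in thresholds:
        records = []
        for im in images:
            records.extend(_match_image(im["sims"], im["scores"],
                                        im["ignore"], t, max_dets))
        records.sort(key=lambda r: -r[0])
        if n_pos == 0:
            ap_per_t.append(-1.0)
            ar_per_t.append(-1.0)
            continue
        tp = fp = 0
        rc, pr = [], []
        for _, is_tp, is_ign in records:
            if is_ign:
                continue
            if is_tp:
                tp += 1
            else:
                fp += 1
            rc.append(tp / n_pos)
            pr.append(tp / (tp + fp))
        ar_per_t.append(rc[-1] if rc else 0.0)
        ap = 0.0
        for r in grid:
            best = 0.0
            for k in range(len(rc)):
                if rc[k] >= r:
                    # envelope: best precision anywhere at recall >= r
                    best = max(pr[k:])
                    break
            ap += best
        ap_per_t.append(ap / recall_points)
    def pick(vals, target):
        for t, v in zip(thresholds, vals):
            if abs(t - target) < 1e-9:
                return v
        return -1.0
    return {
        "ap_mean": sum(ap_per_t) / len(ap_per_t),
        "ap_050": pick(ap_per_t, 0.50),
        "ap_075": pick(ap_per_t, 0.75),
        "ar_mean": sum(ar_per_t) / len(ar_per_t),
        "ar_050": pick(ar_per_t, 0.50),
        "ar_075": pick(ar_per_t, 0.75),
    }
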