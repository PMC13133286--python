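"""Modified OKS, matching and AP/AR: closed forms, properties, protocol."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toolpose import (
    BoundingBox,
    OksParams,
    ScoredDetection,
    evaluate_bbox,
    evaluate_pose,
    frames_to_coco,
    greedy_match,
    iou,
    oks,
    oks_tip_swap,
    scale_factor,
)
from toolpose.metrics import swap_tips
from toolpose import FrameAnnotation

PARAMS = OksParams()
KAPPA = 0.214  # 2 * 0.107


def flat(*triplets):
    out = []
    for t in triplets:
        out.extend(t)
    return out


class TestScaleFactor:
    def test_square_box_reduces_to_side(self):
        assert scale_factor(BoundingBox(0, 0, 100, 100)) == pytest.approx(100)

    def test_hand_arithmetic(self):
        assert scale_factor(BoundingBox(0, 0, 300, 40)) \
            == pytest.approx(math.sqrt(45800), rel=1e-12)

    @given(st.floats(0.0, 1000.0), st.floats(0.0, 1000.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetry_and_am_gm(self, w, h):
        if w == 0 and h == 0:
            return
        a = scale_factor(BoundingBox(0, 0, w, h))
        b = scale_factor(BoundingBox(0, 0, h, w))
        assert a == b
        assert a * a >= w * h - 1e-9

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            scale_factor(BoundingBox(0, 0, 0, 0))


class TestOksClosedForms:
    def test_identity_is_one(self):
        gt = flat((10, 20, 2), (30, 40, 2), (50, 60, 2), (70, 80, 1))
        assert oks(gt, gt, s=100.0) == 1.0

    def test_single_displacement_e_minus_one(self):
        s = 120.0
        d = math.sqrt(2) * s * KAPPA
        gt = flat((100, 100, 2), (0, 0, 0), (0, 0, 0), (0, 0, 0))
        pred = flat((100 + d, 100, 2), (0, 0, 0), (0, 0, 0), (0, 0, 0))
        assert oks(pred, gt, s) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_two_keypoints_hand_sum(self):
        s = 90.0
        d = math.sqrt(2) * s * KAPPA
        gt = flat((100, 100, 2), (300, 100, 2), (0, 0, 0), (0, 0, 0))
        pred = flat((100, 100, 2), (300, 100 + d, 2), (0, 0, 0), (0, 0, 0))
        assert oks(pred, gt, s) == pytest.approx((1 + math.exp(-1)) / 2,
                                                 abs=1e-12)

    def test_unlabelled_gt_keypoints_contribute_nothing(self):
        gt = flat((100, 100, 2), (300, 100, 0), (0, 0, 0), (0, 0, 0))
        pred = flat((100, 100, 2), (999, 999, 2), (0, 0, 0), (0, 0, 0))
        assert oks(pred, gt, 100.0) == 1.0

    def test_all_unlabelled_raises(self):
        gt = flat((0, 0, 0), (0, 0, 0), (0, 0, 0), (0, 0, 0))
        with pytest.raises(ValueError):
            oks(gt, gt, 100.0)

    def test_strictly_decreasing_in_displacement(self):
        gt = flat((100, 100, 2), (200, 100, 2), (0, 0, 0), (0, 0, 0))
        values = []
        for shift in (0, 5, 10, 20, 50):
            pred = flat((100, 100, 2), (200 + shift, 100, 2),
                        (0, 0, 0), (0, 0, 0))
            values.append(oks(pred, gt, 100.0))
        assert all(a > b for a, b in zip(values, values[1:]))
        assert all(0 <= v <= 1 for v in values)


class TestTipSwap:
    def test_crossed_tips_score_one_only_with_swap(self):
        gt = flat((100, 250, 2), (400, 250, 2), (460, 200, 2), (460, 300, 2))
        pred = flat((100, 250, 2), (400, 250, 2), (460, 300, 2), (460, 200, 2))
        s = 150.0
        assert oks(pred, gt, s) < 1.0
        assert oks_tip_swap(pred, gt, s) == 1.0

    def test_rigid_gt_swap_moves_label_to_other_slot(self):
        # gt tip2 unlabelled; prediction put the real tip in the tip2 slot
        gt = flat((100, 250, 2), (400, 250, 2), (460, 200, 2), (0, 0, 0))
        pred = flat((100, 250, 2), (400, 250, 2), (0, 0, 0), (460, 200, 2))
        s = 150.0
        both = [oks(pred, gt, s), oks(pred, swap_tips(gt), s)]
        assert oks_tip_swap(pred, gt, s) == max(both) == 1.0

    def test_max_is_order_free(self):
        gt = flat((100, 250, 2), (400, 250, 2), (460, 200, 2), (460, 300, 2))
        pred = flat((110, 250, 2), (390, 250, 2), (470, 290, 2), (450, 210, 2))
        assert oks_tip_swap(pred, gt, 150.0) \
            == pytest.approx(oks_tip_swap(swap_tips(pred), gt, 150.0))

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_never_below_plain_oks(self, seed):
        rng = np.random.default_rng(seed)
        gt = rng.uniform(0, 500, (4, 3))
        gt[:, 2] = rng.integers(0, 3, 4)
        if not (gt[:, 2] > 0).any():
            gt[0, 2] = 2
        pred = rng.uniform(0, 500, (4, 3))
        s = float(rng.uniform(20, 400))
        assert oks_tip_swap(pred, gt, s) >= oks(pred, gt, s)


class TestIou:
    def test_identical(self):
        b = BoundingBox(10, 10, 50, 80)
        assert iou(b, b) == 1.0

    def test_disjoint(self):
        assert iou(BoundingBox(0, 0, 10, 10), BoundingBox(50, 50, 5, 5)) == 0.0

    def test_hand_arithmetic(self):
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(1, 0, 2, 2)) \
            == pytest.approx(2 / 6)

    def test_zero_area_boxes(self):
        z = BoundingBox(5, 5, 0, 0)
        assert iou(z, z) == 0.0


class TestGreedyMatch:
    def test_single_pair(self):
        dm, gm, di = greedy_match(np.array([[0.9]]), [0.7], [False], 0.5)
        assert dm[0] == 0 and gm[0] == 0 and not di[0]

    def test_higher_score_wins_contested_gt(self):
        sim = np.array([[0.9], [0.95]])  # second det fits better...
        dm, gm, _ = greedy_match(sim, [0.9, 0.8], [False], 0.5)
        # ...but the higher-score detection is processed first and takes it
        assert dm[0] == 0 and dm[1] == -1 and gm[0] == 0

    def test_below_threshold_unmatched(self):
        dm, _, _ = greedy_match(np.array([[0.4]]), [0.9], [False], 0.5)
        assert dm[0] == -1

    def test_match_to_ignore_is_discounted(self):
        sim = np.array([[0.8]])
        dm, _, di = greedy_match(sim, [0.9], [True], 0.5)
        assert dm[0] == 0 and di[0]

    def test_real_gt_preferred_over_ignore(self):
        sim = np.array([[0.6, 0.99]])  # ignore gt is more similar
        dm, _, di = greedy_match(sim, [0.9], [False, True], 0.5)
        assert dm[0] == 0 and not di[0]


def _gt_and_identity_dets(n_frames=6, seed=5):
    from toolpose.synthetic import SceneConfig, gen_scene, perturb_predictions
    cfg = SceneConfig(seed=seed)
    frames = []
    dets = []
    for i in range(n_frames):
        frame, _ = gen_scene(cfg, seed=seed * 1000 + i)
        frames.append(frame)
        dets.extend(perturb_predictions(frame, seed=seed + i,
                                        image_id=i + 1))
    return frames_to_coco(frames), dets


class TestEvaluate:
    def test_identity_predictions_score_one_everywhere(self):
        gt, dets = _gt_and_identity_dets()
        pose = evaluate_pose(gt, dets)
        box = evaluate_bbox(gt, dets)
        for v in list(pose.headline().values()) + list(box.headline().values()):
            assert v == 1.0

    def test_no_detections_scores_zero(self):
        gt, _ = _gt_and_identity_dets()
        summary = evaluate_pose(gt, [])
        assert summary.ap_mean == 0.0 and summary.ar_mean == 0.0

    def test_empty_ground_truth_is_sentinel(self):
        gt = frames_to_coco([FrameAnnotation(frame_id="empty")])
        summary = evaluate_pose(gt, [])
        assert summary.ap_mean == -1.0 and summary.ar_mean == -1.0

    def test_shifted_boxes_pass_050_fail_075(self):
        # one gt box and a prediction shifted to an IoU strictly in (0.5, 0.75)
        gt, dets = _gt_and_identity_dets(n_frames=4)
        shifted = []
        for d in dets:
            b = d.bbox
            dx = 0.25 * b.w  # IoU = 0.75/1.25 = 0.6 for a pure x-shift
            nb = BoundingBox(b.xmin + dx, b.ymin, b.w, b.h)
            assert 0.5 < iou(b, nb) < 0.75
            shifted.append(ScoredDetection(d.image_id, d.keypoints,
                                           d.score, nb))
        summary = evaluate_bbox(gt, shifted)
        assert summary.ap_050 == 1.0
        assert summary.ap_075 == 0.0

    def test_ap_non_increasing_in_threshold(self):
        from toolpose.synthetic import SceneConfig, gen_scene, \
            perturb_predictions
        cfg = SceneConfig(seed=9)
        frames, dets = [], []
        for i in range(10):
            frame, _ = gen_scene(cfg, seed=100 + i)
            frames.append(frame)
            dets.extend(perturb_predictions(frame, noise_sd=8.0,
                                            seed=200 + i, image_id=i + 1))
        summary = evaluate_pose(frames_to_coco(frames), dets)
        ap_per_t = summary.precision.mean(axis=1)
        assert all(a >= b - 1e-12 for a, b in zip(ap_per_t, ap_per_t[1:]))
        assert summary.ap_050 >= summary.ap_075
        assert summary.ar_050 >= summary.ar_075

    def test_tip_swap_toggle_changes_score_for_swapped_tips(self):
        from toolpose.synthetic import SceneConfig, gen_scene, \
            perturb_predictions
        cfg = SceneConfig(seed=4, scenario_weights={"articulated_visible": 1.0})
        frames, dets = [], []
        for i in range(8):
            frame, _ = gen_scene(cfg, seed=300 + i)
            frames.append(frame)
            dets.extend(perturb_predictions(frame, swap_prob=1.0,
                                            seed=400 + i, image_id=i + 1))
        gt = frames_to_coco(frames)
        with_swap = evaluate_pose(gt, dets, OksParams(tip_swap=True))
        without = evaluate_pose(gt, dets, OksParams(tip_swap=False))
        assert with_swap.ap_mean == 1.0
        assert without.ap_mean < 1.0


class TestOksParams:
    def test_kappa_is_twice_sigma(self):
        p = OksParams()
        assert np.allclose(p.kappas, 2 * p.sigmas)
        assert np.allclose(p.sigmas, 0.107)

    def test_threshold_grid_is_ten_values(self):
        p = OksParams()
        assert len(p.oks_thresholds) == 10
        assert p.oks_thresholds[0] == 0.50 and p.oks_thresholds[-1] == 0.95

    @pytest.mark.parametrize("kwargs", [
        {"sigmas": np.zeros(4)},
        {"oks_thresholds": np.array([0.9, 0.5])},
        {"max_detections": 0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OksParams(**kwargs)
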