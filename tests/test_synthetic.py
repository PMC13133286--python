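"""Synthetic scene generator: determinism, geometry, coverage, trees."""

import json
import math

import numpy as np
import pytest

from toolpose import (
    SceneConfig,
    gen_dataset_tree,
    gen_scene,
    parse_raw_json,
    perturb_predictions,
    read_mask,
    validate_frame,
)
from toolpose.synthetic import SCENARIOS


class TestGenScene:
    def test_same_seed_bit_identical(self, scene_config):
        f1, m1 = gen_scene(scene_config)
        f2, m2 = gen_scene(scene_config)
        assert np.array_equal(m1.labels, m2.labels)
        for p1, p2 in zip(f1.poses, f2.poses):
            for (_, a), (_, b) in zip(p1.slots(), p2.slots()):
                assert (a.x, a.y, a.tag) == (b.x, b.y, b.tag)

    def test_different_seeds_differ(self, scene_config):
        _, m1 = gen_scene(scene_config, seed=1)
        _, m2 = gen_scene(scene_config, seed=2)
        assert not np.array_equal(m1.labels, m2.labels)

    def test_every_pose_validates_many_draws(self, scene_config):
        # protocol-clean by construction, across a large seeded sweep
        for s in range(1000):
            frame, _ = gen_scene(scene_config, seed=s)
            assert validate_frame(frame) == []

    def test_entry_on_fov_circle(self, scene_config):
        cx, cy = scene_config.fov_center
        for s in range(50):
            frame, _ = gen_scene(scene_config, seed=s)
            for pose in frame.poses:
                r = math.hypot(pose.entry.x - cx, pose.entry.y - cy)
                assert abs(r - scene_config.fov_radius) < 0.5

    def test_tool_count_within_range(self):
        cfg = SceneConfig(seed=0, n_tools=(2, 2))
        frame, mask = gen_scene(cfg)
        assert len(frame.poses) == 2
        assert mask.instance_ids() == [1, 2]

    def test_scenario_coverage_within_500_draws(self):
        cfg = SceneConfig(seed=31)
        seen = set()
        for s in range(500):
            frame, _ = gen_scene(cfg, seed=s)
            for pose in frame.poses:
                missing = [kp.is_missing for _, kp in pose.slots()]
                occluded = any(kp.tag.value == "occluded"
                               for _, kp in pose.slots())
                if missing == [False, False, False, False]:
                    seen.add("articulated_occluded" if occluded
                             else "articulated_visible")
                elif missing == [False, False, False, True]:
                    seen.add("single_tip")  # closed articulated or rigid
                elif missing == [False, False, True, True]:
                    seen.add("shaft_only")
            if len(seen) == 4:
                break
        assert seen == {"articulated_visible", "articulated_occluded",
                        "single_tip", "shaft_only"}

    def test_forced_scenario_weights(self):
        cfg = SceneConfig(seed=7, scenario_weights={"rigid_visible": 1.0})
        for s in range(20):
            frame, _ = gen_scene(cfg, seed=s)
            for pose in frame.poses:
                assert pose.tip2.is_missing and not pose.tip1.is_missing

    def test_mask_pose_geometric_consistency(self):
        from toolpose import pose_mask_consistency
        cfg = SceneConfig(seed=13)
        fracs = []
        for s in range(50):
            frame, mask = gen_scene(cfg, seed=s)
            for pose in frame.poses:
                fracs.append(pose_mask_consistency(
                    pose, mask, radius=cfg.shaft_thickness))
        assert np.mean(fracs) >= 0.99

    @pytest.mark.parametrize("bad", [
        {"fov_center": (5000.0, 270.0)},
        {"articulated_fraction": 1.5},
        {"n_tools": (0, 2)},
        {"scenario_weights": {"rigid_visible": 0.5}},
        {"scenario_weights": {"no_such_state": 1.0}},
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SceneConfig(**bad)


class TestPerturb:
    def test_zero_noise_equals_ground_truth(self, scene_config):
        from toolpose import frames_to_coco
        frame, _ = gen_scene(scene_config)
        dets = perturb_predictions(frame, seed=0)
        gt = frames_to_coco([frame])
        assert len(dets) == len(gt.annotations)
        for d, a in zip(dets, gt.annotations):
            assert d.keypoints == a.keypoints

    def test_deterministic_given_seed(self, scene_config):
        frame, _ = gen_scene(scene_config)
        a = perturb_predictions(frame, noise_sd=5.0, seed=3)
        b = perturb_predictions(frame, noise_sd=5.0, seed=3)
        assert [d.keypoints for d in a] == [d.keypoints for d in b]
        assert [d.score for d in a] == [d.score for d in b]

    def test_drop_probability_one_drops_everything(self, scene_config):
        frame, _ = gen_scene(scene_config)
        assert perturb_predictions(frame, drop_prob=1.0, seed=0) == []

    def test_swap_exchanges_tip_triplets(self):
        cfg = SceneConfig(seed=2, scenario_weights={"articulated_visible": 1.0})
        frame, _ = gen_scene(cfg)
        plain = perturb_predictions(frame, seed=5)
        swapped = perturb_predictions(frame, swap_prob=1.0, seed=5)
        for p, s in zip(plain, swapped):
            assert s.keypoints[6:9] == p.keypoints[9:12]
            assert s.keypoints[9:12] == p.keypoints[6:9]

    def test_invalid_parameters_rejected(self, scene_config):
        frame, _ = gen_scene(scene_config)
        with pytest.raises(ValueError):
            perturb_predictions(frame, noise_sd=-1.0)
        with pytest.raises(ValueError):
            perturb_predictions(frame, drop_prob=1.5)


class TestDatasetTree:
    def test_layout_and_file_triplet(self, tmp_path):
        cfg = SceneConfig(seed=1)
        manifest = gen_dataset_tree(tmp_path / "ds",
                                    {"Training": (2, 2)}, cfg)
        assert len(manifest["frames"]) == 4
        for entry in manifest["frames"]:
            d = tmp_path / "ds" / entry["frame"]
            assert (d / "raw.json").exists()
            assert (d / "instrument_instances.png").exists()
            assert (d / "raw.png").exists()
            frame = parse_raw_json((d / "raw.json").read_text())
            assert validate_frame(frame) == []
            mask = read_mask(d / "instrument_instances.png")
            assert mask.width == cfg.width and mask.height == cfg.height

    def test_rerun_same_seed_identical_manifest(self, tmp_path):
        cfg = SceneConfig(seed=8)
        m1 = gen_dataset_tree(tmp_path / "a", {"Training": (1, 3)}, cfg)
        m2 = gen_dataset_tree(tmp_path / "b", {"Training": (1, 3)}, cfg)
        strip_root = lambda m: [{k: v for k, v in f.items()}
                                for f in m["frames"]]
        assert strip_root(m1) == strip_root(m2)
        j1 = json.loads((tmp_path / "a" / m1["frames"][0]["frame"]
                         / "raw.json").read_text())
        j2 = json.loads((tmp_path / "b" / m2["frames"][0]["frame"]
                         / "raw.json").read_text())
        assert j1 == j2

    def test_testing_split_adds_held_out_surgery(self, tmp_path):
        cfg = SceneConfig(seed=3)
        manifest = gen_dataset_tree(
            tmp_path / "ds",
            {"Training": (4, 1), "Validation": (2, 1), "Testing": (6, 1)},
            cfg)
        per_split = {}
        for f in manifest["frames"]:
            per_split.setdefault(f["split"], set()).add(f["surgery"])
        assert "Sigmoid_resection" not in per_split["Training"]
        assert "Sigmoid_resection" not in per_split["Validation"]
        assert "Sigmoid_resection" in per_split["Testing"]
        assert per_split["Training"] <= per_split["Testing"]

    def test_refuses_non_empty_root(self, tmp_path):
        root = tmp_path / "ds"
        root.mkdir()
        (root / "existing.txt").write_text("data")
        with pytest.raises(FileExistsError):
            gen_dataset_tree(root, {"Training": (1, 1)}, SceneConfig())
        gen_dataset_tree(root, {"Training": (1, 1)}, SceneConfig(), force=True)


def test_all_six_scenarios_generate():
    for scenario in SCENARIOS:
        cfg = SceneConfig(seed=5, scenario_weights={scenario: 1.0})
        frame, mask = gen_scene(cfg)
        assert frame.poses and validate_frame(frame) == []
        assert mask.instance_ids()
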