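import json
import math
from dataclasses import replace

import numpy as np
import pytest

from glowlabel.barcode import Match
from glowlabel.errors import ExportError, InputError
from glowlabel.fixtures import SpeckleFixtureSpec, gen_speckle_scene
from glowlabel.propagation import (
    AugmentConfig,
    AutoLandmarkConfig,
    NeighborhoodLabelConfig,
    TrainingTargetConfig,
    augment_image,
    composite_background,
    export_dataset,
    import_coco_dataset,
    make_segmentation_mask,
    make_training_targets,
    multiscale_noise,
    pool_manual_neighborhood,
    propagate_frame,
    propagate_landmark,
    select_auto_landmarks,
)
from glowlabel.serial import LandmarkLabel


def mk(left_index, lx, ly, rx, ry):
    return Match(left_index, left_index, (float(lx), float(ly)), (float(rx), float(ry)), 1.0)


def fs_from_xy(xy):
    from glowlabel.barcode import FeatureSet

    xy = np.asarray(xy, float)
    kp = np.column_stack([xy, np.ones(len(xy)), np.zeros(len(xy))])
    rng = np.random.default_rng(0)
    return FeatureSet("template", kp, rng.random((len(xy), 16)))


class TestPoolManualNeighborhood:
    def test_below_minimum_absent(self):
        ms = {1: [mk(i, 0, 0, 10, 10) for i in range(4)]}
        labels = pool_manual_neighborhood(ms, NeighborhoodLabelConfig(min_matches=5))
        assert not labels[1].present

    def test_hand_computed_medians(self):
        xs = [10, 11, 12, 13, 14, 15, 16]
        ms = {2: [mk(i, 0, 0, x, 20) for i, x in enumerate(xs)]}
        labels = pool_manual_neighborhood(ms)
        assert labels[2].present
        assert labels[2].x == 13.0 and labels[2].y == 20.0

    def test_identical_matches(self):
        ms = {0: [mk(i, 0, 0, 50, 50) for i in range(5)]}
        labels = pool_manual_neighborhood(ms)
        assert labels[0].xy == (50.0, 50.0)

    def test_multi_template_pooling_before_count(self):
        # 3 matches from one template + 2 from another: pooled -> present
        pooled = [mk(i, 0, 0, 10 + i, 5) for i in range(3)]
        pooled += [mk(10 + i, 0, 0, 20 + i, 5) for i in range(2)]
        labels = pool_manual_neighborhood({4: pooled})
        assert labels[4].present


class TestSelectAutoLandmarks:
    def test_collinear_spacing(self):
        feats = fs_from_xy([(0, 0), (20, 0), (40, 0)])
        for seed in range(6):
            cfg = AutoLandmarkConfig(min_spacing_px=30, seed=seed)
            sel = select_auto_landmarks(feats, cfg)
            xy = feats.xy[sel.landmark_indices]
            # feasible: pairwise spacing respected; 20-apart pair never both kept
            for i in range(len(xy)):
                for j in range(i + 1, len(xy)):
                    assert np.hypot(*(xy[i] - xy[j])) >= 30
            # maximal: no unselected candidate could be added
            for k in range(3):
                if k not in sel.landmark_indices:
                    assert any(
                        np.hypot(*(feats.xy[k] - xy[i])) < 30 for i in range(len(xy))
                    )
            assert set(sel.landmark_indices) in ({0, 2}, {1})

    def test_all_within_one_disk(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (20, 2))
        sel = select_auto_landmarks(fs_from_xy(pts), AutoLandmarkConfig(min_spacing_px=30))
        assert len(sel.landmark_indices) == 1

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 200, (80, 2))
        feats = fs_from_xy(pts)
        cfg = AutoLandmarkConfig(seed=7)
        a = select_auto_landmarks(feats, cfg)
        b = select_auto_landmarks(feats, cfg)
        assert a.landmark_indices == b.landmark_indices
        assert a.neighbor_lists == b.neighbor_lists

    def test_candidate_mask_restricts(self):
        pts = [(10, 10), (100, 100)]
        mask = np.zeros((128, 128), bool)
        mask[:50, :50] = True
        sel = select_auto_landmarks(fs_from_xy(pts), AutoLandmarkConfig(), candidate_mask=mask)
        assert sel.landmark_indices == [0]

    def test_empty_candidates(self):
        sel = select_auto_landmarks(
            fs_from_xy([(10, 10)]),
            AutoLandmarkConfig(),
            candidate_mask=np.zeros((64, 64), bool),
        )
        assert sel.landmark_indices == []

    def test_neighbor_lists_within_radius(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 150, (60, 2))
        feats = fs_from_xy(pts)
        cfg = AutoLandmarkConfig(neighborhood_radius_px=30)
        sel = select_auto_landmarks(feats, cfg)
        for i, neigh in sel.neighbor_lists.items():
            assert i not in neigh
            for j in neigh:
                assert np.hypot(*(feats.xy[i] - feats.xy[j])) <= 30
            outside = set(range(60)) - set(neigh) - {i}
            for j in outside:
                assert np.hypot(*(feats.xy[i] - feats.xy[j])) > 30

    def test_min_neighbors_floor(self):
        with pytest.raises(ValueError):
            AutoLandmarkConfig(min_neighbors=3)


class TestPropagateLandmark:
    def test_direct_match_used(self):
        feats = fs_from_xy([(50, 50)])
        label = propagate_landmark(0, [], feats, [mk(0, 50, 50, 120, 80)])
        assert label.present and label.xy == (120.0, 80.0)
        assert label.source == "detector"

    def test_translation_homography(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([[(100, 100)], rng.uniform(80, 120, (10, 2))])
        feats = fs_from_xy(pts)
        matches = [mk(j, *pts[j], pts[j][0] + 15, pts[j][1] - 5) for j in range(1, 11)]
        label = propagate_landmark(0, list(range(1, 11)), feats, matches)
        assert label.present and label.source == "propagated"
        assert label.x == pytest.approx(115.0, abs=1e-6)
        assert label.y == pytest.approx(95.0, abs=1e-6)

    def test_too_few_neighbors_absent(self):
        feats = fs_from_xy([(100, 100), (90, 90), (110, 110), (95, 105)])
        matches = [mk(j, *feats.xy[j], feats.xy[j][0] + 1, feats.xy[j][1]) for j in (1, 2, 3)]
        label = propagate_landmark(0, [1, 2, 3], feats, matches, AutoLandmarkConfig())
        assert not label.present

    def test_collinear_support_degenerates_to_absent(self):
        pts = [(100.0, 100.0)] + [(float(x), float(x)) for x in range(50, 150, 10)]
        feats = fs_from_xy(pts)
        matches = [mk(j, *pts[j], pts[j][0] * 2, pts[j][1] * 2) for j in range(1, 11)]
        cfg = AutoLandmarkConfig(min_support_sv_px=1.0)
        with pytest.warns(UserWarning, match="degenerate"):
            label = propagate_landmark(0, list(range(1, 11)), feats, matches, cfg)
        assert not label.present

    def test_projective_fixture_recovery(self, speckle_projective, projective_pair_features):
        from glowlabel.barcode import CoherencyConfig, coherency_filter, match_features

        fa, fb = projective_pair_features
        matches = coherency_filter(match_features(fa, fb), CoherencyConfig(25, 25))
        cfg = AutoLandmarkConfig(seed=0)
        landmarks = select_auto_landmarks(fa, cfg)
        labels = propagate_frame(landmarks, matches, cfg)
        corr = speckle_projective.correspondences[0]
        present = [i for i, l in labels.items() if l.present]
        assert len(present) / len(landmarks.landmark_indices) >= 0.95
        errs = [
            math.hypot(*(np.array(labels[i].xy) - corr(fa.xy[i][None, :])[0]))
            for i in present
        ]
        assert max(errs) < 1.5

    def test_homography_strictly_beats_direct_only(self, projective_pair_features):
        from glowlabel.barcode import CoherencyConfig, coherency_filter, match_features

        fa, fb = projective_pair_features
        matches = coherency_filter(match_features(fa, fb), CoherencyConfig(25, 25))
        cfg = AutoLandmarkConfig(seed=0)
        landmarks = select_auto_landmarks(fa, cfg)
        with_h = propagate_frame(landmarks, matches, cfg, use_homography=True)
        without = propagate_frame(landmarks, matches, cfg, use_homography=False)
        frac_h = np.mean([l.present for l in with_h.values()])
        frac_d = np.mean([l.present for l in without.values()])
        assert frac_h > frac_d


class TestSegmentationMask:
    def test_ellipse_speckles_fused(self):
        spec = SpeckleFixtureSpec(
            foreground="ellipse", n_spots=900, seed=0, background_noise_amp=0.0
        )
        scene = gen_speckle_scene(spec)
        mask = make_segmentation_mask(scene.template, dilation_px=2, closing_px=15)
        ellipse = scene.foreground_masks[0]
        assert mask[ellipse].mean() >= 0.95
        from skimage.morphology import dilation, disk

        grown = dilation(ellipse, disk(4))
        assert mask[~grown].sum() == 0

    def test_blank_frame_empty(self):
        assert not make_segmentation_mask(np.zeros((64, 64))).any()

    def test_solid_region_idempotent(self):
        img = np.zeros((64, 64))
        img[20:40, 20:40] = 1.0
        mask = make_segmentation_mask(img, dilation_px=0, closing_px=3)
        assert np.array_equal(mask, img > 0)


class TestCompositeBackground:
    def test_all_ones_mask_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        out = composite_background(img, np.ones((32, 32), bool), {"type": "noise"}, seed=1)
        assert np.array_equal(out, img)

    def test_all_zeros_mask_constant(self):
        img = np.random.default_rng(0).random((32, 32))
        out = composite_background(
            img, np.zeros((32, 32), bool), {"type": "constant", "value": 0.3}
        )
        assert np.allclose(out, 0.3)

    def test_noise_deterministic(self):
        img = np.zeros((32, 32))
        mask = np.zeros((32, 32), bool)
        a = composite_background(img, mask, None, seed=5)
        b = composite_background(img, mask, None, seed=5)
        assert np.array_equal(a, b)

    def test_foreground_pixels_exact(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        mask = rng.random((32, 32)) > 0.5
        out = composite_background(img, mask, None, seed=2)
        assert np.array_equal(out[mask], img[mask])

    def test_size_mismatch_rejected(self):
        with pytest.raises(InputError):
            composite_background(np.zeros((8, 8)), np.zeros((9, 9), bool))


class TestTrainingTargets:
    def _cfg(self, roster=("hand",), stride=8, radius=17.0):
        return TrainingTargetConfig(
            stride=stride, positive_radius_px=radius, landmark_roster=tuple(roster)
        )

    def test_map_geometry_and_positive_cell(self):
        cfg = self._cfg()
        labels = {"hand": LandmarkLabel(0, 424.0, 424.0, True)}
        targets, loss = make_training_targets(labels, (848, 848), cfg)
        assert targets.shape == (1, 106, 106)  # ceil(848 / 8)
        assert targets[0, 53, 53] == 1.0
        assert loss[0] == 1.0

    def test_absent_label_all_zero_supervised(self):
        cfg = self._cfg(("hand", "foot"))
        labels = {"hand": LandmarkLabel.absent(0)}
        targets, loss = make_training_targets(labels, (64, 64), cfg)
        assert targets[0].sum() == 0.0 and loss[0] == 1.0
        assert loss[1] == 0.0  # foot unlabeled: interleaved contract

    def test_no_labels_all_masks_zero(self):
        cfg = self._cfg(("a", "b"))
        targets, loss = make_training_targets({}, (64, 64), cfg)
        assert (loss == 0).all() and targets.sum() == 0

    def test_label_outside_image_rejected(self):
        cfg = self._cfg()
        with pytest.raises(InputError):
            make_training_targets(
                {"hand": LandmarkLabel(0, 100.0, 10.0, True)}, (64, 64), cfg
            )

    def test_odd_size_ceil(self):
        cfg = self._cfg(stride=8)
        targets, _ = make_training_targets(
            {"hand": LandmarkLabel(0, 1.0, 1.0, True)}, (65, 63), cfg
        )
        assert targets.shape == (1, 9, 8)

    def test_positive_disk_radius(self):
        cfg = self._cfg(stride=1, radius=5.0)
        labels = {"hand": LandmarkLabel(0, 32.0, 32.0, True)}
        targets, _ = make_training_targets(labels, (64, 64), cfg)
        ys, xs = np.nonzero(targets[0])
        assert (np.hypot(xs - 32, ys - 32) <= 5.0).all()
        assert targets[0, 32, 32] == 1.0


class TestAugmentImage:
    def test_identity_config_unchanged(self):
        rng = np.random.default_rng(0)
        img = rng.random((48, 48))
        labels = [LandmarkLabel(0, 10.0, 20.0, True)]
        out, new = augment_image(img, labels, seed=3, cfg=AugmentConfig.identity())
        assert np.array_equal(out, img)
        assert new[0].xy == (10.0, 20.0)

    def test_pure_translation_shifts_labels(self):
        cfg = replace(
            AugmentConfig.identity(),
            translate_x_frac=(10 / 48, 10 / 48),
            translate_y_frac=(0.0, 0.0),
        )
        img = np.zeros((48, 48))
        labels = [LandmarkLabel(0, 10.0, 20.0, True)]
        _, new = augment_image(img, labels, seed=0, cfg=cfg)
        assert new[0].x == pytest.approx(20.0, abs=1e-9)
        assert new[0].y == pytest.approx(20.0, abs=1e-9)

    def test_corner_marker_commutes(self):
        # geometric consistency: brightest pixel follows the transformed label
        cfg = replace(
            AugmentConfig.identity(),
            translate_x_frac=(0.1, 0.1),
            translate_y_frac=(-0.05, -0.05),
        )
        img = np.zeros((64, 64))
        img[30, 20] = 1.0
        labels = [LandmarkLabel(0, 20.0, 30.0, True)]
        out, new = augment_image(img, labels, seed=0, cfg=cfg)
        peak = np.unravel_index(np.argmax(out), out.shape)
        assert peak[1] == pytest.approx(new[0].x, abs=1.0)
        assert peak[0] == pytest.approx(new[0].y, abs=1.0)

    def test_label_leaving_frame_absent(self):
        cfg = replace(
            AugmentConfig.identity(), translate_x_frac=(0.9, 0.9), translate_y_frac=(0.0, 0.0)
        )
        _, new = augment_image(
            np.zeros((48, 48)), [LandmarkLabel(0, 40.0, 10.0, True)], seed=0, cfg=cfg
        )
        assert not new[0].present

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        img = rng.random((48, 48))
        labels = [LandmarkLabel(0, 10.0, 20.0, True)]
        a_img, a_lab = augment_image(img, labels, seed=11)
        b_img, b_lab = augment_image(img, labels, seed=11)
        assert np.array_equal(a_img, b_img)
        assert a_lab == b_lab


class TestExportDataset:
    def _dataset(self):
        images = [
            {"id": f"im{i}", "file_name": f"im{i}.png", "width": 64, "height": 64}
            for i in range(3)
        ]
        roster = ["a", "b"]
        labels = {
            "im0": {"a": LandmarkLabel(0, 1.0, 2.0, True), "b": LandmarkLabel(0, 3.0, 4.0, True)},
            "im1": {"a": LandmarkLabel(1, 5.0, 6.0, True), "b": LandmarkLabel.absent(1)},
            "im2": {},
        }
        return images, labels, roster

    def test_coco_schema_arithmetic(self, tmp_path):
        images, labels, roster = self._dataset()
        path = tmp_path / "d.json"
        export_dataset(images, labels, roster, path)
        doc = json.loads(path.read_text())
        assert len(doc["images"]) == 3
        assert len(doc["annotations"]) == 3
        assert all(len(a["keypoints"]) == 6 for a in doc["annotations"])

    def test_absent_encoded_as_zero_visibility(self, tmp_path):
        images, labels, roster = self._dataset()
        path = tmp_path / "d.json"
        export_dataset(images, labels, roster, path)
        doc = json.loads(path.read_text())
        ann = next(a for a in doc["annotations"] if a["image_id"] == "im1")
        assert ann["keypoints"][3:6] == [0.0, 0.0, 0]

    def test_round_trip_byte_identical(self, tmp_path):
        images, labels, roster = self._dataset()
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        export_dataset(images, labels, roster, p1)
        images2, labels2, roster2 = import_coco_dataset(p1)
        export_dataset(images2, labels2, roster2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_duplicate_image_ids_rejected(self, tmp_path):
        images, labels, roster = self._dataset()
        images.append(dict(images[0]))
        with pytest.raises(ExportError):
            export_dataset(images, labels, roster, tmp_path / "d.json")

    def test_csv_export(self, tmp_path):
        import pandas as pd

        images, labels, roster = self._dataset()
        path = tmp_path / "d.csv"
        export_dataset(images, labels, roster, path, format="csv")
        df = pd.read_csv(path)
        assert len(df) == 6
        assert df["present"].sum() == 3


def test_multiscale_noise_range_and_determinism():
    a = multiscale_noise((40, 40), seed=0)
    b = multiscale_noise((40, 40), seed=0)
    assert np.array_equal(a, b)
    assert a.min() == 0.0 and a.max() == pytest.approx(1.0)
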