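import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spa_pta.pose_features import (
    COCO_KEYPOINTS,
    PoseParseError,
    PoseSchemaError,
    PoseSequence,
    clip_windows,
    combine_hand_labels,
    map_rating_label,
    map_type_label,
    normalize_pose,
    parse_pose_stream,
    scale_by_torso,
    select_upper_body,
    visible_runs,
)

from conftest import make_coco_frame


def coco_sequence(n_frames=3, fps=30.0):
    joints = np.zeros((n_frames, 17, 3))
    for t in range(n_frames):
        joints[t] = np.asarray(make_coco_frame(base=100.0 + t)).reshape(17, 3)
    return PoseSequence(joints=joints, joint_names=COCO_KEYPOINTS, fps=fps)


class TestParsePoseStream:
    def test_toy_three_frames(self):
        records = [{"image_id": f"{t}.jpg", "score": 1.0,
                    "keypoints": make_coco_frame()} for t in range(3)]
        seq = parse_pose_stream(records)
        assert seq.n_frames == 3
        assert seq.joints.shape == (3, 17, 3)
        assert seq.visible.all()

    def test_frame_without_detection_marked_invisible(self):
        records = [
            {"image_id": "0.jpg", "score": 1.0, "keypoints": make_coco_frame()},
            {"image_id": "1.jpg", "score": 0.0, "keypoints": []},
            {"image_id": "2.jpg", "score": 1.0, "keypoints": make_coco_frame()},
        ]
        seq = parse_pose_stream(records)
        assert list(seq.visible) == [True, False, True]

    def test_highest_score_detection_wins(self):
        strong = make_coco_frame(base=200.0)
        weak = make_coco_frame(base=50.0)
        records = [
            {"image_id": "0.jpg", "score": 0.4, "keypoints": weak},
            {"image_id": "0.jpg", "score": 0.9, "keypoints": strong},
        ]
        seq = parse_pose_stream(records)
        assert seq.joints[0, 0, 0] == pytest.approx(200.0)

    def test_frames_sorted_numerically(self):
        records = [{"image_id": f"{t}.jpg", "score": 1.0,
                    "keypoints": make_coco_frame(base=float(t))}
                   for t in (10, 2, 1)]
        seq = parse_pose_stream(records)
        assert list(seq.joints[:, 0, 0]) == [1.0, 2.0, 10.0]

    def test_malformed_record_names_frame(self):
        records = [{"image_id": "7.jpg", "score": 1.0, "keypoints": [1.0, 2.0]}]
        with pytest.raises(PoseParseError, match="7.jpg"):
            parse_pose_stream(records)

    def test_empty_stream_rejected(self):
        with pytest.raises(PoseParseError):
            parse_pose_stream([])


class TestSelectUpperBody:
    def test_nine_joints_no_face_or_legs(self):
        out = select_upper_body(coco_sequence())
        assert len(out.joint_names) == 9
        for name in out.joint_names:
            assert "eye" not in name and "ear" not in name
            assert "knee" not in name and "ankle" not in name and name != "nose"

    def test_neck_is_shoulder_midpoint(self):
        seq = coco_sequence(1)
        ls, rs = seq.joint_index("left_shoulder"), seq.joint_index("right_shoulder")
        seq.joints[0, ls, :2] = (-2.0, 0.0)
        seq.joints[0, rs, :2] = (2.0, 0.0)
        out = select_upper_body(seq)
        np.testing.assert_allclose(out.joints[0, out.joint_index("neck"), :2], 0.0)

    def test_neck_confidence_is_min_of_shoulders(self):
        seq = coco_sequence(1)
        seq.joints[0, seq.joint_index("left_shoulder"), 2] = 0.8
        seq.joints[0, seq.joint_index("right_shoulder"), 2] = 0.6
        out = select_upper_body(seq)
        assert out.joints[0, out.joint_index("neck"), 2] == pytest.approx(0.6)

    def test_missing_shoulders_is_schema_error(self):
        seq = coco_sequence(1)
        names = tuple(n for n in COCO_KEYPOINTS if "shoulder" not in n)
        idx = [COCO_KEYPOINTS.index(n) for n in names]
        broken = PoseSequence(joints=seq.joints[:, idx], joint_names=names, fps=30)
        with pytest.raises(PoseSchemaError):
            select_upper_body(broken)

    def test_low_confidence_joint_hides_frame(self):
        seq = coco_sequence(2)
        seq.joints[1, seq.joint_index("left_wrist"), 2] = 0.01
        out = select_upper_body(seq)
        assert list(out.visible) == [True, False]


class TestNormalizePose:
    def _nine(self):
        return select_upper_body(coco_sequence(1))

    def test_worked_example(self):
        seq = self._nine()
        seq.joints[0, :, :2] = 50.0  # arbitrary fill
        seq.joints[0, seq.joint_index("neck"), :2] = (0.0, 0.0)
        seq.joints[0, seq.joint_index("left_hip"), :2] = (-1.0, 2.0)
        seq.joints[0, seq.joint_index("right_hip"), :2] = (1.0, 2.0)
        seq.joints[0, seq.joint_index("left_wrist"), :2] = (2.0, 2.0)
        out = normalize_pose(seq)
        np.testing.assert_allclose(
            out.joints[0, out.joint_index("left_wrist"), :2], (2.0, 2.0 - 4.0 / 3.0))

    @given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
    def test_translation_invariance(self, dx, dy):
        seq = self._nine()
        shifted = PoseSequence(joints=seq.joints.copy(), joint_names=seq.joint_names,
                               fps=seq.fps)
        shifted.joints[:, :, 0] += dx
        shifted.joints[:, :, 1] += dy
        a = normalize_pose(seq).joints[:, :, :2]
        b = normalize_pose(shifted).joints[:, :, :2]
        np.testing.assert_allclose(a, b, atol=1e-9 * max(1.0, abs(dx), abs(dy)))

    def test_already_centered_is_identity(self):
        seq = self._nine()
        out1 = normalize_pose(seq)
        out2 = normalize_pose(out1)
        np.testing.assert_allclose(out1.joints, out2.joints, atol=1e-12)

    def test_zero_confidence_anchor_flags_frame(self):
        seq = self._nine()
        seq.joints[0, seq.joint_index("left_hip"), 2] = 0.0
        out = normalize_pose(seq)
        assert not out.visible[0]

    def test_confidences_unchanged(self):
        seq = self._nine()
        out = normalize_pose(seq)
        np.testing.assert_array_equal(out.joints[:, :, 2], seq.joints[:, :, 2])


def test_scale_by_torso_normalizes_torso_to_unit_length():
    seq = normalize_pose(select_upper_body(coco_sequence(4)))
    out = scale_by_torso(seq)
    neck = out.joints[:, out.joint_index("neck"), :2]
    hips = 0.5 * (out.joints[:, out.joint_index("left_hip"), :2]
                  + out.joints[:, out.joint_index("right_hip"), :2])
    torso = np.median(np.linalg.norm(neck - hips, axis=1))
    assert torso == pytest.approx(1.0)


class TestClipWindows:
    def _seq(self, visible):
        n = len(visible)
        joints = np.zeros((n, 9, 3))
        joints[:, :, 2] = 1.0
        from spa_pta.skeleton_graph import UPPER_BODY_JOINTS

        return PoseSequence(joints=joints, joint_names=UPPER_BODY_JOINTS, fps=30,
                            visible=np.asarray(visible, bool))

    @pytest.mark.parametrize("n_visible,expected", [(250, 2), (99, 0), (100, 1)])
    def test_contiguous_runs(self, n_visible, expected):
        wins = clip_windows(self._seq([True] * n_visible), label=0)
        assert len(wins) == expected
        for w in wins:
            assert w.features.shape == (100, 9, 3)

    def test_gap_splits_runs(self):
        visible = [True] * 120 + [False] + [True] * 130
        wins = clip_windows(self._seq(visible), label=1)
        assert len(wins) == 2
        assert all(w.label == 1 for w in wins)

    @given(st.lists(st.booleans(), min_size=0, max_size=400))
    def test_count_matches_per_run_floor_division(self, visible):
        wins = clip_windows(self._seq(visible), label=0, window=100)
        # brute-force oracle: walk runs and count floor(len/100)
        expected, run = 0, 0
        for v in visible + [False]:
            if v:
                run += 1
            else:
                expected += run // 100
                run = 0
        assert len(wins) == expected

    def test_runs_helper(self):
        assert visible_runs(np.array([0, 1, 1, 0, 1], bool)) == [(1, 3), (4, 5)]

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            clip_windows(self._seq([True] * 10), label=0, window=0)


class TestLabels:
    @pytest.mark.parametrize("l,r,expected", [(2, 3, 3), (0, 0, 0), (7, 1, 7)])
    def test_combine_hand_labels(self, l, r, expected):
        assert combine_hand_labels(l, r) == expected

    @given(st.integers(0, 7), st.integers(0, 7))
    def test_combine_symmetric_idempotent(self, a, b):
        assert combine_hand_labels(a, b) == combine_hand_labels(b, a)
        assert combine_hand_labels(a, a) == a

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValueError):
            combine_hand_labels(8, 0)

    @pytest.mark.parametrize("rating,mode,expected", [
        (5, "rating-123plus", "3+"),
        (3, "rating-123", "3"),
        (0, "rating-123", None),
        (0, "rating-123plus", None),
        (4, "rating-123", None),
        (3, "rating-123plus", "3+"),
        (2, "rating-123plus", "2"),
    ])
    def test_map_rating_label(self, rating, mode, expected):
        assert map_rating_label(rating, mode) == expected

    @pytest.mark.parametrize("t,mode,expected", [
        ("PT", "type-binary", "PT"),
        ("ET", "type-binary", "non-PT"),
        ("NT", "type-binary", "non-PT"),
        ("Other", "type-binary", None),
        ("Other", "type-multiclass", None),
        ("DT", "type-multiclass", "DT"),
    ])
    def test_map_type_label(self, t, mode, expected):
        assert map_type_label(t, mode) == expected
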