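"""Pose ingestion and preprocessing.

Consumes per-frame COCO-17 keypoints (x, y, confidence) as produced by
pose estimators such as AlphaPose/OpenPose, restricts them to the
upper-body joint set, re-expresses coordinates relative to a body-centric
origin (mean of neck and both hips) and cuts fixed-length labeled windows
from maximal runs of visible frames.

Coordinates are image pixels: x to the right, y down, origin at the
top-left of the frame.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .skeleton_graph import UPPER_BODY_JOINTS

COCO_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: default confidence below which a joint (and hence its frame) counts as
#: unreliable / occluded
DEFAULT_VISIBILITY_THRESHOLD = 0.05

DEFAULT_WINDOW = 100

TREMOR_TYPES = ("PT", "ET", "DT", "FT", "NT", "Other")

RATING_MIN, RATING_MAX = 0, 7


class PoseParseError(ValueError):
    pass


class PoseSchemaError(ValueError):
    pass


@dataclass
class PoseSequence:
    """Time-indexed 2D keypoints with confidences.

    ``joints`` has shape (n_frames, n_keypoints, 3) holding (x, y, c);
    ``visible`` flags frames in which the subject was detected and every
    retained joint is trustworthy.
    """

    joints: np.ndarray
    joint_names: tuple[str, ...]
    fps: float
    subject_id: str = ""
    video_id: str = ""
    task_id: str = ""
    visible: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=float)
        if self.joints.ndim != 3 or self.joints.shape[2] != 3:
            raise ValueError("joints must have shape (frames, keypoints, 3)")
        if self.joints.shape[1] != len(self.joint_names):
            raise ValueError("joint_names length must match keypoint axis")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        c = self.joints[:, :, 2]
        if c.size and (np.nanmin(c) < 0 or np.nanmax(c) > 1):
            raise ValueError("confidences must lie in [0, 1]")
        if self.visible is None:
            self.visible = np.ones(self.joints.shape[0], dtype=bool)
        else:
            self.visible = np.asarray(self.visible, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.joints.shape[0]

    def joint_index(self, name: str) -> int:
        return self.joint_names.index(name)

    def trajectory(self, name: str) -> np.ndarray:
        """(x, y) positions of one joint over time, shape (frames, 2)."""
        return self.joints[:, self.joint_index(name), :2]


@dataclass(frozen=True)
class SampleWindow:
    """Fixed-length labeled subclip — the network's training/inference unit."""

    features: np.ndarray  # (window, joints, 3)
    label: int
    subject_id: str
    video_id: str
    window_index: int


@dataclass(frozen=True)
class LabelSpace:
    """Task label space: tremor-type (binary/multiclass) or rating levels."""

    mode: str
    classes: tuple[str, ...]

    MODES = ("type-binary", "type-multiclass", "rating-123", "rating-123plus")

    @classmethod
    def from_mode(cls, mode: str) -> "LabelSpace":
        table = {
            "type-binary": ("PT", "non-PT"),
            "type-multiclass": ("PT", "ET", "DT", "FT", "NT"),
            "rating-123": ("1", "2", "3"),
            "rating-123plus": ("1", "2", "3+"),
        }
        if mode not in table:
            raise ValueError(f"unknown label mode {mode!r}; choose from {cls.MODES}")
        return cls(mode=mode, classes=table[mode])

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def index(self, name: str) -> int:
        return self.classes.index(name)


def _frame_key(record: dict) -> object:
    key = record.get("image_id", record.get("frame_id"))
    if key is None:
        raise PoseParseError(f"record lacks image_id/frame_id: {record!r}")
    return key


def _frame_order(key: object) -> tuple:
    # numeric sort where possible ("frame_10.png" after "frame_2.png")
    digits = re.findall(r"\d+", str(key))
    return (int(digits[-1]),) if digits else (str(key),)


def parse_pose_stream(source: str | Path | Iterable[dict], fps: float = 30.0,
                      subject_id: str = "", video_id: str = "",
                      task_id: str = "") -> PoseSequence:
    """Parse pose-estimator JSON into a :class:`PoseSequence`.

    The accepted schema is a list of per-detection records, each with an
    ``image_id`` (or ``frame_id``), a flat ``keypoints`` list of
    17 x (x, y, c) floats and a detection ``score``.  When a frame holds
    several detections the highest-score one is kept; frames present in the
    file but with no detection (empty ``keypoints``) are marked not-visible.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            records = json.load(fh)
    else:
        records = list(source)
    if not records:
        raise PoseParseError("pose stream holds zero frames")

    best: dict[object, dict] = {}
    for rec in records:
        key = _frame_key(rec)
        score = float(rec.get("score", 0.0))
        if key not in best or score > float(best[key].get("score", 0.0)):
            best[key] = rec

    keys = sorted(best, key=_frame_order)
    n = len(keys)
    joints = np.zeros((n, len(COCO_KEYPOINTS), 3))
    visible = np.ones(n, dtype=bool)
    for t, key in enumerate(keys):
        kp = best[key].get("keypoints") or []
        if not kp:
            visible[t] = False
            continue
        arr = np.asarray(kp, dtype=float)
        if arr.size != len(COCO_KEYPOINTS) * 3:
            raise PoseParseError(
                f"frame {key!r}: expected {len(COCO_KEYPOINTS) * 3} keypoint "
                f"floats, got {arr.size}"
            )
        joints[t] = arr.reshape(len(COCO_KEYPOINTS), 3)
    joints[:, :, 2] = np.clip(joints[:, :, 2], 0.0, 1.0)
    return PoseSequence(joints=joints, joint_names=COCO_KEYPOINTS, fps=fps,
                        subject_id=subject_id, video_id=video_id,
                        task_id=task_id, visible=visible)


def select_upper_body(seq: PoseSequence,
                      visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
                      ) -> PoseSequence:
    """Restrict to the 9 upper-body joints, synthesizing the neck.

    COCO-17 carries no neck keypoint; it is synthesized as the shoulder
    midpoint with confidence equal to the smaller shoulder confidence
    (the convention pose estimators with an explicit neck use).  Head/face
    and leg joints are dropped.  Frame visibility is re-evaluated: a frame
    is visible iff it was visible before and every retained joint has
    confidence >= ``visibility_threshold``.
    """
    try:
        ls = seq.joint_index("left_shoulder")
        rs = seq.joint_index("right_shoulder")
    except ValueError as exc:
        raise PoseSchemaError("shoulder keypoints required to synthesize the neck") from exc

    neck = np.empty((seq.n_frames, 1, 3))
    neck[:, 0, :2] = 0.5 * (seq.joints[:, ls, :2] + seq.joints[:, rs, :2])
    neck[:, 0, 2] = np.minimum(seq.joints[:, ls, 2], seq.joints[:, rs, 2])

    cols = []
    for name in UPPER_BODY_JOINTS:
        if name == "neck":
            cols.append(neck)
        else:
            try:
                cols.append(seq.joints[:, [seq.joint_index(name)], :])
            except ValueError as exc:
                raise PoseSchemaError(f"keypoint {name!r} missing from input") from exc
    joints = np.concatenate(cols, axis=1)
    visible = seq.visible & (joints[:, :, 2] >= visibility_threshold).all(axis=1)
    return replace(seq, joints=joints, joint_names=UPPER_BODY_JOINTS, visible=visible)


def normalize_pose(seq: PoseSequence) -> PoseSequence:
    """Express coordinates relative to the mean of neck and both hips.

    The per-frame origin is the mean position of the neck and the two hip
    joints; subtracting it removes global translation.  Confidences are
    untouched.  Frames where any origin joint has zero confidence cannot be
    normalized and are flagged not-visible instead.
    """
    anchors = [seq.joint_index(n) for n in ("neck", "left_hip", "right_hip")]
    joints = seq.joints.copy()
    bad = (joints[:, anchors, 2] <= 0.0).any(axis=1)
    origin = joints[:, anchors, :2].mean(axis=1, keepdims=True)
    ok = ~bad
    joints[ok, :, :2] = joints[ok, :, :2] - origin[ok]
    return replace(seq, joints=joints, visible=seq.visible & ok)


def scale_by_torso(seq: PoseSequence) -> PoseSequence:
    """Opt-in scale normalization: divide coordinates by the torso length.

    Torso length is the median over frames of the distance from the neck to
    the hip midpoint; dividing by it removes inter-subject body-size and
    camera-distance variation.  Apply after :func:`normalize_pose`.
    """
    neck = seq.joints[:, seq.joint_index("neck"), :2]
    hips = 0.5 * (seq.joints[:, seq.joint_index("left_hip"), :2]
                  + seq.joints[:, seq.joint_index("right_hip"), :2])
    torso = float(np.median(np.linalg.norm(neck - hips, axis=1)))
    if torso <= 0:
        raise ValueError("degenerate pose: zero torso length")
    joints = seq.joints.copy()
    joints[:, :, :2] /= torso
    return replace(seq, joints=joints)


def visible_runs(visible: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive visible frames as (start, stop) pairs."""
    runs: list[tuple[int, int]] = []
    start = None
    for t, v in enumerate(visible):
        if v and start is None:
            start = t
        elif not v and start is not None:
            runs.append((start, t))
            start = None
    if start is not None:
        runs.append((start, len(visible)))
    return runs


def clip_windows(seq: PoseSequence, label: int, window: int = DEFAULT_WINDOW,
                 ) -> list[SampleWindow]:
    """Cut non-overlapping ``window``-frame samples from visible runs.

    Windows are left-aligned within each maximal run of visible frames;
    the remainder shorter than ``window`` is discarded.  Every window
    inherits the video-level ``label``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out: list[SampleWindow] = []
    for start, stop in visible_runs(seq.visible):
        for k in range((stop - start) // window):
            lo = start + k * window
            out.append(SampleWindow(
                features=seq.joints[lo:lo + window].copy(),
                label=label,
                subject_id=seq.subject_id,
                video_id=seq.video_id,
                window_index=len(out),
            ))
    return out


def combine_hand_labels(left_rating: int, right_rating: int) -> int:
    """Video-level severity rating = max of the two per-hand ratings."""
    for r in (left_rating, right_rating):
        if not (RATING_MIN <= r <= RATING_MAX):
            raise ValueError(f"rating {r} outside [{RATING_MIN}, {RATING_MAX}]")
    return max(left_rating, right_rating)


def map_rating_label(rating: int, mode: str) -> str | None:
    """Map a 0-7 severity rating onto a rating label space, or exclude.

    ``rating-123`` keeps levels 1, 2, 3 only; ``rating-123plus`` groups all
    levels >= 3 into "3+" and keeps 1 and 2.  Level 0 (and, for rating-123,
    levels above 3) are excluded (returns None).
    """
    if mode not in ("rating-123", "rating-123plus"):
        raise ValueError(f"unknown rating mode {mode!r}")
    if rating <= 0:
        return None
    if mode == "rating-123":
        return str(rating) if rating <= 3 else None
    return str(rating) if rating < 3 else "3+"


def map_type_label(tremor_type: str, mode: str) -> str | None:
    """Map a tremor-type label onto a type label space, or exclude.

    Binary mode is PT vs non-PT ({ET, DT, FT, NT}); videos labeled "Other"
    (inconclusive type) are excluded from both type tasks.
    """
    if tremor_type not in TREMOR_TYPES:
        raise ValueError(f"unknown tremor type {tremor_type!r}")
    if tremor_type == "Other":
        return None
    if mode == "type-binary":
        return "PT" if tremor_type == "PT" else "non-PT"
    if mode == "type-multiclass":
        return tremor_type
    raise ValueError(f"unknown type mode {mode!r}")


def windows_to_arrays(windows: Sequence[SampleWindow]) -> tuple[np.ndarray, "pd.DataFrame"]:
    """Stack windows into (N, T, V, 3) features plus a manifest table."""
    import pandas as pd

    x = np.stack([w.features for w in windows]) if windows else np.empty((0, 0, 0, 3))
    manifest = pd.DataFrame({
        "subject_id": [w.subject_id for w in windows],
        "video_id": [w.video_id for w in windows],
        "window_index": [w.window_index for w in windows],
        "label": [w.label for w in windows],
    })
    return x, manifest


def video_class(tremor_type: str, left_rating: int, right_rating: int,
                mode: str) -> str | None:
    """Video-level class name under ``mode``, or None if excluded."""
    if mode.startswith("type-"):
        return map_type_label(tremor_type, mode)
    return map_rating_label(combine_hand_labels(left_rating, right_rating), mode)


def prepare_dataset(items: Sequence[tuple[PoseSequence, object]], mode: str,
                    window: int = DEFAULT_WINDOW,
                    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
                    torso_scale: bool = False,
                    motion_magnify: "BandSpec | None" = None,
                    ) -> tuple[np.ndarray, "pd.DataFrame", LabelSpace]:
    """Run the full preprocessing chain on (sequence, labels) pairs.

    ``labels`` objects expose tremor_type, left_rating and right_rating
    attributes.  Each COCO-17 sequence is restricted to the upper body,
    origin-normalized and cut into windows; videos excluded by the label
    mode (e.g. "Other" types, rating 0) are dropped.  Returns stacked
    window features, the manifest and the label space.

    ``motion_magnify`` applies pose-domain motion magnification first —
    the trajectory-level equivalent of running the video through Eulerian
    magnification before pose extraction, which is how the full video
    pipeline enhances subtle tremor.
    """
    space = LabelSpace.from_mode(mode)
    windows: list[SampleWindow] = []
    for seq, labels in items:
        cls = video_class(labels.tremor_type, labels.left_rating,
                          labels.right_rating, mode)
        if cls is None:
            continue
        if motion_magnify is not None:
            from .evm import magnify_trajectories

            seq = replace(seq, joints=magnify_trajectories(
                seq.joints, seq.fps, motion_magnify))
        seq9 = normalize_pose(select_upper_body(seq, visibility_threshold))
        if torso_scale:
            seq9 = scale_by_torso(seq9)
        windows.extend(clip_windows(seq9, space.index(cls), window))
    x, manifest = windows_to_arrays(windows)
    return x, manifest, space


def load_pose_dataset(root: str | Path) -> list[tuple[PoseSequence, object]]:
    """Load a dataset directory (poses/*.json + labels.csv) from disk."""
    from types import SimpleNamespace

    import pandas as pd

    root = Path(root)
    labels = pd.read_csv(root / "labels.csv")
    items: list[tuple[PoseSequence, object]] = []
    for row in labels.itertuples():
        seq = parse_pose_stream(root / "poses" / f"{row.video_id}.json",
                                fps=float(row.fps), subject_id=str(row.subject_id),
                                video_id=str(row.video_id),
                                task_id=str(getattr(row, "task_id", "")))
        items.append((seq, SimpleNamespace(
            tremor_type=str(row.tremor_type),
            left_rating=int(row.left_rating),
            right_rating=int(row.right_rating))))
    return items
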