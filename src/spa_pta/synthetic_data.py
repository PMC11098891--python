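"""Synthetic tremor pose sequences and test videos.

Emulates what the classification pipeline assumes about its input: a seated
subject filmed front-on, pose-estimated to COCO-17 keypoints at 30 fps,
with band-limited (3-7 Hz) oscillatory wrist/arm motion whose laterality
depends on the tremor class (Parkinsonian tremor is typically unilateral,
essential tremor bilateral), amplitude grows with the clinical severity
rating, and keypoint jitter plus occasional occlusion gaps mimic estimator
noise.  The non-Parkinsonian classes get distinct kinematic signatures so
the multiclass code paths are exercisable; they are fixtures, not clinical
models.

Everything is driven by a single seed and is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evm import VideoClip, check_nyquist
from .pose_features import COCO_KEYPOINTS, PoseSequence

#: neutral seated pose in image pixels (x right, y down, 640x480 frame)
TEMPLATE_POSE: dict[str, tuple[float, float]] = {
    "nose": (320, 100),
    "left_eye": (332, 92), "right_eye": (308, 92),
    "left_ear": (348, 97), "right_ear": (292, 97),
    "left_shoulder": (375, 160), "right_shoulder": (265, 160),
    "left_elbow": (395, 230), "right_elbow": (245, 230),
    "left_wrist": (405, 295), "right_wrist": (235, 295),
    "left_hip": (355, 330), "right_hip": (285, 330),
    "left_knee": (360, 420), "right_knee": (280, 420),
    "left_ankle": (365, 470), "right_ankle": (275, 470),
}

#: severity rating -> wrist oscillation amplitude in pixels (monotone)
DEFAULT_AMPLITUDE_BY_SEVERITY: dict[int, float] = {1: 2.0, 2: 5.0, 3: 10.0, 4: 16.0}

#: fraction of the wrist displacement transferred to the elbow
ELBOW_COUPLING = 0.4

LATERALITY = {"PT": "unilateral", "ET": "bilateral", "DT": "unilateral",
              "FT": "unilateral", "NT": "none"}


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Cohort-level generation settings."""

    n_subjects: int = 30
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"PT": 0.5, "NT": 0.5})
    fps: float = 30.0
    duration: float = 20.0  # seconds per video
    videos_per_subject: int = 1
    tremor_freq_range: tuple[float, float] = (3.0, 7.0)
    amplitude_by_severity: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDE_BY_SEVERITY))
    severity_levels: tuple[int, ...] = (1, 2, 3)
    jitter_sd: float = 1.0  # px, keypoint-estimator noise
    occlusion_rate: float = 0.005  # per-frame probability of an occlusion gap
    occlusion_exit: float = 0.2  # per-frame probability a gap ends
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0):
            raise SyntheticSpecError(f"class mix must sum to 1 (got {total})")
        amps = [self.amplitude_by_severity[s]
                for s in sorted(self.amplitude_by_severity)]
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise SyntheticSpecError("amplitudes must strictly increase with severity")
        ok, msg = check_nyquist(self.fps, self.tremor_freq_range[1])
        if not ok:
            raise SyntheticSpecError(msg)


@dataclass(frozen=True)
class VideoLabels:
    """Ground truth attached to one generated video."""

    tremor_type: str
    left_rating: int
    right_rating: int
    tremor_freq: float | None = None
    affected_side: str | None = None  # "left" | "right" | "both" | None


def _amplitude(spec: SyntheticSpec, rating: int) -> float:
    keys = sorted(spec.amplitude_by_severity)
    key = min(max(rating, keys[0]), keys[-1])
    return spec.amplitude_by_severity[key]


def _tremor_displacement(rng: np.random.Generator, t: np.ndarray, kind: str,
                         freq: float, amp: float) -> np.ndarray:
    """(frames, 2) wrist displacement for one affected arm."""
    phase = rng.uniform(0, 2 * np.pi)
    if kind in ("PT", "ET"):
        arg = 2 * np.pi * freq * t + phase
        return np.stack([amp * np.sin(arg),
                         0.3 * amp * np.sin(arg + rng.uniform(0, 2 * np.pi))], axis=1)
    if kind == "DT":
        # slower, irregular: random-walk phase jitter plus postural drift
        jitter = np.cumsum(rng.normal(0, 0.25, t.size))
        arg = 2 * np.pi * freq * t + phase + jitter
        drift = 0.5 * amp * np.sin(2 * np.pi * 0.15 * t + rng.uniform(0, 2 * np.pi))
        return np.stack([amp * np.sin(arg) + drift, 0.3 * amp * np.cos(arg)], axis=1)
    if kind == "FT":
        # intermittent bursts: on/off envelope with ~1.5 s segments
        env = np.zeros(t.size)
        on = rng.random() < 0.5
        i = 0
        while i < t.size:
            seg = max(1, int(rng.exponential(1.5) * (t.size / max(t[-1], 1e-9))))
            if on:
                env[i:i + seg] = 1.0
            on = not on
            i += seg
        arg = 2 * np.pi * freq * t + phase
        return np.stack([amp * env * np.sin(arg), 0.3 * amp * env * np.cos(arg)], axis=1)
    raise ValueError(f"no tremor signature for class {kind!r}")


def generate_subject(spec: SyntheticSpec, subject_id: str, seed: int,
                     tremor_type: str | None = None,
                     ) -> tuple[PoseSequence, VideoLabels]:
    """Generate one subject's pose sequence plus its ground-truth labels.

    The subject sits still (template pose with per-subject limb-length and
    position variation); the affected wrist(s) oscillate at a frequency
    drawn from the spec's band, with the elbow co-displaced at 40% of the
    wrist amplitude.  Gaussian jitter on every joint and Markov occlusion
    gaps (all confidences dropping near zero) emulate pose-estimator noise.
    """
    rng = np.random.default_rng(seed)
    classes = sorted(spec.class_mix)
    if tremor_type is None:
        probs = np.array([spec.class_mix[c] for c in classes])
        tremor_type = classes[rng.choice(len(classes), p=probs)]
    if tremor_type not in LATERALITY:
        raise SyntheticSpecError(f"unknown class {tremor_type!r}")

    n = int(round(spec.duration * spec.fps))
    t = np.arange(n) / spec.fps

    # subject-level nuisance variation: limb scale and global placement
    scale = rng.uniform(0.9, 1.1)
    offset = rng.uniform(-40, 40, size=2)
    anchor = np.array([320.0, 160.0])  # shoulder midpoint of the template
    base = {}
    for name, xy in TEMPLATE_POSE.items():
        base[name] = anchor + scale * (np.asarray(xy, float) - anchor) + offset

    pos = np.tile(
        np.stack([base[name] for name in COCO_KEYPOINTS]), (n, 1, 1))

    laterality = LATERALITY[tremor_type]
    sides: list[str] = []
    if laterality == "unilateral":
        sides = [rng.choice(["left", "right"])]
    elif laterality == "bilateral":
        sides = ["left", "right"]

    ratings = {"left": 0, "right": 0}
    freq = None
    if sides:
        lo, hi = spec.tremor_freq_range
        if tremor_type == "DT":
            lo, hi = 2.0, 4.0
        freq = float(rng.uniform(lo, hi))
        ok, msg = check_nyquist(spec.fps, freq)
        if not ok:
            raise SyntheticSpecError(msg)
        for side in sides:
            rating = int(rng.choice(spec.severity_levels))
            ratings[side] = rating
            disp = _tremor_displacement(rng, t, tremor_type, freq,
                                        _amplitude(spec, rating))
            wi = COCO_KEYPOINTS.index(f"{side}_wrist")
            ei = COCO_KEYPOINTS.index(f"{side}_elbow")
            pos[:, wi, :] += disp
            pos[:, ei, :] += ELBOW_COUPLING * disp

    if spec.jitter_sd > 0:
        pos += rng.normal(0, spec.jitter_sd, size=pos.shape)

    conf = np.clip(rng.normal(0.95, 0.02, size=(n, len(COCO_KEYPOINTS))), 0.0, 1.0)
    occluded = np.zeros(n, dtype=bool)
    state = False
    for i in range(n):
        state = (rng.random() >= spec.occlusion_exit) if state \
            else (rng.random() < spec.occlusion_rate)
        occluded[i] = state
    conf[occluded] = rng.uniform(0.0, 0.04, size=(occluded.sum(), len(COCO_KEYPOINTS)))

    joints = np.concatenate([pos, conf[:, :, None]], axis=2)
    seq = PoseSequence(joints=joints, joint_names=COCO_KEYPOINTS, fps=spec.fps,
                       subject_id=subject_id, video_id=f"{subject_id}_v0",
                       task_id="rest")
    affected = {"unilateral": sides[0] if sides else None,
                "bilateral": "both", "none": None}[laterality]
    labels = VideoLabels(tremor_type=tremor_type, left_rating=ratings["left"],
                         right_rating=ratings["right"], tremor_freq=freq,
                         affected_side=affected)
    return seq, labels


def generate_dataset(spec: SyntheticSpec,
                     ) -> list[tuple[PoseSequence, VideoLabels]]:
    """Generate the full cohort (``n_subjects`` x ``videos_per_subject``).

    Subject class assignment follows ``class_mix``; every video of a
    subject shares the subject's tremor class (labels are per video, as in
    clinical recordings).  Fully determined by ``spec.seed``.
    """
    if spec.n_subjects < 2:
        raise SyntheticSpecError("need at least 2 subjects")
    root = np.random.default_rng(spec.seed)
    classes = sorted(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in classes])
    out = []
    for s in range(spec.n_subjects):
        subject_id = f"S{s:03d}"
        cls = classes[root.choice(len(classes), p=probs)]
        for v in range(spec.videos_per_subject):
            seed = int(root.integers(0, 2**31 - 1))
            seq, labels = generate_subject(spec, subject_id, seed, tremor_type=cls)
            seq = replace(seq, video_id=f"{subject_id}_v{v}")
            out.append((seq, labels))
    return out


def generate_stratified(spec: SyntheticSpec, counts: dict[str, int],
                        ) -> list[tuple[PoseSequence, VideoLabels]]:
    """Generate exactly ``counts[cls]`` subjects per class (deterministic)."""
    for cls, k in counts.items():
        if k > 0 and spec.class_mix.get(cls, 0.0) <= 0:
            raise SyntheticSpecError(
                f"class {cls!r} requested but has zero probability in the spec")
    root = np.random.default_rng(spec.seed)
    out = []
    s = 0
    for cls in sorted(counts):
        for _ in range(counts[cls]):
            subject_id = f"S{s:03d}"
            for v in range(spec.videos_per_subject):
                seed = int(root.integers(0, 2**31 - 1))
                seq, labels = generate_subject(spec, subject_id, seed, tremor_type=cls)
                seq = replace(seq, video_id=f"{subject_id}_v{v}")
                out.append((seq, labels))
            s += 1
    return out


# ---------------------------------------------------------------------------
# disk round trip: the same pose-JSON schema pose_features.parse_pose_stream
# reads, plus a labels CSV


def write_dataset(dataset: list[tuple[PoseSequence, VideoLabels]],
                  out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    (out_dir / "poses").mkdir(parents=True, exist_ok=True)
    rows = []
    for seq, labels in dataset:
        records = []
        for f in range(seq.n_frames):
            records.append({
                "image_id": f"{f:06d}.jpg",
                "score": 2.0,
                "keypoints": np.round(seq.joints[f].ravel(), 3).tolist(),
            })
        (out_dir / "poses" / f"{seq.video_id}.json").write_text(json.dumps(records))
        rows.append({
            "video_id": seq.video_id, "subject_id": seq.subject_id,
            "task_id": seq.task_id, "fps": seq.fps,
            "tremor_type": labels.tremor_type,
            "left_rating": labels.left_rating,
            "right_rating": labels.right_rating,
            "tremor_freq": labels.tremor_freq if labels.tremor_freq is not None else "",
            "affected_side": labels.affected_side or "",
        })
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)
    return out_dir


# ---------------------------------------------------------------------------
# oscillating-dot videos for testing the motion-magnification stage


def generate_synthetic_video(dot_freq: float, dot_amp: float, fps: float = 30.0,
                             duration: float = 10.0, size: int = 128,
                             sigma: float = 12.0, background: float = 0.35,
                             peak: float = 0.9,
                             ) -> tuple[VideoClip, np.ndarray]:
    """Gaussian blob oscillating horizontally on a dark background.

    Returns the clip together with the analytic ground-truth x-trajectory
    of the blob center (pixels, one value per frame).
    """
    ok, msg = check_nyquist(fps, dot_freq)
    if not ok:
        raise ValueError(msg)
    if dot_amp >= size / 4:
        raise ValueError(f"amplitude {dot_amp} px too large for a {size} px frame")
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    traj = dot_amp * np.sin(2 * np.pi * dot_freq * t)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx, cy = size / 2, size / 2
    frames = np.empty((n, size, size))
    for k in range(n):
        frames[k] = background + (peak - background) * np.exp(
            -(((xx - cx - traj[k]) ** 2) + (yy - cy) ** 2) / (2 * sigma ** 2))
    return VideoClip(frames=frames, fps=fps), traj


def track_dot(clip: VideoClip, background: float | None = None) -> np.ndarray:
    """Brightness-weighted centroid x-position per frame.

    The flat background level (default: spatial median of the first frame)
    is subtracted first; the centroid uses the signed residual, so the
    estimate is the exact first moment of the blob and stays linear even
    when magnification distorts the blob shape.
    """
    frames = clip.frames if not clip.is_color else clip.frames.mean(axis=3)
    if background is None:
        background = float(np.median(frames[0]))
    xs = np.arange(frames.shape[2])
    w = frames - background
    mass = w.sum(axis=(1, 2))
    return (w.sum(axis=1) * xs).sum(axis=1) / np.where(np.abs(mass) < 1e-12, 1e-12, mass)


def oscillation_amplitude(series: np.ndarray, fps: float,
                          trim: float = 1.0) -> float:
    """Sinusoid amplitude estimate of a 1-D series: sqrt(2) x RMS.

    ``trim`` seconds are dropped from each end so temporal-filter edge
    effects do not bias the estimate.  Exact for a pure sinusoid spanning
    whole periods.
    """
    series = np.asarray(series, float)
    k = int(round(trim * fps))
    if series.size > 2 * k + 8:
        series = series[k:series.size - k]
    series = series - series.mean()
    return float(np.sqrt(2.0) * series.std())
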