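"""Subject-wise leave-one-out evaluation with subclip voting.

Clinical tremor datasets are small and identity leakage is the main threat
to validity, so evaluation is individual-based leave-one-out
cross-validation (LOOCV): each fold holds out every window of one subject,
trains on everyone else, predicts the held-out windows, aggregates them to
video-level labels by majority voting and scores accuracy, sensitivity,
specificity and F1 (macro-averaged one-vs-rest for multiclass).  Reported
summary values are the unweighted means over folds plus pooled video-level
metrics over all held-out videos.

Also provides the spectral wrist-tremor frequency estimator used to sanity
check pose quality (a reliable pose stream should reproduce the tremor
frequency to within a fraction of a Hz).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .pose_features import LabelSpace
from .skeleton_graph import SkeletonGraph, build_graph
from .spa_model import SPAPTA, AttentionMap, ModelConfig


@dataclass(frozen=True)
class FoldPlan:
    """Leave-one-subject-out folds: (test subject, train subjects) pairs."""

    folds: tuple[tuple[str, tuple[str, ...]], ...]
    mode: str = ""

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_folds(manifest: pd.DataFrame, mode: str = "") -> FoldPlan:
    """One fold per distinct subject; training set = all other subjects."""
    subjects = tuple(sorted(manifest["subject_id"].unique()))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least two subjects")
    folds = tuple(
        (s, tuple(o for o in subjects if o != s)) for s in subjects
    )
    return FoldPlan(folds=folds, mode=mode)


def vote(window_labels: np.ndarray, window_probs: np.ndarray) -> int:
    """Video-level label: majority over windows, ties by mean probability.

    ``window_labels`` are per-window predicted class indices;
    ``window_probs`` the matching (n_windows, n_classes) probabilities.
    """
    window_labels = np.asarray(window_labels, dtype=int)
    if window_labels.size == 0:
        raise ValueError("vote needs at least one window prediction")
    window_probs = np.asarray(window_probs, dtype=float)
    counts = np.bincount(window_labels, minlength=window_probs.shape[1])
    best = np.flatnonzero(counts == counts.max())
    if best.size == 1:
        return int(best[0])
    mean_probs = window_probs.mean(axis=0)
    return int(best[np.argmax(mean_probs[best])])


@dataclass
class MetricsReport:
    """Classification metrics, all expressed as percentages."""

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    confusion: np.ndarray = field(repr=False)
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    n_videos: int = 0

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "f1": self.f1,
                "n_videos": self.n_videos}


def _prf(tp: float, fp: float, fn: float, tn: float) -> tuple[float, float, float]:
    se = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    sp = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    f1 = 100.0 * 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return se, sp, f1


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    space: LabelSpace) -> MetricsReport:
    """Accuracy, SE, SP and F1 from aligned video-level labels.

    Binary mode treats PT (class index 0) as the positive class; multiclass
    modes compute one-vs-rest SE/SP/F1 per class and macro-average them.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("predictions and labels must be aligned")
    k = space.n_classes
    if y_true.size and (min(y_true.min(), y_pred.min()) < 0
                        or max(y_true.max(), y_pred.max()) >= k):
        raise ValueError("label outside the configured label space")
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (y_true, y_pred), 1)
    n = int(confusion.sum())
    accuracy = 100.0 * np.trace(confusion) / n if n else float("nan")

    per_class: dict[str, dict[str, float]] = {}
    for c, name in enumerate(space.classes):
        tp = confusion[c, c]
        fn = confusion[c].sum() - tp
        fp = confusion[:, c].sum() - tp
        tn = n - tp - fn - fp
        se, sp, f1 = _prf(tp, fp, fn, tn)
        per_class[name] = {"sensitivity": se, "specificity": sp, "f1": f1}

    if k == 2:
        pos = space.classes[0]  # PT is listed first in the binary space
        se = per_class[pos]["sensitivity"]
        sp = per_class[pos]["specificity"]
        f1 = per_class[pos]["f1"]
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            se = float(np.nanmean([v["sensitivity"] for v in per_class.values()]))
            sp = float(np.nanmean([v["specificity"] for v in per_class.values()]))
            f1 = float(np.nanmean([v["f1"] for v in per_class.values()]))
    return MetricsReport(accuracy=accuracy, sensitivity=se, specificity=sp,
                         f1=f1, confusion=confusion, per_class=per_class,
                         n_videos=n)


# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    subject_id: str
    video_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    metrics: MetricsReport
    attention: np.ndarray | None = None  # mean aggregate attention, per joint


@dataclass
class ExperimentResult:
    folds: list[FoldResult]
    fold_mean: dict[str, float]
    pooled: MetricsReport
    space: LabelSpace
    joint_names: tuple[str, ...]
    skipped: list[str] = field(default_factory=list)

    def attention_table(self) -> pd.DataFrame:
        rows = []
        for fr in self.folds:
            if fr.attention is None:
                continue
            for joint, value in zip(self.joint_names, fr.attention):
                rows.append({"subject_id": fr.subject_id, "joint": joint,
                             "attention": value})
        return pd.DataFrame(rows)

    def cohort_attention(self) -> pd.Series:
        tab = self.attention_table()
        if tab.empty:
            return pd.Series(dtype=float)
        return tab.groupby("joint")["attention"].mean().reindex(self.joint_names)


def run_experiment(x: np.ndarray, manifest: pd.DataFrame, space: LabelSpace,
                   config: ModelConfig, graph: SkeletonGraph | None = None,
                   extract_attention: bool = True,
                   out_dir: str | Path | None = None) -> ExperimentResult:
    """Full LOOCV experiment on a windowed dataset.

    ``x`` holds window features (N, T, V, 3); ``manifest`` one row per
    window with subject_id, video_id, window_index and integer label.
    One model is trained per fold (seeded deterministically from
    ``config.seed`` and the fold index); held-out windows are voted into
    video labels.  Folds whose test videos vanish after label filtering are
    skipped with a warning.
    """
    graph = graph or build_graph()
    plan = make_folds(manifest, mode=space.mode)
    subjects = manifest["subject_id"].to_numpy()
    labels = manifest["label"].to_numpy(dtype=int)
    videos = manifest["video_id"].to_numpy()

    folds: list[FoldResult] = []
    skipped: list[str] = []
    for fold_idx, (test_subject, _) in enumerate(plan.folds):
        test_mask = subjects == test_subject
        if not test_mask.any():
            warnings.warn(f"fold {test_subject}: no test videos, skipping")
            skipped.append(test_subject)
            continue
        train_mask = ~test_mask
        fold_cfg = replace(config, seed=(config.seed * 1009 + fold_idx) % (2**31))
        model = SPAPTA(fold_cfg, graph, space.n_classes)
        model.fit(x[train_mask], labels[train_mask])

        probs = model.predict_proba(x[test_mask])
        preds = probs.argmax(axis=1)
        test_videos = videos[test_mask]
        test_labels = labels[test_mask]
        vid_ids, y_true, y_pred = [], [], []
        for vid in pd.unique(test_videos):
            m = test_videos == vid
            vid_ids.append(vid)
            y_true.append(int(test_labels[m][0]))
            y_pred.append(vote(preds[m], probs[m]))
        y_true = np.array(y_true)
        y_pred = np.array(y_pred)
        metrics = compute_metrics(y_true, y_pred, space)

        att = None
        if extract_attention and config.variant != "no_attention":
            att = model.extract_attention(x[test_mask]).aggregate.mean(axis=0)
        folds.append(FoldResult(subject_id=test_subject, video_ids=vid_ids,
                                y_true=y_true, y_pred=y_pred, metrics=metrics,
                                attention=att))

    if not folds:
        raise RuntimeError("no usable folds")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fold_mean = {
            key: float(np.nanmean([fr.metrics.as_dict()[key] for fr in folds]))
            for key in ("accuracy", "sensitivity", "specificity", "f1")
        }
    pooled = compute_metrics(
        np.concatenate([fr.y_true for fr in folds]),
        np.concatenate([fr.y_pred for fr in folds]), space)
    result = ExperimentResult(folds=folds, fold_mean=fold_mean, pooled=pooled,
                              space=space, joint_names=graph.nodes,
                              skipped=skipped)
    if out_dir is not None:
        _write_reports(result, config, Path(out_dir))
    return result


def _write_reports(result: ExperimentResult, config: ModelConfig,
                   out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([
        {"subject_id": fr.subject_id, **fr.metrics.as_dict()}
        for fr in result.folds
    ]).to_csv(out_dir / "folds.csv", index=False)
    summary = {
        "mode": result.space.mode,
        "classes": list(result.space.classes),
        "fold_mean": result.fold_mean,
        "pooled": result.pooled.as_dict(),
        "skipped_folds": result.skipped,
        "config": dataclasses.asdict(config),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    pd.DataFrame(result.pooled.confusion,
                 index=result.space.classes,
                 columns=result.space.classes).to_csv(out_dir / "confusion.csv")
    att = result.attention_table()
    if not att.empty:
        att.to_csv(out_dir / "attention.csv", index=False)


# ---------------------------------------------------------------------------
# spectral tremor-frequency estimation (pose-quality check)


def estimate_tremor_frequency(trajectory: np.ndarray, fps: float,
                              f_min: float = 1.0,
                              concentration_threshold: float = 0.2,
                              ) -> float | None:
    """Dominant oscillation frequency of a wrist trajectory, in Hz.

    Each coordinate axis is linearly detrended and Hann-windowed; the
    per-axis power spectra are summed and the dominant peak in
    [f_min, fps/2) is located with parabolic interpolation.  Returns None
    (tremor-free) when the trajectory is essentially constant or no peak
    concentrates enough of the in-band power (less than
    ``concentration_threshold`` of it within +-0.5 Hz of the peak).
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim == 1:
        traj = traj[:, None]
    n = traj.shape[0]
    if n / fps < 2.0:
        raise ValueError("need at least 2 s of samples to estimate a frequency")
    if float(traj.var(axis=0).sum()) < 1e-12:
        return None

    detrended = sp_signal.detrend(traj, axis=0)
    window = np.hanning(n)[:, None]
    spec = np.abs(np.fft.rfft(detrended * window, axis=0)) ** 2
    power = spec.sum(axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)

    band = (freqs >= f_min) & (freqs < fps / 2)
    if not band.any():
        raise ValueError("frequency band empty for this fps")
    in_band = np.flatnonzero(band)
    k = in_band[np.argmax(power[in_band])]

    near = np.abs(freqs - freqs[k]) <= 0.5
    if power[band & near].sum() < concentration_threshold * power[band].sum():
        return None

    # parabolic interpolation around the peak bin
    if 0 < k < power.size - 1 and power[k] > 0:
        y0, y1, y2 = power[k - 1], power[k], power[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float((k + delta) * fps / n)
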