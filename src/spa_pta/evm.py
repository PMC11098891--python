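"""Eulerian video magnification (EVM) for subtle tremor enhancement.

Parkinsonian rest tremor lives in a narrow 3-7 Hz band; at consumer-grade
resolution the corresponding wrist displacement can be a fraction of a
pixel.  Linear EVM amplifies it: each frame is decomposed into a Laplacian
(band-pass) pyramid, every level's per-pixel time series is band-pass
filtered in the temporal frequency domain, the filtered signal is scaled by
``alpha`` and added back, and the pyramid is collapsed.  To first order in
the motion this multiplies in-band displacement by (1 + alpha).

A video is only suitable for tremor analysis if its frame rate satisfies
the Nyquist criterion: fps >= 2 * (highest tremor frequency of interest).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

DEFAULT_BAND = (3.0, 7.0)
DEFAULT_ALPHA = 10.0
DEFAULT_LEVELS = 4

# RGB <-> YIQ (NTSC) — motion is amplified on luminance only
_RGB2YIQ = np.array([
    [0.299, 0.587, 0.114],
    [0.596, -0.274, -0.322],
    [0.211, -0.523, 0.312],
])
_YIQ2RGB = np.linalg.inv(_RGB2YIQ)


class NyquistError(ValueError):
    """Frame rate too low for the requested frequency band."""


@dataclass(frozen=True)
class BandSpec:
    """Temporal pass-band and amplification settings."""

    f_lo: float = DEFAULT_BAND[0]
    f_hi: float = DEFAULT_BAND[1]
    alpha: float = DEFAULT_ALPHA
    pyramid_levels: int = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("need 0 < f_lo < f_hi")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")


@dataclass
class VideoClip:
    """Stack of equally sized frames with intensities in [0, 1]."""

    frames: np.ndarray  # (T, H, W) or (T, H, W, 3)
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T, H, W) or (T, H, W, C)")
        if self.frames.shape[0] < 2:
            raise ValueError("a video needs at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def is_color(self) -> bool:
        return self.frames.ndim == 4


def check_nyquist(fps: float, f_max: float) -> tuple[bool, str]:
    """Check whether ``fps`` can represent motion up to ``f_max`` Hz.

    Valid iff fps >= 2 * f_max ("at least twice the highest frequency").
    Returns (flag, human-readable message).
    """
    if fps <= 0 or f_max <= 0:
        raise ValueError("fps and f_max must be positive")
    if fps >= 2 * f_max:
        return True, (
            f"frame rate {fps:g} Hz resolves motion up to {f_max:g} Hz "
            f"(Nyquist limit {fps / 2:g} Hz)"
        )
    return False, (
        f"frame rate {fps:g} Hz is below the required {2 * f_max:g} Hz "
        f"for {f_max:g} Hz motion; tremor analysis would alias"
    )


def temporal_bandpass(series: np.ndarray, fps: float, f_lo: float,
                      f_hi: float) -> np.ndarray:
    """Ideal band-pass filter along the first (time) axis.

    Frequency components in [f_lo, f_hi] are kept, everything else
    (including DC) is zeroed.  The signal is reflect-padded before the FFT
    so short clips do not ring at the edges.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples to band-pass filter")
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    if f_hi > fps / 2:
        raise ValueError(
            f"band edge {f_hi:g} Hz exceeds the Nyquist frequency {fps / 2:g} Hz"
        )
    pad = n // 2
    idx = np.r_[pad - 1::-1, 0:n, n - 1:n - 1 - pad:-1] if pad else np.arange(n)
    padded = series[idx]
    freqs = np.fft.rfftfreq(padded.shape[0], d=1.0 / fps)
    spec = np.fft.rfft(padded, axis=0)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=padded.shape[0], axis=0)
    return out[pad:pad + n]


def _downsample(img: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma=1.0, mode="reflect")[..., ::2, ::2]


def _upsample(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    factors = [1.0] * (img.ndim - 2) + [shape[0] / img.shape[-2], shape[1] / img.shape[-1]]
    return ndimage.zoom(img, factors, order=1, mode="reflect", grid_mode=True)


def _laplacian_pyramid(stack: np.ndarray, levels: int) -> list[np.ndarray]:
    """Per-frame Laplacian pyramid of a (T, H, W) stack.

    Levels sum back to the input exactly (the coarsest level is the
    residual Gaussian), so the decomposition is lossless.
    """
    pyramid: list[np.ndarray] = []
    current = stack
    for _ in range(levels - 1):
        if min(current.shape[-2:]) < 4:
            break
        down = _downsample(current)
        pyramid.append(current - _upsample(down, current.shape[-2:]))
        current = down
    pyramid.append(current)
    return pyramid


def _collapse(pyramid: list[np.ndarray]) -> np.ndarray:
    out = pyramid[-1]
    for level in reversed(pyramid[:-1]):
        out = level + _upsample(out, level.shape[-2:])
    return out


def magnify(video: VideoClip, spec: BandSpec = BandSpec()) -> VideoClip:
    """Amplify in-band motion of ``video`` by ``spec.alpha``.

    Refuses to run when the frame rate cannot represent the upper band edge
    (Nyquist violation).  Color input is processed on the luminance channel
    only; chrominance passes through untouched.  Output intensities are
    clipped back to [0, 1].
    """
    ok, msg = check_nyquist(video.fps, spec.f_hi)
    if not ok:
        raise NyquistError(msg)

    if video.is_color:
        yiq = np.einsum("thwc,dc->thwd", video.frames, _RGB2YIQ)
        luma = yiq[..., 0]
    else:
        luma = video.frames

    pyramid = _laplacian_pyramid(luma, spec.pyramid_levels)
    if spec.alpha > 0:
        for k, level in enumerate(pyramid):
            pyramid[k] = level + spec.alpha * temporal_bandpass(
                level, video.fps, spec.f_lo, spec.f_hi)
    out_luma = _collapse(pyramid)

    if video.is_color:
        yiq = yiq.copy()
        yiq[..., 0] = out_luma
        frames = np.einsum("thwd,cd->thwc", yiq, _YIQ2RGB)
    else:
        frames = out_luma
    return VideoClip(frames=np.clip(frames, 0.0, 1.0), fps=video.fps)


def magnify_trajectories(joints: np.ndarray, fps: float,
                         spec: BandSpec = BandSpec()) -> np.ndarray:
    """Pose-domain motion magnification: amplify in-band joint motion.

    When the pipeline starts from video, magnification happens on pixels
    and the pose estimator sees tremor displacements scaled by ~(1+alpha).
    When the input is an already-extracted pose stream, this applies the
    equivalent operation directly to the trajectories: each joint's (x, y)
    time series is band-pass filtered and the filtered component is added
    back scaled by alpha.  Confidences are untouched.

    ``joints`` has shape (frames, keypoints, 3); returns the same shape.
    """
    ok, msg = check_nyquist(fps, spec.f_hi)
    if not ok:
        raise NyquistError(msg)
    out = np.asarray(joints, dtype=float).copy()
    if spec.alpha > 0:
        out[:, :, :2] += spec.alpha * temporal_bandpass(
            out[:, :, :2], fps, spec.f_lo, spec.f_hi)
    return out


# ---------------------------------------------------------------------------
# video I/O: PNG image-stack directories always work; container formats go
# through imageio and require its ffmpeg backend


def read_video(path: str | Path, fps: float | None = None) -> VideoClip:
    """Read a video from a PNG-stack directory or a container file."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        frames = np.stack([iio.imread(f) for f in files]).astype(float) / 255.0
        if fps is None:
            raise ValueError("fps must be given for image-stack input")
        return VideoClip(frames=frames, fps=fps)
    frames = iio.imread(path).astype(float) / 255.0
    if fps is None:
        meta = iio.immeta(path)
        fps = float(meta.get("fps", 0.0)) or None
        if fps is None:
            raise ValueError(f"{path} carries no frame-rate metadata; pass fps")
    return VideoClip(frames=frames, fps=fps)


def write_video(clip: VideoClip, path: str | Path) -> None:
    """Write a video as a PNG-stack directory or a container file."""
    import imageio.v3 as iio

    path = Path(path)
    frames8 = (np.clip(clip.frames, 0, 1) * 255).round().astype(np.uint8)
    if path.suffix == "":
        path.mkdir(parents=True, exist_ok=True)
        for t, frame in enumerate(frames8):
            iio.imwrite(path / f"frame_{t:05d}.png", frame)
    else:
        iio.imwrite(path, frames8, fps=clip.fps)
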