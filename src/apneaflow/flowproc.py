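"""Video → motion representations.

Temporal decimation of infrared video, dense optical flow between retained
frames, per-pixel movement magnitude ``d = √(x² + y²)`` with the 0.5 px/s
cap, fixed-size region crops, and detection of gross position shifts from
the frame-mean movement.

Units: optical flow is stored in px/frame; magnitudes are converted to
px/s (multiplied by the frame rate) before capping, so the 0.5 px/s cap
applies verbatim at any frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import optical_flow_ilk, optical_flow_tvl1

__all__ = [
    "VideoSequence",
    "FlowSequence",
    "MagnitudeSequence",
    "downsample_video",
    "compute_flow",
    "flow_magnitude",
    "cap_magnitude",
    "cap_flow",
    "crop_region_flow",
    "crop_region_flow_array",
    "detect_position_shifts",
    "DEFAULT_CAP",
]

DEFAULT_CAP = 0.5  # px/s


@dataclass
class VideoSequence:
    """Grayscale frames (T, H, W) float32 plus frame rate in Hz."""

    frames: np.ndarray
    fps: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("video needs >= 2 frames of identical shape (T, H, W)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class FlowSequence:
    """Displacement fields (T-1, H, W, 2), px/frame; channel 0 = x, 1 = y."""

    fields: np.ndarray
    fps: float

    def __post_init__(self):
        self.fields = np.asarray(self.fields, dtype=np.float32)
        if self.fields.ndim != 4 or self.fields.shape[-1] != 2:
            raise ValueError("flow fields must have shape (T-1, H, W, 2)")
        if not np.isfinite(self.fields).all():
            raise ValueError("flow fields contain non-finite values")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_fields(self) -> int:
        return self.fields.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.fields.shape[1:3]


@dataclass
class MagnitudeSequence:
    """Per-pixel movement magnitudes (T-1, H, W) in px/s."""

    mags: np.ndarray
    fps: float
    cap: float | None = None

    def __post_init__(self):
        self.mags = np.asarray(self.mags, dtype=np.float32)
        if self.mags.ndim != 3:
            raise ValueError("magnitudes must have shape (T-1, H, W)")
        if self.cap is not None and (self.mags > self.cap).any():
            raise ValueError("capped magnitudes exceed the declared cap")


def downsample_video(video: VideoSequence, target_fps: float) -> VideoSequence:
    """Decimate to ``target_fps`` by keeping every k-th frame (k = fps ratio)."""
    ratio = video.fps / target_fps
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"source fps {video.fps} is not an integer multiple of target {target_fps}"
        )
    return VideoSequence(frames=video.frames[::k], fps=target_fps)


_BACKENDS = {
    "ilk": lambda ref, mov: optical_flow_ilk(ref, mov, radius=7),
    "tvl1": lambda ref, mov: optical_flow_tvl1(ref, mov),
}


def compute_flow(video: VideoSequence, backend: str = "ilk") -> FlowSequence:
    """Dense optical flow between consecutive frames.

    Backends are classical dense-flow estimators (iterative Lucas-Kanade
    ``"ilk"`` — the default — or ``"tvl1"``); both are deterministic.  The
    sign convention is physical: content moving right (+x) or down (+y)
    yields positive flow.
    """
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise ValueError(
            f"unknown optical-flow backend {backend!r}; choose from {sorted(_BACKENDS)}"
        ) from None
    frames = video.frames
    fields = np.empty((video.n_frames - 1, *video.frame_shape, 2), dtype=np.float32)
    for i in range(video.n_frames - 1):
        # registration's (row, col) field maps frame i coordinates onto
        # their new location in frame i+1, i.e. the scene motion itself.
        vrow, vcol = fn(frames[i], frames[i + 1])
        fields[i, :, :, 0] = vcol
        fields[i, :, :, 1] = vrow
    return FlowSequence(fields=fields, fps=video.fps)


def flow_magnitude(flow: FlowSequence) -> MagnitudeSequence:
    """Per-pixel Euclidean norm of the flow, converted to px/s."""
    mags = np.linalg.norm(flow.fields, axis=-1) * flow.fps
    return MagnitudeSequence(mags=mags.astype(np.float32), fps=flow.fps, cap=None)


def cap_magnitude(mags: MagnitudeSequence, cap: float = DEFAULT_CAP) -> MagnitudeSequence:
    """Replace magnitudes strictly above ``cap`` (px/s) with ``cap``."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return MagnitudeSequence(
        mags=np.minimum(mags.mags, np.float32(cap)), fps=mags.fps, cap=cap
    )


def cap_flow(flow: FlowSequence, cap: float = DEFAULT_CAP) -> FlowSequence:
    """Rescale flow vectors whose speed exceeds ``cap`` px/s onto the cap.

    The vector-field analogue of :func:`cap_magnitude`, for feeding
    magnitude-capped motion to models that consume 2-channel flow.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    speed = np.linalg.norm(flow.fields, axis=-1) * flow.fps
    scale = np.ones_like(speed)
    np.divide(cap, speed, out=scale, where=speed > cap)
    return FlowSequence(fields=flow.fields * scale[..., None], fps=flow.fps)


def crop_region_flow_array(arr: np.ndarray, center: tuple[float, float], size: int) -> np.ndarray:
    """Fixed ``size×size`` spatial crop of an (H, W, ...) array around ``center``.

    ``center`` is (x, y) in pixels.  The nominal window is clamped to the
    frame; out-of-frame pixels are zero-filled, so the output is always
    exactly ``size×size`` spatially.
    """
    h, w = arr.shape[:2]
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"crop center {center} lies outside the {h}x{w} frame")
    top = int(round(cy)) - size // 2
    left = int(round(cx)) - size // 2
    out = np.zeros((size, size, *arr.shape[2:]), dtype=arr.dtype)
    src_t, src_l = max(top, 0), max(left, 0)
    src_b, src_r = min(top + size, h), min(left + size, w)
    if src_b > src_t and src_r > src_l:
        out[src_t - top : src_b - top, src_l - left : src_r - left] = arr[
            src_t:src_b, src_l:src_r
        ]
    return out


def crop_region_flow(flow: FlowSequence, center: tuple[float, float], size: int = 100) -> FlowSequence:
    """Crop every flow field to a ``size×size`` window around ``center`` (x, y)."""
    fields = np.stack(
        [
            crop_region_flow_array(field, center, size)
            for field in flow.fields
        ]
    )
    return FlowSequence(fields=fields, fps=flow.fps)


def detect_position_shifts(mags: MagnitudeSequence, threshold: float) -> list[int]:
    """Frame indices where whole-scene movement exceeds ``threshold`` px/s.

    Uses the frame-mean *uncapped* magnitude; runs of consecutive
    above-threshold frames are merged and reported by their first index.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    frame_mean = mags.mags.mean(axis=(1, 2))
    above = frame_mean > threshold
    shifts = []
    prev = False
    for i, flag in enumerate(above):
        if flag and not prev:
            shifts.append(i)
        prev = flag
    return shifts
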