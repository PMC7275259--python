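"""Seeded synthetic respiratory-motion generator.

Emulates the motion phenomenology that distinguishes apnea types in
overhead infrared video:

* normal breathing — chest and abdomen oscillate vertically *in phase*;
* obstructive apnea (OA) — continued effort against a blocked airway moves
  chest and abdomen *out of phase* (π offset), so their summed displacement
  is near zero;
* central apnea (CA) — absent effort, near-zero motion in both regions
  (a small residual ``motion_scale`` mimics sensor/tissue noise).

On top of the region sinusoids the generator models sensor noise, spatial
smearing of motion beyond region borders (a blanket propagates chest and
abdominal movement outward — emulated as a Gaussian blur of the
displacement field), and abrupt whole-body position shifts.

Everything is driven by a ``numpy`` Generator seeded explicitly, and
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .flowproc import FlowSequence, VideoSequence
from .roi import BoundingBox
from .windowing import ApneaEvent

__all__ = [
    "BreathingSpec",
    "SyntheticScene",
    "EventSpec",
    "generate_event_flow",
    "generate_recording",
    "generate_anthropometrics",
    "torso_boxes_from_predictors",
    "default_scene",
    "write_annotations",
    "read_annotations",
    "save_flow",
    "load_flow",
    "ANTHRO_COEFFS",
]

#: Breathing rate during sleep spans 12-25 breaths/min, i.e. 0.2-0.42 Hz.
BREATH_RATE_RANGE = (0.2, 0.42)
MIN_APNEA_SECONDS = 10.0
#: Fraction of the sensor-noise scale that is spatially coherent
#: (common-mode whole-frame jitter per frame).
JITTER_FRACTION = 0.4


@dataclass(frozen=True)
class BreathingSpec:
    """Parameters of the two-compartment breathing oscillation.

    ``phase_offset`` is the abdomen-vs-chest phase in radians (0 = in
    phase, π = paradoxical/out of phase); ``motion_scale`` multiplies both
    amplitudes (≈0 suppresses motion, as in CA); ``smear_sigma`` is the
    spatial Gaussian radius of the blanket smear in px.

    Sensor noise has two components: per-pixel i.i.d. noise of ``noise_sd``
    px, and a spatially coherent common-mode jitter (whole-frame flow
    offset per frame) of ``JITTER_FRACTION × noise_sd`` px — camera and
    gross-body micro-motions are correlated across the frame and survive
    spatial averaging, unlike i.i.d. pixel noise.
    """

    breath_rate: float = 0.3  # Hz
    chest_amplitude: float = 0.35  # px
    abdomen_amplitude: float = 0.28  # px
    phase_offset: float = 0.0  # radians
    motion_scale: float = 1.0
    noise_sd: float = 0.05  # px, sensor-noise scale (pixel + common-mode)
    smear_sigma: float = 4.0  # px
    speed_mod: float = 0.5  # inspiratory/expiratory speed asymmetry (0 = sinusoid)

    def __post_init__(self):
        if not (0.05 <= self.breath_rate <= 0.5):
            raise ValueError("breath_rate must lie in [0.05, 0.5] Hz")
        if min(self.chest_amplitude, self.abdomen_amplitude) < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.smear_sigma < 0 or self.noise_sd < 0:
            raise ValueError("smear_sigma and noise_sd must be >= 0")


#: Presets for the three event classes.
def oa_breathing(**kw) -> BreathingSpec:
    return BreathingSpec(phase_offset=np.pi, **kw)


def ca_breathing(**kw) -> BreathingSpec:
    kw.setdefault("motion_scale", 0.05)
    return BreathingSpec(**kw)


@dataclass(frozen=True)
class SyntheticScene:
    """Frame geometry: frame size and chest/abdomen/head rectangles."""

    frame_size: tuple[int, int]  # (H, W)
    chest_box: BoundingBox
    abdomen_box: BoundingBox
    head_box: BoundingBox
    texture_seed: int = 0

    def __post_init__(self):
        h, w = self.frame_size
        for name, box in (
            ("chest", self.chest_box),
            ("abdomen", self.abdomen_box),
            ("head", self.head_box),
        ):
            if box.x < 0 or box.y < 0 or box.x + box.width > w or box.y + box.height > h:
                raise ValueError(f"{name} box {box} lies outside the {h}x{w} frame")
        from .roi import iou

        for name, box in (("chest", self.chest_box), ("abdomen", self.abdomen_box)):
            if iou(box, self.head_box) > 0:
                raise ValueError(f"{name} box overlaps the head box")


@dataclass(frozen=True)
class EventSpec:
    """A labeled breathing segment: OA / CA / NORMAL."""

    label: str
    start: float  # s
    duration: float  # s
    breathing: BreathingSpec

    def __post_init__(self):
        if self.label not in ("OA", "CA", "NORMAL"):
            raise ValueError(f"label must be OA, CA or NORMAL, got {self.label!r}")
        if self.label in ("OA", "CA") and self.duration < MIN_APNEA_SECONDS:
            raise ValueError(
                f"{self.label} events last >= {MIN_APNEA_SECONDS:.0f} s, got {self.duration} s"
            )
        if self.duration <= 0 or self.start < 0:
            raise ValueError("events need start >= 0 and duration > 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


def default_scene(frame_size: tuple[int, int] = (48, 64), texture_seed: int = 0) -> SyntheticScene:
    """A supine-sleeper layout scaled to ``frame_size`` (head up, torso below)."""
    h, w = frame_size
    return SyntheticScene(
        frame_size=frame_size,
        head_box=BoundingBox(0.42 * w, 0.02 * h, 0.16 * w, 0.18 * h),
        chest_box=BoundingBox(0.27 * w, 0.30 * h, 0.46 * w, 0.28 * h),
        abdomen_box=BoundingBox(0.27 * w, 0.62 * h, 0.46 * w, 0.28 * h),
        texture_seed=texture_seed,
    )


def make_event_spec(label: str, start: float, duration: float, rng: np.random.Generator,
                    **breathing_kw) -> EventSpec:
    """Draw a breathing spec with a random in-band rate for a labeled event."""
    rate = float(rng.uniform(*BREATH_RATE_RANGE))
    breathing_kw.setdefault("breath_rate", rate)
    if label == "OA":
        spec = oa_breathing(**breathing_kw)
    elif label == "CA":
        spec = ca_breathing(**breathing_kw)
    else:
        spec = BreathingSpec(**breathing_kw)
    return EventSpec(label=label, start=start, duration=duration, breathing=spec)


# ---------------------------------------------------------------------------
# displacement model


def _region_mask(scene: SyntheticScene, box: BoundingBox) -> np.ndarray:
    # round position and size separately so equal-sized boxes rasterize to
    # congruent masks (required for the exact OA antiphase null)
    h, w = scene.frame_size
    y0, x0 = int(round(box.y)), int(round(box.x))
    y1 = min(y0 + int(round(box.height)), h)
    x1 = min(x0 + int(round(box.width)), w)
    mask = np.zeros((h, w), dtype=np.float32)
    mask[y0:y1, x0:x1] = 1.0
    return mask


def region_slices(box: BoundingBox) -> tuple[slice, slice]:
    """(row, col) slices of a box, rasterized the same way as the generator."""
    y0, x0 = int(round(box.y)), int(round(box.x))
    return (
        slice(y0, y0 + int(round(box.height))),
        slice(x0, x0 + int(round(box.width))),
    )


def breathing_waveform(spec: BreathingSpec, times: np.ndarray, phase: float = 0.0) -> np.ndarray:
    """Unit breathing displacement waveform at ``times`` (s).

    ``sin(θ + speed_mod·sin θ + phase)`` with θ = 2π·rate·t: a phase-warped
    sinusoid whose velocity is asymmetric between inspiration and
    expiration (fast inhale, slow exhale), as in real breathing.  The warp
    is shared by chest and abdomen, so a π phase offset is an exact sign
    flip and the paradoxical (OA) two-compartment sum still cancels.
    """
    theta = 2.0 * np.pi * spec.breath_rate * times
    return np.sin(theta + spec.speed_mod * np.sin(theta) + phase)


def _region_displacements(spec: BreathingSpec, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vertical displacement (px) of chest and abdomen at ``times`` (s)."""
    chest = spec.motion_scale * spec.chest_amplitude * breathing_waveform(spec, times)
    abd = spec.motion_scale * spec.abdomen_amplitude * breathing_waveform(
        spec, times, spec.phase_offset
    )
    return chest, abd


def _smear(field: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blanket smear on a padded canvas (edge-truncation free)."""
    if sigma <= 0:
        return field
    pad = int(np.ceil(4 * sigma)) + 1
    padded = np.pad(field, pad)
    return ndimage.gaussian_filter(padded, sigma, mode="constant")[pad:-pad, pad:-pad]


def _displacement_fields(
    scene: SyntheticScene, spec: BreathingSpec, times: np.ndarray
) -> np.ndarray:
    """Dense (T, H, W, 2) displacement from the two-region model + smear."""
    h, w = scene.frame_size
    chest_mask = _region_mask(scene, scene.chest_box)
    abd_mask = _region_mask(scene, scene.abdomen_box)
    d_chest, d_abd = _region_displacements(spec, times)
    fields = np.zeros((len(times), h, w, 2), dtype=np.float32)
    for i in range(len(times)):
        dy = _smear(d_chest[i] * chest_mask + d_abd[i] * abd_mask, spec.smear_sigma)
        fields[i, :, :, 1] = dy
    return fields


def generate_event_flow(
    scene: SyntheticScene,
    spec: EventSpec,
    fps: float = 2.0,
    seed: int = 0,
) -> tuple[FlowSequence, str]:
    """Ground-truth optical flow for one event, plus its label.

    Returns ``T - 1`` flow fields for the event's ``T = duration·fps + 1``
    frames.  Flow = frame-to-frame difference of the dense displacement
    field, plus i.i.d. Gaussian sensor noise of ``noise_sd`` px.
    Deterministic given the seed.
    """
    if fps not in (2, 2.0, 30, 30.0):
        raise ValueError(f"fps must be 2 or 30, got {fps}")
    n_frames = int(round(spec.duration * fps)) + 1
    if n_frames < 2:
        raise ValueError("duration x fps must give at least 2 frames")
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) / fps
    disp = _displacement_fields(scene, spec.breathing, times)
    flow = np.diff(disp, axis=0)
    if spec.breathing.noise_sd > 0:
        flow = flow + rng.normal(0.0, spec.breathing.noise_sd, size=flow.shape).astype(
            np.float32
        )
        jitter = rng.normal(
            0.0, JITTER_FRACTION * spec.breathing.noise_sd, size=(flow.shape[0], 1, 1, 2)
        )
        flow = flow + jitter.astype(np.float32)
    return FlowSequence(fields=flow.astype(np.float32), fps=fps), spec.label


# ---------------------------------------------------------------------------
# full recordings (rendered frames + flow + annotations)


def _texture(scene: SyntheticScene, rng: np.random.Generator) -> np.ndarray:
    """Smooth random texture so flow estimators see usable gradients."""
    h, w = scene.frame_size
    base = rng.normal(0.0, 1.0, size=(h, w))
    tex = ndimage.gaussian_filter(base, 2.0)
    tex = (tex - tex.min()) / (tex.max() - tex.min() + 1e-12)
    return (60.0 + 160.0 * tex).astype(np.float32)


def _ramp_envelope(times: np.ndarray, start: float, end: float, ramp: float = 1.0) -> np.ndarray:
    """Cosine on/off ramp confining a segment's oscillation to [start, end]."""
    env = np.zeros_like(times)
    inside = (times >= start) & (times <= end)
    rel = np.clip((times - start) / ramp, 0, 1) * np.clip((end - times) / ramp, 0, 1)
    env[inside] = 0.5 * (1 - np.cos(np.pi * np.clip(rel[inside], 0, 1)))
    return env


def generate_recording(
    scene: SyntheticScene,
    specs: list[EventSpec],
    fps: float = 2.0,
    seed: int = 0,
    duration: float | None = None,
    recording_id: str = "synthetic",
    position_shifts: list[float] | None = None,
    shift_magnitude: float = 8.0,
    frame_noise_sd: float = 1.0,
    gap_breathing: BreathingSpec | None = None,
    render_frames: bool = True,
) -> dict:
    """Render a full recording: frames, exact flow, annotations, metadata.

    Inter-event gaps contain normal breathing (``gap_breathing``).  Optional
    position shifts add a permanent whole-frame displacement step of
    ``shift_magnitude`` px at the given times.  Returns a dict with keys
    ``video`` (:class:`VideoSequence`; ``None`` when ``render_frames`` is
    off), ``flow`` (:class:`FlowSequence` — the displacement differences
    driving the rendering plus the sensor-noise model, i.e. the flow a
    motion front-end would report), ``events`` (annotated OA/CA events),
    and ``meta``.
    """
    specs = sorted(specs, key=lambda s: s.start)
    for a, b in zip(specs, specs[1:]):
        if a.end > b.start:
            raise ValueError(f"event specs overlap: {a} and {b}")
    if duration is None:
        duration = (specs[-1].end if specs else 0.0) + 5.0
    if specs and specs[-1].end > duration:
        raise ValueError("recording duration is shorter than the last event")

    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * fps))
    times = np.arange(n_frames) / fps
    h, w = scene.frame_size
    gap = gap_breathing or BreathingSpec()

    # Active breathing segments: declared events plus NORMAL gap filler.
    segments = [(s.breathing, s.start, s.end) for s in specs]
    edges = [0.0] + sorted(t for s in specs for t in (s.start, s.end)) + [duration]
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi - lo > 1.0:
            segments.append((gap, lo, hi))

    chest_mask = _region_mask(scene, scene.chest_box)
    abd_mask = _region_mask(scene, scene.abdomen_box)
    d_chest = np.zeros(n_frames)
    d_abd = np.zeros(n_frames)
    for breathing, lo, hi in segments:
        env = _ramp_envelope(times, lo, hi)
        d_chest += (
            env
            * breathing.motion_scale
            * breathing.chest_amplitude
            * breathing_waveform(breathing, times - lo)
        )
        d_abd += (
            env
            * breathing.motion_scale
            * breathing.abdomen_amplitude
            * breathing_waveform(breathing, times - lo, breathing.phase_offset)
        )

    # Whole-body offsets from position shifts (permanent steps).
    shift_frames = sorted(int(round(t * fps)) for t in (position_shifts or []))
    offset_x = np.zeros(n_frames)
    offset_y = np.zeros(n_frames)
    for k, fidx in enumerate(shift_frames):
        direction = 1 if k % 2 == 0 else -1
        offset_x[fidx:] += direction * shift_magnitude
        offset_y[fidx:] += direction * 0.5 * shift_magnitude

    # Common-mode sensor jitter: a whole-frame random-walk displacement
    # whose per-frame flow step is JITTER_FRACTION x the sensor-noise scale.
    jitter_sd = JITTER_FRACTION * gap.noise_sd
    if jitter_sd > 0 and n_frames > 1:
        steps = rng.normal(0.0, jitter_sd, size=(n_frames - 1, 2))
        walk = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        offset_x = offset_x + walk[:, 0]
        offset_y = offset_y + walk[:, 1]

    smear = max(s.smear_sigma for s, *_ in segments) if segments else 0.0
    disp = np.zeros((n_frames, h, w, 2), dtype=np.float32)
    for i in range(n_frames):
        dy = _smear(d_chest[i] * chest_mask + d_abd[i] * abd_mask, smear)
        disp[i, :, :, 0] = offset_x[i]
        disp[i, :, :, 1] = dy + offset_y[i]

    video = None
    if render_frames:
        texture = _texture(scene, np.random.default_rng(scene.texture_seed))
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
        frames = np.empty((n_frames, h, w), dtype=np.float32)
        for i in range(n_frames):
            coords = np.stack([yy - disp[i, :, :, 1], xx - disp[i, :, :, 0]])
            frames[i] = ndimage.map_coordinates(texture, coords, order=1, mode="nearest")
        if frame_noise_sd > 0:
            frames += rng.normal(0.0, frame_noise_sd, size=frames.shape).astype(np.float32)
        video = VideoSequence(frames=frames, fps=fps)

    flow = np.diff(disp, axis=0)
    if gap.noise_sd > 0:
        flow = flow + rng.normal(0.0, gap.noise_sd, size=flow.shape).astype(np.float32)
    events = [
        ApneaEvent(recording_id=recording_id, start=s.start, end=s.end, label=s.label)
        for s in specs
        if s.label in ("OA", "CA")
    ]
    return {
        "video": video,
        "flow": FlowSequence(fields=flow.astype(np.float32), fps=fps),
        "events": events,
        "meta": {
            "recording_id": recording_id,
            "fps": fps,
            "duration": duration,
            "frame_size": (h, w),
            "position_shift_frames": shift_frames,
            "seed": seed,
        },
    }


# ---------------------------------------------------------------------------
# anthropometrics + torso-box generative model

#: Coefficients of the generative affine map from predictors to torso boxes
#: (pixel units at the nominal 640x480 frame; 200 px per meter overhead).
ANTHRO_COEFFS = {
    "px_per_m": 200.0,
    "head_w0": 36.0,
    "head_w_per_m": 30.0,  # d(head_w)/d(height)
    "head_aspect": 1.3,
    "chest_gap_frac": 0.10,  # of height (m), times px_per_m, below the head box
    "abd_gap_frac": 0.13,
    "chest_w_per_head_w": 2.8,
    "chest_w_per_bmi": 0.8,
    "chest_aspect": 0.60,
    "abd_w_scale": 1.05,
    "lateral_dx": 10.0,  # body-lateral shifts the torso center sideways
}


def torso_boxes_from_predictors(table: pd.DataFrame) -> pd.DataFrame:
    """The documented noiseless affine map predictors → torso-box targets."""
    c = ANTHRO_COEFFS
    head_cx = table["head_x"] + table["head_w"] / 2.0
    lateral = (table["body_position"] == "lateral").astype(float)
    chest_cx = head_cx + c["lateral_dx"] * lateral
    chest_cy = table["head_y"] + table["head_h"] + c["chest_gap_frac"] * table["height"] * c["px_per_m"]
    chest_w = c["chest_w_per_head_w"] * table["head_w"] + c["chest_w_per_bmi"] * (table["bmi"] - 30.0)
    chest_h = c["chest_aspect"] * chest_w
    abd_cy = chest_cy + c["abd_gap_frac"] * table["height"] * c["px_per_m"]
    return pd.DataFrame(
        {
            "chest_cx": chest_cx,
            "chest_cy": chest_cy,
            "chest_w": chest_w,
            "chest_h": chest_h,
            "abd_cx": chest_cx,
            "abd_cy": abd_cy,
            "abd_w": c["abd_w_scale"] * chest_w,
            "abd_h": chest_h,
        }
    )


def generate_anthropometrics(n: int, seed: int = 0, noise_sd: float = 0.0) -> pd.DataFrame:
    """Sample an anthropometric table with ground-truth torso boxes.

    Torso boxes are a known noisy affine function of the predictors (the
    coefficients in :data:`ANTHRO_COEFFS`), enabling regression-recovery
    tests.  ``noise_sd`` (px) perturbs the 8 target values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    c = ANTHRO_COEFFS
    height = np.clip(rng.normal(1.70, 0.10, size=n), 1.50, 1.95)
    bmi = np.clip(rng.normal(30.0, 7.0, size=n), 18.0, 45.0)
    weight = bmi * height**2
    head_w = c["head_w0"] + c["head_w_per_m"] * (height - 1.70) + rng.normal(0, 0.5, n)
    head_h = c["head_aspect"] * head_w
    # heads cluster near the pillow center of the overhead view
    head_x = rng.uniform(295.0, 325.0, size=n)
    head_y = rng.uniform(30.0, 50.0, size=n)
    head_pos = np.where(rng.random(n) < 0.5, "supine", "lateral")
    body_pos = np.where(rng.random(n) < 0.5, "supine", "lateral")
    table = pd.DataFrame(
        {
            "head_x": head_x,
            "head_y": head_y,
            "head_w": head_w,
            "head_h": head_h,
            "bmi": bmi,
            "weight": weight,
            "height": height,
            "head_position": head_pos,
            "body_position": body_pos,
        }
    )
    targets = torso_boxes_from_predictors(table)
    if noise_sd > 0:
        targets = targets + rng.normal(0.0, noise_sd, size=targets.shape)
    return pd.concat([table, targets], axis=1)


# ---------------------------------------------------------------------------
# external interfaces: annotations and flow containers


def write_annotations(path, events: list[ApneaEvent]) -> None:
    """One event per line: ``recording_id,start_s,end_s,label``."""
    with open(path, "w") as fh:
        for e in events:
            fh.write(f"{e.recording_id},{e.start:g},{e.end:g},{e.label}\n")


def read_annotations(path) -> list[ApneaEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rid, start, end, label = line.split(",")
            events.append(
                ApneaEvent(recording_id=rid, start=float(start), end=float(end), label=label)
            )
    return events


def save_flow(path_prefix: str, flow: FlowSequence) -> None:
    """Store flow as ``<prefix>.npy`` (T-1, H, W, 2) + ``<prefix>.json`` sidecar."""
    import json

    np.save(f"{path_prefix}.npy", flow.fields)
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(
            {
                "fps": flow.fps,
                "shape": list(flow.fields.shape),
                "units": "px/frame",
                "channels": ["x", "y"],
            },
            fh,
            indent=2,
        )


def load_flow(path_prefix: str) -> FlowSequence:
    import json

    with open(f"{path_prefix}.json") as fh:
        meta = json.load(fh)
    fields = np.load(f"{path_prefix}.npy")
    return FlowSequence(fields=fields, fps=float(meta["fps"]))
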