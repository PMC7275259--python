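"""Event → fixed 10-s windows, and window votes → event label.

An annotated apnea event of duration D seconds is cut into 10-s windows
(20 flow frames at 2 Hz) starting 5 s before the event and ending 5 s
after it.  During training the stride is label-dependent — 1 s for CA,
5 s for OA — which rebalances the window counts of the rarer CA class;
at test time the stride is always 1 s and a majority vote over the window
probabilities yields the event label.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .flowproc import FlowSequence

__all__ = [
    "ApneaEvent",
    "Window",
    "WindowSet",
    "EventPrediction",
    "make_windows",
    "vote",
    "window_count",
    "WINDOW_SECONDS",
    "MIN_EVENT_SECONDS",
]

WINDOW_SECONDS = 10.0
MIN_EVENT_SECONDS = 10.0
LEAD_SECONDS = 5.0  # windows start this far before the event and end this far after

LABELS = ("OA", "CA")
#: CA is the positive class throughout the package.
POSITIVE_LABEL = "CA"


@dataclass(frozen=True)
class ApneaEvent:
    """One annotated apnea interval."""

    recording_id: str
    start: float
    end: float
    label: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.end - self.start < MIN_EVENT_SECONDS:
            raise ValueError(
                f"apneas last >= {MIN_EVENT_SECONDS:.0f} s; got {self.end - self.start:.2f} s"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def y(self) -> int:
        return int(self.label == POSITIVE_LABEL)


@dataclass(frozen=True)
class Window:
    start: float  # seconds, recording clock
    tensor: np.ndarray  # (H, W, T, C)


@dataclass
class WindowSet:
    windows: list[Window]
    label: str
    event: ApneaEvent

    def tensors(self) -> np.ndarray:
        return np.stack([w.tensor for w in self.windows])

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class EventPrediction:
    probabilities: list[float]
    label: str
    margin: float
    event: ApneaEvent | None = None


def window_count(duration: float, stride: float) -> int:
    """floor(duration/stride) + 1 — the number of 10-s windows in an event."""
    return int(math.floor(duration / stride + 1e-9)) + 1


def make_windows(
    event: ApneaEvent,
    flow: FlowSequence,
    stride: float,
    mode: str = "train",
) -> WindowSet:
    """Cut an event's flow into 10-s windows.

    Window starts run from ``event.start - 5`` in steps of ``stride`` while
    the window end stays within ``event.end + 5``.  In test mode the stride
    is forced to 1 s.  Start times are snapped to the frame grid by
    flooring.  The flow must cover the padded event span.
    """
    if mode not in ("train", "test"):
        raise ValueError(f"mode must be 'train' or 'test', got {mode!r}")
    if mode == "test":
        stride = 1.0
    else:
        if stride not in (1.0, 5.0, 1, 5):
            raise ValueError("training stride must be 1 s (CA) or 5 s (OA)")
        if event.label == "OA" and stride == 1:
            warnings.warn(
                "OA event windowed with stride 1 in train mode (protocol uses 5 s)",
                stacklevel=2,
            )

    fps = flow.fps
    n_frames = int(round(WINDOW_SECONDS * fps))
    count = window_count(event.duration, stride)
    windows = []
    for i in range(count):
        t0 = event.start - LEAD_SECONDS + i * stride
        i0 = int(math.floor(t0 * fps + 1e-9))
        if i0 < 0 or i0 + n_frames > flow.n_fields:
            raise ValueError(
                f"flow does not cover window [{t0:.1f}, {t0 + WINDOW_SECONDS:.1f}] s "
                f"of event [{event.start}, {event.end}] (need frames "
                f"{i0}..{i0 + n_frames}, have {flow.n_fields})"
            )
        tensor = np.moveaxis(flow.fields[i0 : i0 + n_frames], 0, 2)  # (H, W, T, C)
        windows.append(Window(start=t0, tensor=tensor))
    return WindowSet(windows=windows, label=event.label, event=event)


def vote(probabilities: list[float], event: ApneaEvent | None = None) -> EventPrediction:
    """Majority vote over thresholded (0.5) window probabilities.

    CA wins when CA-positive windows are the strict majority; ties are
    broken by the mean probability vs 0.5, with OA on exact equality.
    The margin is the absolute vote difference over the window count.
    """
    probs = [float(p) for p in probabilities]
    if not probs:
        raise ValueError("cannot vote over an empty probability list")
    if any(not (0.0 <= p <= 1.0) for p in probs):
        raise ValueError("probabilities must lie in [0, 1]")
    ca_votes = sum(p > 0.5 for p in probs)
    oa_votes = len(probs) - ca_votes
    if ca_votes != oa_votes:
        label = "CA" if ca_votes > oa_votes else "OA"
    else:
        label = "CA" if float(np.mean(probs)) > 0.5 else "OA"
    margin = abs(ca_votes - oa_votes) / len(probs)
    return EventPrediction(probabilities=probs, label=label, margin=margin, event=event)
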