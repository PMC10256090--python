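"""Fixed-grid window segmentation with a flexible final overlap.

Recordings are cut into windows of fixed length (0.4 s default) starting at
multiples of ``window_len - nominal_overlap``; the last window is anchored to
end exactly at the recording end so every source sample is used, which may
enlarge its overlap with the previous window (a 0.6 s signal becomes two
0.4 s windows overlapping by 0.2 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from beeradar.sim import CLASSES, EventTimeline, IQRecording

#: Event-label priority used when a window overlaps several events; higher
#: wins.  Inward and outward rank equally above hover; ties are broken by
#: larger overlap duration, then earlier event start.
DEFAULT_PRIORITY: dict[str, int] = {"inward": 2, "outward": 2, "hover": 1}


@dataclass(frozen=True)
class SegmentationSpec:
    window_len: float = 0.4
    nominal_overlap: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.nominal_overlap < self.window_len):
            raise ValueError("require 0 <= nominal_overlap < window_len")


@dataclass
class WindowSample:
    """One fixed-length two-channel excerpt with provenance and a class label."""

    samples: np.ndarray  # complex, length = window_len * sample_rate
    sample_rate: float
    start: float
    end: float
    label: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("window start must be >= 0")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def i(self) -> np.ndarray:
        return self.samples.real

    @property
    def q(self) -> np.ndarray:
        return self.samples.imag


def window_starts(n_samples: int, window: int, step: int) -> list[int]:
    """Start indices: multiples of ``step``, plus a final window ending at
    the last sample.  Half-open index spans ``[s, s + window)``."""
    if n_samples < window:
        raise ValueError(
            f"recording of {n_samples} samples is shorter than one window "
            f"({window} samples); 0.4 s is the minimal event"
        )
    last = n_samples - window
    starts = list(range(0, last, step))
    starts.append(last)
    return starts


def segment(
    recording: IQRecording,
    spec: SegmentationSpec = SegmentationSpec(),
    source_id: str = "",
) -> list[WindowSample]:
    """Split a recording into overlapping fixed-length windows.

    Raises ``ValueError`` if the recording is shorter than one window.
    """
    fs = recording.sample_rate
    window = int(round(spec.window_len * fs))
    step = int(round((spec.window_len - spec.nominal_overlap) * fs))
    out = []
    for s in window_starts(len(recording), window, step):
        out.append(
            WindowSample(
                samples=recording.samples[s : s + window],
                sample_rate=fs,
                start=s / fs,
                end=(s + window) / fs,
                source_id=source_id,
            )
        )
    return out


def label_window(
    window: WindowSample,
    timeline: EventTimeline,
    priority: dict[str, int] | None = None,
) -> str:
    """Assign one class label to a window from the ground-truth timeline.

    A window overlapping no event is ``background``; otherwise the label of
    the highest-priority overlapping event, ties broken by larger overlap
    duration and then earlier event start.  Pure function of its inputs.
    """
    prio = DEFAULT_PRIORITY if priority is None else priority
    best = None
    for ev in timeline.events:
        overlap = min(window.end, ev.end) - max(window.start, ev.start)
        if overlap <= 0:
            continue
        key = (prio.get(ev.label, 0), overlap, -ev.start)
        if best is None or key > best[0]:
            best = (key, ev.label)
    return "background" if best is None else best[1]


def segment_and_label(
    recording: IQRecording,
    timeline: EventTimeline,
    spec: SegmentationSpec = SegmentationSpec(),
    source_id: str = "",
    priority: dict[str, int] | None = None,
) -> list[WindowSample]:
    """Convenience composition of :func:`segment` and :func:`label_window`."""
    windows = segment(recording, spec, source_id)
    for w in windows:
        w.label = label_window(w, timeline, priority)
    return windows
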