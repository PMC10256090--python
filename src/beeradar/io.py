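"""File formats: two-channel IQ WAV, event-timeline CSV, feature tables.

Channel convention for WAV files: channel 0 = I, channel 1 = Q.  Timelines
are CSVs with header ``label,start_s,end_s`` (seconds, time origin 0 at
recording start, half-open intervals).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from beeradar.sim import (
    CLASSES,
    FLIGHT_CLASSES,
    Event,
    EventTimeline,
    IQRecording,
    MotionProfile,
)

_INT_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31}


def read_iq_wav(path: str | Path) -> IQRecording:
    """Read a 2-channel WAV as an IQ recording (channel 0 = I, channel 1 = Q).

    Integer PCM is normalized to [-1, 1]; float data is taken as-is.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 2 or data.shape[1] != 2:
        n_ch = 1 if data.ndim == 1 else data.shape[1]
        raise ValueError(
            f"{path}: expected a 2-channel WAV (channel 0 = I, channel 1 = Q), "
            f"got {n_ch} channel(s)"
        )
    if data.dtype in _INT_SCALE:
        data = data.astype(np.float64) / _INT_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    return IQRecording(data[:, 0] + 1j * data[:, 1], float(rate))


def write_iq_wav(
    path: str | Path, recording: IQRecording, dtype: str = "float32"
) -> None:
    """Write an IQ recording as a 2-channel WAV (float32 or int16)."""
    stereo = np.column_stack([recording.i, recording.q])
    if dtype == "float32":
        wavfile.write(path, int(round(recording.sample_rate)), stereo.astype(np.float32))
    elif dtype == "int16":
        peak = np.abs(stereo).max()
        if peak > 1.0:
            stereo = stereo / peak
        wavfile.write(
            path,
            int(round(recording.sample_rate)),
            np.clip(np.round(stereo * 32768), -32768, 32767).astype(np.int16),
        )
    else:
        raise ValueError("dtype must be 'float32' or 'int16'")


def _placeholder_motion(label: str, duration: float) -> MotionProfile:
    # CSV timelines carry only (label, start, end); the motion profile is a
    # constant-range stand-in sufficient for window labeling.
    return MotionProfile(label, lambda t: np.full_like(np.asarray(t, float), 1.0), duration)


def read_timeline_csv(
    path: str | Path, total_duration: float | None = None
) -> EventTimeline:
    """Read a ``label,start_s,end_s`` CSV into a sorted timeline.

    Rows labelled ``background`` are accepted and skipped (absence of events
    already means background).  Unknown labels or ``end <= start`` are
    rejected with the offending line number.
    """
    events = []
    max_end = 0.0
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["label", "start_s", "end_s"]:
            raise ValueError(f"{path}: expected header 'label,start_s,end_s'")
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            label = row[0].strip()
            if label not in CLASSES:
                raise ValueError(
                    f"{path}:{lineno}: unknown label {label!r}; expected one of {CLASSES}"
                )
            try:
                start, end = float(row[1]), float(row[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}") from exc
            if end <= start or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}] (need 0 <= start < end)"
                )
            max_end = max(max_end, end)
            if label == "background":
                continue
            events.append(
                Event(label, start, end, _placeholder_motion(label, end - start))
            )
    if total_duration is None:
        total_duration = max_end
    return EventTimeline(events, total_duration)


def write_timeline_csv(path: str | Path, timeline: EventTimeline) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "start_s", "end_s"])
        for ev in timeline.events:
            writer.writerow([ev.label, repr(ev.start), repr(ev.end)])


def write_manifest_csv(path: str | Path, rows: list[dict]) -> None:
    """Window manifest: ``window_id,start_s,end_s,label``."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["window_id", "start_s", "end_s", "label"])
        writer.writeheader()
        writer.writerows(rows)


__all__ = [
    "read_iq_wav",
    "write_iq_wav",
    "read_timeline_csv",
    "write_timeline_csv",
    "write_manifest_csv",
    "FLIGHT_CLASSES",
]
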