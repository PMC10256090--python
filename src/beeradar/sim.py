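"""Synthesis of 5.8 GHz CW-radar IQ recordings of bee flights and clutter.

The scattering model is a two-component phase return: a body term at range
``R(t)`` and a wing term whose range is harmonically modulated by the wingbeat,

    x(t) = A1 * exp(-j*(4*pi/lambda)*R(t))
         + A2 * exp(-j*(4*pi/lambda)*(R(t) + AH*cos(wH*t)))

The I channel (real part) is the classic real cosine-sum return; the Q channel
supplies the quadrature component so that approaching targets map to positive
frequencies of the complex spectrum and receding targets to negative ones.
Clutter (wind shake of the radar, mechanical vibration coupling) reuses the
same model with the body term removed (``A1 = 0``) and the range harmonically
modulated.  A modeled receiver chain applies the first-order 408 Hz IF
low-pass, broadband noise and an optional narrowband equipment tone near
1 kHz.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

SPEED_OF_LIGHT = 299_792_458.0

#: Canonical class vocabulary, in the fixed order used throughout the package.
CLASSES = ("background", "hover", "inward", "outward")
FLIGHT_CLASSES = ("inward", "outward", "hover")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RadarConfig:
    """Physical constants of the radar front end and receiver chain."""

    carrier_frequency: float = 5.8e9
    if_cutoff: float = 408.0
    sample_rate: float = 44100.0
    noise_rms: float = 0.0
    tone_1khz_amplitude: float = 0.0
    tone_1khz_freq: float = 1000.0
    ac_coupling_hz: float = 2.0  # sound-card input high-pass; 0 disables
    recording_noise_rms: float = 0.0  # wideband floor added after the IF chain

    def __post_init__(self) -> None:
        if self.carrier_frequency <= 0:
            raise ValueError("carrier_frequency must be positive")
        if self.sample_rate <= 2 * self.if_cutoff:
            raise ValueError(
                f"sample_rate ({self.sample_rate}) must exceed twice the IF "
                f"cutoff ({self.if_cutoff})"
            )
        if min(self.noise_rms, self.tone_1khz_amplitude, self.recording_noise_rms) < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength in metres (~0.0517 m at 5.8 GHz)."""
        return SPEED_OF_LIGHT / self.carrier_frequency


@dataclass(frozen=True)
class WingbeatSpec:
    """Harmonic wing motion: displacement amplitude (m) and angular frequency (rad/s)."""

    amplitude: float = 0.01
    angular_frequency: float = 2 * math.pi * 190.0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.angular_frequency < 0:
            raise ValueError("wingbeat amplitude and frequency must be non-negative")

    @property
    def frequency_hz(self) -> float:
        return self.angular_frequency / (2 * math.pi)


@dataclass(frozen=True)
class ScattererSpec:
    """Scalar scattering amplitudes of the body and wing components."""

    body_amplitude: float = 1.0
    wing_amplitude: float = 0.2

    def __post_init__(self) -> None:
        if self.body_amplitude < 0 or self.wing_amplitude < 0:
            raise ValueError("scattering amplitudes must be non-negative")


@dataclass(frozen=True)
class MotionProfile:
    """Radial trajectory R(t) of one scatterer over the event duration.

    ``range_fn`` maps an array of times in ``[0, duration]`` seconds to ranges
    in metres.
    """

    class_label: str
    range_fn: Callable[[np.ndarray], np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        if self.class_label not in FLIGHT_CLASSES:
            raise ValueError(
                f"unknown class label {self.class_label!r}; "
                f"expected one of {FLIGHT_CLASSES}"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def sample(self, sample_rate: float) -> np.ndarray:
        """Evaluate R(t) on the uniform sampling grid of the event."""
        n = int(round(self.duration * sample_rate))
        t = np.arange(n) / sample_rate
        return np.asarray(self.range_fn(t), dtype=float)


@dataclass(frozen=True)
class ClutterSpec:
    """Non-target return: wind shake of the radar or vibration coupling.

    Modeled with the body term absent and range harmonically modulated with
    displacement ``amplitude`` (m) at ``frequency`` (rad/s).
    """

    kind: str
    amplitude: float
    frequency: float
    a2: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("wind", "vibration"):
            raise ValueError(f"unknown clutter kind {self.kind!r}")
        f_hz = self.frequency / (2 * math.pi)
        if self.kind == "wind" and f_hz > 5.0 + 1e-9:
            raise ValueError("wind clutter frequency must be <= 5 Hz")
        if self.kind == "vibration" and abs(f_hz - 50.0) > 1e-6:
            raise ValueError("vibration clutter frequency must be 50 Hz")
        if self.amplitude < 0 or self.a2 < 0:
            raise ValueError("clutter amplitudes must be non-negative")


@dataclass(frozen=True)
class Event:
    """One labelled flight event placed on the recording timeline."""

    label: str
    start: float
    end: float
    motion: MotionProfile
    scatterer: ScattererSpec = field(default_factory=ScattererSpec)
    wingbeat: WingbeatSpec = field(default_factory=WingbeatSpec)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("event must satisfy 0 <= start < end")
        if abs(self.motion.duration - (self.end - self.start)) > 1e-9:
            raise ValueError("motion.duration must equal end - start")


@dataclass
class EventTimeline:
    """Ground-truth event list plus scene-wide clutter sources."""

    events: list[Event]
    total_duration: float
    clutter: list[ClutterSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.start, e.end))
        for ev in self.events:
            if ev.end > self.total_duration + 1e-9:
                raise ValueError(
                    f"event [{ev.start}, {ev.end}] extends past total_duration "
                    f"{self.total_duration}"
                )


@dataclass(frozen=True)
class IQRecording:
    """Complex baseband recording; I = real part, Q = imaginary part."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.complex128)
        )
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional complex")

    @property
    def i(self) -> np.ndarray:
        return self.samples.real

    @property
    def q(self) -> np.ndarray:
        return self.samples.imag

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# Flight kinematics
# ---------------------------------------------------------------------------

#: Default kinematic parameter ranges per class; every entry is a (low, high)
#: interval sampled uniformly.  These encode the qualitative class behaviours:
#: outward bees ramp up speed and pass close to the radar, inward bees
#: decelerate to rest near the hive entrance while receding from the radar,
#: hovering bees drift slowly with bounded oscillatory radial motion.
DEFAULT_KINEMATICS: dict[str, dict[str, tuple[float, float]]] = {
    "outward": {
        "v_max": (1.5, 1.95),  # peak speed, m/s
        "duration": (0.6, 1.1),
        "lateral_offset": (0.03, 0.08),  # closest-approach distance, m
    },
    "inward": {
        "v0": (0.4, 1.1),  # initial speed, m/s
        "duration": (0.6, 1.1),
        "entrance_range": (1.0, 2.0),  # final rest range, m
    },
    "hover": {
        "range0": (0.5, 1.5),
        "duration": (0.6, 1.1),
        "osc_amplitude": (0.003, 0.01),  # radial oscillation, m
        "osc_freq": (1.0, 4.0),  # Hz
        "drift_amplitude": (0.02, 0.06),
        "drift_freq": (0.1, 0.5),  # Hz
    },
}


#: Wingbeat-frequency bands per flight mode (Hz), all inside the species'
#: 150-230 Hz envelope.  Hovering bees beat slowest, accelerating outward
#: bees work hardest; the heavily overlapping bands mean the fundamental is
#: a weak class cue while the n-th harmonic spreads the differences n-fold.
DEFAULT_WINGBEAT_BANDS: dict[str, tuple[float, float]] = {
    "hover": (160.0, 200.0),
    "inward": (172.0, 212.0),
    "outward": (184.0, 224.0),
}


def draw_wingbeat(class_label: str, rng: np.random.Generator) -> WingbeatSpec:
    """Draw a class-consistent wingbeat: ~1 cm displacement, banded frequency."""
    lo, hi = DEFAULT_WINGBEAT_BANDS[class_label]
    return WingbeatSpec(
        amplitude=float(rng.uniform(0.008, 0.012)),
        angular_frequency=2 * math.pi * float(rng.uniform(lo, hi)),
    )


def _draw(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    return float(rng.uniform(*bounds))


def make_flight_profile(
    class_label: str,
    rng: np.random.Generator,
    kinematic_ranges: dict | None = None,
    duration: float | None = None,
) -> MotionProfile:
    """Draw a class-consistent radial trajectory R(t).

    Parameters
    ----------
    class_label : {"inward", "outward", "hover"}
    rng : seeded numpy Generator; all draws flow from it.
    kinematic_ranges : optional per-class overrides of
        :data:`DEFAULT_KINEMATICS` entries.
    duration : event duration in seconds; drawn from the class range if None.
    """
    if class_label not in FLIGHT_CLASSES:
        raise ValueError(
            f"unknown class label {class_label!r}; expected one of {FLIGHT_CLASSES}"
        )
    params = dict(DEFAULT_KINEMATICS[class_label])
    if kinematic_ranges and class_label in kinematic_ranges:
        params.update(kinematic_ranges[class_label])

    if duration is None:
        duration = _draw(rng, params["duration"])
    T = float(duration)

    if class_label == "outward":
        # Speed ramps as v(t) = v_max (t/T)^2 along a straight line that
        # passes the radar at lateral offset d; path position s(t) is the
        # integral, with closest approach placed at 90% of the event.
        v_max = _draw(rng, params["v_max"])
        d = _draw(rng, params["lateral_offset"])
        total_path = v_max * T / 3.0
        pass_frac = 0.9

        def range_fn(t: np.ndarray, _v=v_max, _T=T, _d=d, _S=total_path) -> np.ndarray:
            s = _S * (np.asarray(t) / _T) ** 3 - _S * pass_frac**3
            return np.sqrt(_d**2 + s**2) + 0.05

        return MotionProfile(class_label, range_fn, T)

    if class_label == "inward":
        # Speed ramps down as v(t) = v0 (1 - t/T)^2 while the bee recedes from
        # the radar, coming to rest at the hive-entrance range.
        v0 = _draw(rng, params["v0"])
        r_end = _draw(rng, params["entrance_range"])

        def range_fn(t: np.ndarray, _v=v0, _T=T, _r=r_end) -> np.ndarray:
            remaining = _v * _T * (1.0 - np.asarray(t) / _T) ** 3 / 3.0
            return _r - remaining

        return MotionProfile(class_label, range_fn, T)

    # hover: slow drift plus bounded oscillation; radial speed amplitude
    # 2*pi*f*a stays below 0.5 m/s for the default ranges.
    r0 = _draw(rng, params["range0"])
    a_osc = _draw(rng, params["osc_amplitude"])
    f_osc = _draw(rng, params["osc_freq"])
    a_drift = _draw(rng, params["drift_amplitude"])
    f_drift = _draw(rng, params["drift_freq"])
    phi1 = float(rng.uniform(0, 2 * math.pi))
    phi2 = float(rng.uniform(0, 2 * math.pi))

    def range_fn(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t)
        return (
            r0
            + a_drift * np.sin(2 * math.pi * f_drift * t + phi1)
            + a_osc * np.sin(2 * math.pi * f_osc * t + phi2)
        )

    return MotionProfile(class_label, range_fn, T)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------


def synthesize_event(event: Event, radar_config: RadarConfig) -> IQRecording:
    """Render one flight event as complex baseband IQ at the configured rate.

    The I channel alone reproduces the real cosine-sum return; the complex
    form additionally discriminates approach (positive frequencies) from
    recession (negative frequencies).
    """
    fs = radar_config.sample_rate
    lam = radar_config.wavelength
    f_wing = event.wingbeat.frequency_hz
    if f_wing > fs / 2:
        logger.warning(
            "wingbeat frequency %.1f Hz exceeds Nyquist %.1f Hz; line will alias",
            f_wing,
            fs / 2,
        )
    n = int(round(event.motion.duration * fs))
    t = np.arange(n) / fs
    r = np.asarray(event.motion.range_fn(t), dtype=float)
    k = 4.0 * math.pi / lam
    wing_range = r + event.wingbeat.amplitude * np.cos(
        event.wingbeat.angular_frequency * t
    )
    x = event.scatterer.body_amplitude * np.exp(-1j * k * r)
    x = x + event.scatterer.wing_amplitude * np.exp(-1j * k * wing_range)
    return IQRecording(x, fs)


def synthesize_clutter(
    clutter_spec: ClutterSpec,
    radar_config: RadarConfig,
    duration: float,
    base_range: float = 1.0,
) -> IQRecording:
    """Render a clutter source: harmonically modulated range, no body term."""
    fs = radar_config.sample_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    k = 4.0 * math.pi / radar_config.wavelength
    r = base_range + clutter_spec.amplitude * np.cos(clutter_spec.frequency * t)
    x = clutter_spec.a2 * np.exp(-1j * k * r)
    return IQRecording(x, fs)


def _if_lowpass(radar_config: RadarConfig):
    return sps.butter(
        1, radar_config.if_cutoff, btype="low", fs=radar_config.sample_rate
    )


def apply_receiver_chain(
    iq: IQRecording,
    radar_config: RadarConfig,
    rng: np.random.Generator | None = None,
) -> IQRecording:
    """Model the receiver: amplifier noise, the 408 Hz first-order IF
    low-pass, AC coupling of the sound-card input, and the faint narrowband
    equipment tone near 1 kHz.

    Noise at ``noise_rms`` is added before the IF low-pass (it originates in
    the VGAs, so the filter bounds it to the ~DC-408 Hz range); the tone and
    the wideband ``recording_noise_rms`` floor are added after (they come
    from the recording equipment).  With all stochastic amplitudes zero no
    randomness is consumed.
    """
    x = iq.samples
    if radar_config.noise_rms > 0:
        if rng is None:
            raise ValueError("noise_rms > 0 requires an rng")
        noise = rng.normal(scale=radar_config.noise_rms, size=(2, len(x)))
        x = x + noise[0] + 1j * noise[1]
    b, a = _if_lowpass(radar_config)
    x = sps.lfilter(b, a, x)
    if radar_config.ac_coupling_hz > 0:
        bh, ah = sps.butter(
            1, radar_config.ac_coupling_hz, btype="high", fs=radar_config.sample_rate
        )
        x = sps.lfilter(bh, ah, x)
    if radar_config.tone_1khz_amplitude > 0:
        if rng is None:
            raise ValueError("tone_1khz_amplitude > 0 requires an rng")
        phi = rng.uniform(0, 2 * math.pi)
        t = np.arange(len(x)) / iq.sample_rate
        x = x + radar_config.tone_1khz_amplitude * np.exp(
            1j * (2 * math.pi * radar_config.tone_1khz_freq * t + phi)
        )
    if radar_config.recording_noise_rms > 0:
        if rng is None:
            raise ValueError("recording_noise_rms > 0 requires an rng")
        floor = rng.normal(scale=radar_config.recording_noise_rms, size=(2, len(x)))
        x = x + floor[0] + 1j * floor[1]
    return IQRecording(x, iq.sample_rate)


def random_timeline(
    rng: np.random.Generator,
    total_duration: float,
    events_per_class: int = 5,
    wind: bool = True,
    vibration: bool = False,
    min_event: float = 0.4,
) -> EventTimeline:
    """Draw a random scene: events of every flight class at random starts
    (overlaps allowed, as at a busy hive entrance) plus optional clutter."""
    events = []
    for label in FLIGHT_CLASSES:
        for _ in range(events_per_class):
            profile = make_flight_profile(label, rng)
            dur = max(min_event, profile.duration)
            start = float(rng.uniform(0, max(total_duration - dur, 0)))
            wing = draw_wingbeat(label, rng)
            events.append(Event(label, start, start + profile.duration, profile, wingbeat=wing))
    clutter = []
    if wind:
        clutter.append(
            ClutterSpec(
                "wind",
                amplitude=float(rng.uniform(0.001, 0.01)),
                frequency=2 * math.pi * float(rng.uniform(0.5, 5.0)),
                a2=0.3,
            )
        )
    if vibration:
        clutter.append(
            ClutterSpec("vibration", amplitude=0.001, frequency=2 * math.pi * 50.0, a2=0.2)
        )
    return EventTimeline(events, total_duration, clutter)


def compose_scene(
    timeline: EventTimeline,
    radar_config: RadarConfig,
    seed: int,
) -> tuple[IQRecording, EventTimeline]:
    """Superpose all events and clutter of a timeline and run the receiver chain.

    Deterministic given the seed; returns the recording together with the
    unchanged ground-truth timeline.
    """
    fs = radar_config.sample_rate
    n_total = int(round(timeline.total_duration * fs))
    x = np.zeros(n_total, dtype=np.complex128)
    for ev in timeline.events:
        rec = synthesize_event(ev, radar_config)
        i0 = int(round(ev.start * fs))
        i1 = min(i0 + len(rec), n_total)
        x[i0:i1] += rec.samples[: i1 - i0]
    for cl in timeline.clutter:
        rec = synthesize_clutter(cl, radar_config, timeline.total_duration)
        x[: len(rec)] += rec.samples[:n_total]
    rng = np.random.default_rng(seed)
    out = apply_receiver_chain(IQRecording(x, fs), radar_config, rng)
    return out, timeline
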