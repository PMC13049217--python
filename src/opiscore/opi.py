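"""Objective performance indicators computed from kinematic and event streams.

Six metrics are produced per performance: speed peaks (smoothness), angular
path length (wrist articulation), linear path length (instrument movement),
idle time (instrument active time), energy proportion (energy usage), and
clutch count (clutching). Units are fixed: millimetres, radians, seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
from scipy import signal

from ._quat import geodesic_angles
from .errors import InsufficientDataError, InvalidArgumentError, InvalidDataError

if TYPE_CHECKING:  # pragma: no cover
    from .synth import EventStream, KinematicStream

#: Canonical metric names, in rubric-category order (items 7..12).
METRIC_NAMES = (
    "energy_proportion",
    "clutch_count",
    "linear_path_length_mm",
    "angular_path_length_rad",
    "speed_peaks",
    "idle_time_s",
)

_QUAT_NORM_TOL = 1e-6


@dataclass(frozen=True)
class OpiConfig:
    """Signal-processing parameters for OPI extraction.

    ``peak_min_prominence_mm_s=None`` selects the adaptive default of 10%
    of the 95th percentile of the smoothed speed profile.
    """

    smoothing_cutoff_hz: float = 5.0
    peak_min_prominence_mm_s: float | None = None
    idle_speed_threshold_mm_s: float = 1.0
    idle_min_dwell_s: float = 0.5

    def __post_init__(self) -> None:
        if self.smoothing_cutoff_hz <= 0:
            raise InvalidArgumentError("smoothing_cutoff_hz must be positive")
        if self.peak_min_prominence_mm_s is not None and self.peak_min_prominence_mm_s <= 0:
            raise InvalidArgumentError("peak_min_prominence_mm_s must be positive")
        if self.idle_speed_threshold_mm_s <= 0:
            raise InvalidArgumentError("idle_speed_threshold_mm_s must be positive")
        if self.idle_min_dwell_s <= 0:
            raise InvalidArgumentError("idle_min_dwell_s must be positive")


@dataclass(frozen=True)
class OpiVector:
    """The six OPI values for one performance."""

    speed_peaks: int
    angular_path_length_rad: float
    linear_path_length_mm: float
    idle_time_s: float
    energy_proportion: float
    clutch_count: int

    def __post_init__(self) -> None:
        if self.speed_peaks < 0 or self.clutch_count < 0:
            raise InvalidArgumentError("counts must be non-negative")
        if self.angular_path_length_rad < 0 or self.linear_path_length_mm < 0:
            raise InvalidArgumentError("path lengths must be non-negative")
        if self.idle_time_s < 0:
            raise InvalidArgumentError("idle_time_s must be non-negative")
        if not 0.0 <= self.energy_proportion <= 1.0:
            raise InvalidArgumentError("energy_proportion must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {
            "energy_proportion": self.energy_proportion,
            "clutch_count": float(self.clutch_count),
            "linear_path_length_mm": self.linear_path_length_mm,
            "angular_path_length_rad": self.angular_path_length_rad,
            "speed_peaks": float(self.speed_peaks),
            "idle_time_s": self.idle_time_s,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "OpiVector":
        return cls(
            speed_peaks=int(round(d["speed_peaks"])),
            angular_path_length_rad=float(d["angular_path_length_rad"]),
            linear_path_length_mm=float(d["linear_path_length_mm"]),
            idle_time_s=float(d["idle_time_s"]),
            energy_proportion=float(d["energy_proportion"]),
            clutch_count=int(round(d["clutch_count"])),
        )


def speed_profile(stream: "KinematicStream", config: OpiConfig | None = None) -> np.ndarray:
    """Smoothed linear-speed series (mm/s), one value per sample interval.

    Finite-difference speeds are low-pass filtered (zero-phase, 2nd-order
    Butterworth at ``smoothing_cutoff_hz``) so that tremor-scale jitter does
    not dominate peak counting.
    """
    config = config or OpiConfig()
    if len(stream.t) < 2:
        raise InsufficientDataError("speed profile needs at least 2 samples")
    dt = np.diff(stream.t)
    step = np.linalg.norm(np.diff(stream.pos, axis=0), axis=1)
    raw = step / dt
    fs = 1.0 / float(np.median(dt))
    nyq = 0.5 * fs
    if config.smoothing_cutoff_hz >= nyq:
        return raw
    b, a = signal.butter(2, config.smoothing_cutoff_hz / nyq, btype="low")
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(raw) <= padlen:
        return raw
    return np.asarray(signal.filtfilt(b, a, raw))


def count_speed_peaks(speed: np.ndarray, config: OpiConfig | None = None) -> int:
    """Number of local maxima with prominence above the configured floor."""
    config = config or OpiConfig()
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0:
        raise InsufficientDataError("speed series is empty")
    prom = config.peak_min_prominence_mm_s
    if prom is None:
        prom = 0.1 * float(np.percentile(speed, 95))
        if prom <= 0:
            return 0
    peaks, _ = signal.find_peaks(speed, prominence=prom)
    return int(peaks.size)


def linear_path_length(stream: "KinematicStream") -> float:
    """Total 3D distance travelled by the instrument tip (mm)."""
    if len(stream.t) < 2:
        raise InsufficientDataError("path length needs at least 2 samples")
    return float(np.linalg.norm(np.diff(stream.pos, axis=0), axis=1).sum())


def angular_path_length(stream: "KinematicStream") -> float:
    """Total rotational distance (rad), summed over consecutive orientations.

    Invariant to the sign convention of individual quaternions.
    """
    if len(stream.t) < 2:
        raise InsufficientDataError("angular path needs at least 2 samples")
    norms = np.linalg.norm(stream.quat, axis=1)
    if np.any(np.abs(norms - 1.0) > _QUAT_NORM_TOL):
        raise InvalidDataError("non-unit quaternion beyond tolerance")
    return float(geodesic_angles(stream.quat).sum())


def idle_time(speed: np.ndarray, t: np.ndarray, config: OpiConfig | None = None) -> float:
    """Total duration (s) of sub-threshold segments lasting at least the dwell."""
    config = config or OpiConfig()
    speed = np.asarray(speed, dtype=float)
    t = np.asarray(t, dtype=float)
    if speed.size != t.size - 1:
        raise InvalidArgumentError("speed series must align with t intervals")
    dt = np.diff(t)
    idle = speed < config.idle_speed_threshold_mm_s
    total = 0.0
    run = 0.0
    for flag, d in zip(idle, dt):
        if flag:
            run += d
        else:
            if run >= config.idle_min_dwell_s:
                total += run
            run = 0.0
    if run >= config.idle_min_dwell_s:
        total += run
    return total


def energized_intervals(events: "EventStream") -> list[tuple[float, float]]:
    """(on, off) pairs from an alternating energy event sequence."""
    intervals: list[tuple[float, float]] = []
    on_time: float | None = None
    for t, kind in events.events:
        if kind == "energy_on":
            if on_time is not None:
                raise InvalidDataError("energy_on without matching energy_off")
            on_time = t
        elif kind == "energy_off":
            if on_time is None:
                raise InvalidDataError("energy_off without preceding energy_on")
            intervals.append((on_time, t))
            on_time = None
    if on_time is not None:
        raise InvalidDataError("unmatched trailing energy_on")
    return intervals


def energy_proportion(events: "EventStream", active_time_s: float) -> float:
    """Energized time divided by active time, clipped to [0, 1]."""
    if active_time_s <= 0:
        raise InvalidArgumentError("active_time_s must be positive")
    energized = sum(off - on for on, off in energized_intervals(events))
    return float(np.clip(energized / active_time_s, 0.0, 1.0))


def clutch_count(events: "EventStream") -> int:
    return sum(1 for _, kind in events.events if kind == "clutch")


def extract_opis(
    stream: "KinematicStream",
    events: "EventStream",
    config: OpiConfig | None = None,
) -> OpiVector:
    """All six OPIs for one performance, mutually consistent.

    Active time is the task duration minus idle time; it is the denominator
    of the energy proportion. A fully idle stream has zero active time, in
    which case the energy proportion is 0 when no energy was applied and 1
    otherwise.
    """
    config = config or OpiConfig()
    speed = speed_profile(stream, config)
    idle = idle_time(speed, stream.t, config)
    duration = float(stream.t[-1] - stream.t[0])
    active = duration - idle
    if active > 0:
        energy = energy_proportion(events, active)
    else:
        energy = 1.0 if energized_intervals(events) else 0.0
    return OpiVector(
        speed_peaks=count_speed_peaks(speed, config),
        angular_path_length_rad=angular_path_length(stream),
        linear_path_length_mm=linear_path_length(stream),
        idle_time_s=idle,
        energy_proportion=energy,
        clutch_count=clutch_count(events),
    )


def extract_opis_pooled(
    streams: Sequence["KinematicStream"],
    events: "EventStream",
    config: OpiConfig | None = None,
) -> OpiVector:
    """Pool per-instrument metrics for a multi-instrument recording.

    Counts, path lengths and idle time are summed across instruments; active
    time is duration-minus-idle summed per instrument; the energy proportion
    uses that pooled active time with the union of energized intervals.
    """
    if not streams:
        raise InvalidArgumentError("at least one stream required")
    config = config or OpiConfig()
    peaks = 0
    ang = lin = idle = active = 0.0
    for stream in streams:
        speed = speed_profile(stream, config)
        peaks += count_speed_peaks(speed, config)
        ang += angular_path_length(stream)
        lin += linear_path_length(stream)
        this_idle = idle_time(speed, stream.t, config)
        idle += this_idle
        active += float(stream.t[-1] - stream.t[0]) - this_idle
    if active > 0:
        energy = energy_proportion(events, active)
    else:
        energy = 1.0 if energized_intervals(events) else 0.0
    return OpiVector(
        speed_peaks=peaks,
        angular_path_length_rad=ang,
        linear_path_length_mm=lin,
        idle_time_s=idle,
        energy_proportion=energy,
        clutch_count=clutch_count(events),
    )
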