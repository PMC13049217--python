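"""Synthetic data generation: kinematic/event streams, Rasch response
matrices, and a reference cohort matching the study's printed counts.

Trajectories are sums of minimum-jerk submovements along random 3D
directions, with additive Gaussian tremor and stationary pauses; orientation
advances about a slowly drifting axis in proportion to translation. This
gives smooth-vs-jerky contrast that the speed-peak and path-length metrics
can detect, with closed-form per-submovement peak speed 1.875·D/T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _quat
from .errors import InvalidArgumentError
from .scoring import ItemResponseMatrix, VideoOutcome

_AXIS_DRIFT_SD = 0.05  # per-step axis random-walk scale (dimensionless)
_SUBMOVE_T_RANGE = (0.4, 0.8)  # submovement duration range, seconds
_ENERGY_CYCLE_S = 10.0  # mean on+off renewal cycle length, seconds


@dataclass(frozen=True)
class SkillProfile:
    """Generator knobs for one skill archetype; all rates non-negative."""

    submovement_rate: float
    submovement_amplitude_mm: float
    tremor_sd_mm: float
    pause_rate_per_min: float
    pause_mean_s: float
    energy_duty: float
    clutch_rate_per_min: float
    rotation_gain_rad_per_mm: float

    def __post_init__(self) -> None:
        for name in (
            "submovement_rate",
            "submovement_amplitude_mm",
            "tremor_sd_mm",
            "pause_rate_per_min",
            "pause_mean_s",
            "clutch_rate_per_min",
            "rotation_gain_rad_per_mm",
        ):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be non-negative")
        if not 0.0 <= self.energy_duty <= 1.0:
            raise InvalidArgumentError("energy_duty must lie in [0, 1]")


EXPERT_PROFILE = SkillProfile(
    submovement_rate=1.0,
    submovement_amplitude_mm=15.0,
    tremor_sd_mm=0.05,
    pause_rate_per_min=1.0,
    pause_mean_s=1.0,
    energy_duty=0.15,
    clutch_rate_per_min=0.5,
    rotation_gain_rad_per_mm=0.02,
)

NOVICE_PROFILE = SkillProfile(
    submovement_rate=3.0,
    submovement_amplitude_mm=12.0,
    tremor_sd_mm=0.4,
    pause_rate_per_min=6.0,
    pause_mean_s=2.5,
    energy_duty=0.35,
    clutch_rate_per_min=3.0,
    rotation_gain_rad_per_mm=0.05,
)


@dataclass
class KinematicStream:
    """Instrument pose series: strictly increasing time, 3D tip position
    (mm), scalar-first unit quaternions."""

    t: np.ndarray
    pos: np.ndarray
    quat: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        n = self.t.shape[0]
        if self.pos.shape != (n, 3) or self.quat.shape != (n, 4):
            raise InvalidArgumentError("t/pos/quat lengths must agree")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise InvalidArgumentError("t must be strictly increasing")

    def __len__(self) -> int:
        return self.t.shape[0]


@dataclass
class EventStream:
    """Timestamped console events; energy events strictly alternate."""

    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise InvalidArgumentError("event times must be non-decreasing")
        state = 0
        for _, kind in self.events:
            if kind == "energy_on":
                if state:
                    raise InvalidArgumentError("energy_on while already energized")
                state = 1
            elif kind == "energy_off":
                if not state:
                    raise InvalidArgumentError("energy_off without energy_on")
                state = 0
            elif kind != "clutch":
                raise InvalidArgumentError(f"unknown event kind {kind!r}")
        if state:
            raise InvalidArgumentError("unterminated energy_on")


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _pause_intervals(
    rng: np.random.Generator, profile: SkillProfile, duration_s: float
) -> list[tuple[float, float]]:
    k = rng.poisson(profile.pause_rate_per_min * duration_s / 60.0)
    if k == 0 or profile.pause_mean_s == 0:
        return []
    starts = np.sort(rng.uniform(0.0, duration_s, size=k))
    lengths = rng.exponential(profile.pause_mean_s, size=k)
    merged: list[tuple[float, float]] = []
    for s, d in zip(starts, lengths):
        e = min(s + d, duration_s)
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def simulate_trajectory(
    profile: SkillProfile,
    duration_s: float,
    rate_hz: float = 50.0,
    seed: int = 0,
) -> KinematicStream:
    """Seeded synthetic instrument trajectory.

    Submovement count is Poisson in active (non-pause) time; submovements
    are scheduled in an active-time coordinate so position is frozen during
    pauses. Tremor is added on active samples only.
    """
    if duration_s <= 0:
        raise InvalidArgumentError("duration_s must be positive")
    if rate_hz <= 0:
        raise InvalidArgumentError("rate_hz must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz

    pauses = _pause_intervals(rng, profile, duration_s)
    paused_before = np.zeros(n)
    active_mask = np.ones(n, dtype=bool)
    for s, e in pauses:
        inside = (t >= s) & (t < e)
        active_mask[inside] = False
        paused_before += np.clip(np.minimum(t, e) - s, 0.0, None) * (t >= s)
    a = t - paused_before  # active-time coordinate
    total_active = float(a[-1]) if n else 0.0

    pos = np.zeros((n, 3))
    m = rng.poisson(profile.submovement_rate * max(total_active, 0.0))
    if m > 0:
        starts = rng.uniform(0.0, max(total_active - _SUBMOVE_T_RANGE[0], 0.0), size=m)
        durs = rng.uniform(*_SUBMOVE_T_RANGE, size=m)
        amps = rng.gamma(2.0, profile.submovement_amplitude_mm / 2.0, size=m)
        dirs = rng.normal(size=(m, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for s0, T, D, u in zip(starts, durs, amps, dirs):
            pos += np.outer(D * _minimum_jerk((a - s0) / T), u)
    if profile.tremor_sd_mm > 0:
        tremor = rng.normal(scale=profile.tremor_sd_mm, size=(n, 3))
        pos[active_mask] += tremor[active_mask]

    # Orientation: incremental rotation about a slowly drifting axis,
    # magnitude proportional to translation.
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    drift = rng.normal(scale=_AXIS_DRIFT_SD, size=(max(n - 1, 0), 3))
    step_mm = np.linalg.norm(np.diff(pos, axis=0), axis=1) if n > 1 else np.empty(0)
    # lognormal jitter keeps angular path correlated with, but not a fixed
    # multiple of, linear path
    gain_jitter = np.exp(rng.normal(scale=0.3, size=max(n - 1, 0)))
    step_mm = step_mm * gain_jitter
    quat = np.empty((n, 4))
    quat[0] = _quat.IDENTITY
    q = _quat.IDENTITY.copy()
    for k in range(n - 1):
        axis = axis + drift[k]
        axis /= np.linalg.norm(axis)
        dq = _quat.from_axis_angle(axis, profile.rotation_gain_rad_per_mm * step_mm[k])
        q = _quat.normalize(_quat.qmul(dq, q))
        quat[k + 1] = q
    return KinematicStream(t=t, pos=pos, quat=quat)


def simulate_events(
    profile: SkillProfile, duration_s: float, seed: int = 0
) -> EventStream:
    """Seeded clutch (Poisson) and energy (alternating-renewal) events.

    Energized/idle interval lengths are exponential with means chosen so the
    long-run energized fraction equals ``energy_duty``; the process starts
    de-energized and any trailing burst is closed at ``duration_s``.
    """
    if duration_s <= 0:
        raise InvalidArgumentError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    events: list[tuple[float, str]] = []
    k = rng.poisson(profile.clutch_rate_per_min * duration_s / 60.0)
    events += [(float(tt), "clutch") for tt in np.sort(rng.uniform(0, duration_s, k))]
    duty = profile.energy_duty
    if duty > 0:
        mean_on = duty * _ENERGY_CYCLE_S
        mean_off = max((1.0 - duty) * _ENERGY_CYCLE_S, 1e-9)
        t = float(rng.exponential(mean_off))
        while t < duration_s:
            on = t
            off = min(on + float(rng.exponential(mean_on)), duration_s)
            events.append((on, "energy_on"))
            events.append((off, "energy_off"))
            t = off + float(rng.exponential(mean_off))
    events.sort(key=lambda e: (e[0], e[1] != "energy_on"))
    return EventStream(events=events)


def simulate_response_matrix(
    abilities: Sequence[float],
    difficulties: Sequence[float],
    seed: int = 0,
    subject_prefix: str = "sim",
) -> ItemResponseMatrix:
    """Binary matrix drawn from the dichotomous Rasch model.

    Entry (n, i) is Bernoulli with success probability
    ``exp(θn − δi) / (1 + exp(θn − δi))``.
    """
    theta = np.asarray(abilities, dtype=float)
    delta = np.asarray(difficulties, dtype=float)
    if theta.size == 0:
        raise InvalidArgumentError("abilities must be non-empty")
    if delta.size == 0:
        raise InvalidArgumentError("difficulties must be non-empty")
    rng = np.random.default_rng(seed)
    logits = theta[:, None] - delta[None, :]
    p = 1.0 / (1.0 + np.exp(-logits))
    scores = (rng.uniform(size=p.shape) < p).astype(np.int8)
    ids = [f"{subject_prefix}{n:05d}" for n in range(theta.size)]
    return ItemResponseMatrix(
        subject_ids=ids, scores=scores, gated_from=np.zeros(theta.size, dtype=int)
    )


@dataclass
class CohortRecord:
    subject_id: str
    role: str  # "trainee" | "expert"
    year: int
    stream: KinematicStream
    events: EventStream
    video: VideoOutcome
    group: str = ""


@dataclass
class Cohort:
    records: list[CohortRecord]

    @property
    def trainees(self) -> list[CohortRecord]:
        return [r for r in self.records if r.role == "trainee"]

    @property
    def experts(self) -> list[CohortRecord]:
        return [r for r in self.records if r.role == "expert"]


def _video_outcome(failure_mode: str, failed_item: int | None) -> VideoOutcome:
    if failure_mode == "none":
        return VideoOutcome(item_results=(1,) * 6, failure_mode="none")
    items = [1] * 6
    assert failed_item is not None
    for i in range(failed_item - 1, 6):
        items[i] = 0
    return VideoOutcome(item_results=tuple(items), failure_mode=failure_mode)


def _interp_profile(lam: float) -> SkillProfile:
    """Linear interpolation expert (λ=0) → novice (λ=1)."""
    kwargs = {}
    for name in SkillProfile.__dataclass_fields__:
        a = getattr(EXPERT_PROFILE, name)
        b = getattr(NOVICE_PROFILE, name)
        kwargs[name] = (1 - lam) * a + lam * b
    return SkillProfile(**kwargs)


def _jitter_profile(profile: SkillProfile, rng: np.random.Generator, rel: float = 0.2) -> SkillProfile:
    kwargs = {}
    for name in SkillProfile.__dataclass_fields__:
        v = getattr(profile, name) * float(rng.uniform(1 - rel, 1 + rel))
        if name == "energy_duty":
            v = float(np.clip(v, 0.0, 1.0))
        kwargs[name] = v
    return SkillProfile(**kwargs)


def make_reference_cohort(
    seed: int = 0,
    duration_s: float = 60.0,
    rate_hz: float = 50.0,
    beyond_norm_fraction: float = 0.4,
) -> Cohort:
    """Cohort reproducing the study's printed counts.

    65 scored trainees (35 from 2019, 30 from 2023): 15 with bleeding
    (failure on item 2, 3 or 4), 4 with poor tissue handling (item 5),
    3 who lost tension (item 6), 43 clean. Plus 7 experts with clean
    outcomes. Clean trainees mix within-norm and beyond-norm skill via
    ``beyond_norm_fraction``. The 2023 cohort carries 13 female and 17 male
    subgroup labels.
    """
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []

    # (year, failure_mode, failed_item, count) — per printed cohort table.
    plan: list[tuple[int, str, int | None, int]] = [
        (2019, "bleeding", 2, 3),
        (2019, "bleeding", 3, 3),
        (2019, "bleeding", 4, 2),
        (2019, "poor_tissue_handling", 5, 4),
        (2019, "lost_tension", 6, 2),
        (2019, "none", None, 21),
        (2023, "bleeding", 2, 2),
        (2023, "bleeding", 3, 3),
        (2023, "bleeding", 4, 2),
        (2023, "lost_tension", 6, 1),
        (2023, "none", None, 22),
    ]
    idx = 0
    for year, mode, failed_item, count in plan:
        for _ in range(count):
            sid = f"T{idx:03d}"
            if mode == "none":
                beyond = rng.uniform() < beyond_norm_fraction
                lam = float(rng.uniform(0.3, 1.0)) if beyond else float(rng.uniform(0.0, 0.12))
            else:
                lam = float(rng.uniform(0.5, 1.0))
            profile = _interp_profile(lam)
            stream_seed = int(rng.integers(2**31))
            records.append(
                CohortRecord(
                    subject_id=sid,
                    role="trainee",
                    year=year,
                    stream=simulate_trajectory(profile, duration_s, rate_hz, stream_seed),
                    events=simulate_events(profile, duration_s, stream_seed + 1),
                    video=_video_outcome(mode, failed_item),
                )
            )
            idx += 1

    # Subgroup labels: 13 female / 17 male among the 30 scored 2023 trainees.
    idx_2023 = [i for i, r in enumerate(records) if r.year == 2023]
    order = rng.permutation(len(idx_2023))
    for j, k in enumerate(order):
        records[idx_2023[k]].group = "female" if j < 13 else "male"

    for e in range(7):
        sid = f"E{e:03d}"
        profile = _jitter_profile(EXPERT_PROFILE, rng, rel=0.25)
        stream_seed = int(rng.integers(2**31))
        records.append(
            CohortRecord(
                subject_id=sid,
                role="expert",
                year=2023,
                stream=simulate_trajectory(profile, duration_s, rate_hz, stream_seed),
                events=simulate_events(profile, duration_s, stream_seed + 1),
                video=VideoOutcome(item_results=(1,) * 6),
            )
        )
    return Cohort(records=records)
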