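"""Tests for OPI metric extraction, including closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opiscore._quat import from_axis_angle, normalize, qmul
from opiscore.errors import (
    InsufficientDataError,
    InvalidArgumentError,
    InvalidDataError,
)
from opiscore.opi import (
    OpiConfig,
    OpiVector,
    angular_path_length,
    clutch_count,
    count_speed_peaks,
    energy_proportion,
    extract_opis,
    idle_time,
    linear_path_length,
    speed_profile,
)
from opiscore.synth import (
    EXPERT_PROFILE,
    NOVICE_PROFILE,
    EventStream,
    KinematicStream,
    simulate_events,
    simulate_trajectory,
)


def make_stream(t, pos, quat=None):
    t = np.asarray(t, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if quat is None:
        quat = np.tile([1.0, 0, 0, 0], (len(t), 1))
    return KinematicStream(t=t, pos=pos, quat=quat)


def min_jerk_stream(extent_mm=100.0, duration_s=2.0, rate_hz=50.0, lead_s=1.0):
    """Single minimum-jerk submovement along x with stationary lead/tail."""
    total = duration_s + 2 * lead_s
    t = np.arange(int(total * rate_hz)) / rate_hz
    tau = np.clip((t - lead_s) / duration_s, 0, 1)
    x = extent_mm * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    pos = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    return make_stream(t, pos)


class TestSpeedProfile:
    def test_uniform_motion_constant_profile(self):
        t = np.arange(200) / 50.0
        pos = np.column_stack([10.0 * t, np.zeros_like(t), np.zeros_like(t)])
        speed = speed_profile(make_stream(t, pos))
        assert speed.shape == (199,)
        assert np.allclose(speed, 10.0, atol=1e-9)

    def test_stationary_stream_zero_profile(self):
        t = np.arange(100) / 50.0
        speed = speed_profile(make_stream(t, np.zeros((100, 3))))
        assert np.allclose(speed, 0.0, atol=1e-12)

    def test_min_jerk_peak_speed_closed_form(self):
        # peak speed of a minimum-jerk movement is 1.875 * D / T
        stream = min_jerk_stream(extent_mm=100.0, duration_s=2.0)
        speed = speed_profile(stream)
        assert abs(speed.max() - 93.75) / 93.75 < 0.02

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            speed_profile(make_stream([0.0], np.zeros((1, 3))))


class TestCountSpeedPeaks:
    def test_constant_series_zero_peaks(self):
        assert count_speed_peaks(np.full(100, 5.0)) == 0

    def test_single_submovement_one_peak(self):
        speed = speed_profile(min_jerk_stream())
        assert count_speed_peaks(speed) == 1

    def test_two_then_three_submovements(self):
        # Constructive oracle: each well-separated submovement adds one peak.
        def stream_with(n_moves):
            rate = 50.0
            seg = min_jerk_stream(80.0, 1.0, rate, lead_s=1.5)
            x = seg.pos[:, 0]
            xs = [x + i * 80.0 for i in range(n_moves)]
            full_x = np.concatenate([xs[0]] + [s[1:] for s in xs[1:]])
            t = np.arange(len(full_x)) / rate
            pos = np.column_stack([full_x, np.zeros_like(full_x), np.zeros_like(full_x)])
            return make_stream(t, pos)

        s2 = speed_profile(stream_with(2))
        s3 = speed_profile(stream_with(3))
        assert count_speed_peaks(s2) == 2
        assert count_speed_peaks(s3) == 3

    def test_single_submovement_any_prominence_below_peak(self):
        speed = speed_profile(min_jerk_stream(100.0, 2.0))
        for prom in (1.0, 10.0, 50.0, 90.0):
            cfg = OpiConfig(peak_min_prominence_mm_s=prom)
            assert count_speed_peaks(speed, cfg) == 1

    def test_empty_series(self):
        with pytest.raises(InsufficientDataError):
            count_speed_peaks(np.array([]))


class TestLinearPathLength:
    def test_pythagorean_segments(self):
        stream = make_stream([0, 1, 2], [(0, 0, 0), (3, 4, 0), (3, 4, 12)])
        assert linear_path_length(stream) == pytest.approx(17.0)

    def test_stationary_zero(self):
        stream = make_stream([0, 1, 2], np.zeros((3, 3)))
        assert linear_path_length(stream) == 0.0

    def test_helix_arc_length(self):
        # helix r=10, pitch term c=2: arc length = t_max * sqrt(r^2 + c^2)
        tt = np.linspace(0, 4 * np.pi, 1000)
        pos = np.column_stack([10 * np.cos(tt), 10 * np.sin(tt), 2 * tt])
        analytic = 4 * np.pi * np.sqrt(104.0)
        got = linear_path_length(make_stream(tt, pos))
        assert abs(got - analytic) / analytic < 0.005

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(50) / 50.0
        pos = rng.normal(size=(50, 3)).cumsum(axis=0)
        stream = make_stream(t, pos)
        # random rotation + translation
        q = normalize(rng.normal(size=4))
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        moved = make_stream(t, pos @ R.T + rng.normal(size=3))
        assert linear_path_length(moved) == pytest.approx(linear_path_length(stream), rel=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_refinement_never_decreases(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(20)
        pos = rng.normal(size=(20, 3))
        coarse = linear_path_length(make_stream(t, pos))
        t_fine = np.sort(np.concatenate([t, t[:-1] + 0.5]))
        pos_fine = np.empty((len(t_fine), 3))
        pos_fine[::2] = pos
        pos_fine[1::2] = 0.5 * (pos[:-1] + pos[1:]) + rng.normal(scale=0.1, size=(19, 3))
        fine = linear_path_length(make_stream(t_fine, pos_fine))
        assert fine >= coarse - 1e-12


class TestAngularPathLength:
    def test_constant_orientation_zero(self):
        stream = make_stream([0, 1, 2], np.zeros((3, 3)))
        assert angular_path_length(stream) == 0.0

    def test_geodesic_additivity_quarter_turn(self):
        angles = np.linspace(0, np.pi / 2, 91)
        quat = np.column_stack(
            [np.cos(angles / 2), np.sin(angles / 2), np.zeros(91), np.zeros(91)]
        )
        stream = make_stream(np.arange(91), np.zeros((91, 3)), quat)
        assert angular_path_length(stream) == pytest.approx(np.pi / 2, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_sign_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        q = np.array([1.0, 0, 0, 0])
        quats = [q]
        for _ in range(30):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            q = normalize(qmul(from_axis_angle(axis, rng.uniform(0, 0.5)), q))
            quats.append(q)
        quat = np.array(quats)
        stream = make_stream(np.arange(len(quat)), np.zeros((len(quat), 3)), quat)
        base = angular_path_length(stream)
        flips = rng.uniform(size=len(quat)) < 0.5
        flipped = quat * np.where(flips, -1.0, 1.0)[:, None]
        stream_f = make_stream(np.arange(len(quat)), np.zeros((len(quat), 3)), flipped)
        assert angular_path_length(stream_f) == pytest.approx(base, abs=1e-10)

    def test_non_unit_quaternion_rejected(self):
        quat = np.tile([2.0, 0, 0, 0], (3, 1))
        stream = make_stream([0, 1, 2], np.zeros((3, 3)), quat)
        with pytest.raises(InvalidDataError):
            angular_path_length(stream)


class TestIdleTime:
    def test_always_moving_zero_idle(self):
        t = np.arange(100) / 50.0
        speed = np.full(99, 50.0)
        assert idle_time(speed, t) == 0.0

    def test_stationary_block_detected(self):
        # 10 s stationary block inside a 60 s stream at 50 Hz
        rate = 50.0
        t = np.arange(int(60 * rate)) / rate
        speed = np.full(len(t) - 1, 20.0)
        block = (t[:-1] >= 20.0) & (t[:-1] < 30.0)
        speed[block] = 0.1
        assert idle_time(speed, t) == pytest.approx(10.0, abs=1.0 / rate)

    def test_short_dip_filtered_by_dwell(self):
        rate = 50.0
        t = np.arange(int(10 * rate)) / rate
        speed = np.full(len(t) - 1, 20.0)
        dip = (t[:-1] >= 5.0) & (t[:-1] < 5.1)
        speed[dip] = 0.0
        assert idle_time(speed, t, OpiConfig(idle_min_dwell_s=0.5)) == 0.0


class TestEnergyProportion:
    def test_no_events(self):
        assert energy_proportion(EventStream(events=[]), 40.0) == 0.0

    def test_quarter_energized(self):
        ev = EventStream(events=[(5.0, "energy_on"), (15.0, "energy_off")])
        assert energy_proportion(ev, 40.0) == pytest.approx(0.25)

    def test_three_bursts(self):
        ev = EventStream(
            events=[
                (1.0, "energy_on"), (3.0, "energy_off"),
                (10.0, "energy_on"), (12.0, "energy_off"),
                (20.0, "energy_on"), (22.0, "energy_off"),
            ]
        )
        assert energy_proportion(ev, 30.0) == pytest.approx(0.2)

    def test_invalid_active_time(self):
        with pytest.raises(InvalidArgumentError):
            energy_proportion(EventStream(events=[]), 0.0)

    @settings(max_examples=30, deadline=None)
    @given(duty=st.floats(0.0, 1.0), seed=st.integers(0, 5000), active=st.floats(1.0, 200.0))
    def test_in_unit_interval_property(self, duty, seed, active):
        from dataclasses import replace

        ev = simulate_events(replace(EXPERT_PROFILE, energy_duty=duty), 120.0, seed=seed)
        assert 0.0 <= energy_proportion(ev, active) <= 1.0


class TestClutchCount:
    def test_empty(self):
        assert clutch_count(EventStream(events=[])) == 0

    def test_three_clutches(self):
        ev = EventStream(events=[(1.0, "clutch"), (2.0, "clutch"), (3.0, "clutch")])
        assert clutch_count(ev) == 3

    def test_mixed_stream_filters_kind(self):
        events = [(float(i), "clutch") for i in range(5)]
        events += [(10.0, "energy_on"), (11.0, "energy_off"), (12.0, "energy_on"), (13.0, "energy_off")]
        assert clutch_count(EventStream(events=sorted(events))) == 5


class TestExtractOpis:
    def test_stationary_no_events(self):
        t = np.arange(500) / 50.0
        stream = make_stream(t, np.zeros((500, 3)))
        v = extract_opis(stream, EventStream(events=[]))
        assert v.speed_peaks == 0
        assert v.angular_path_length_rad == 0.0
        assert v.linear_path_length_mm == 0.0
        assert v.idle_time_s == pytest.approx(t[-1], abs=0.05)
        assert v.energy_proportion == 0.0
        assert v.clutch_count == 0

    def test_novice_dominates_expert(self):
        ve = extract_opis(
            simulate_trajectory(EXPERT_PROFILE, 60, 50, seed=21),
            simulate_events(EXPERT_PROFILE, 60, seed=22),
        )
        vn = extract_opis(
            simulate_trajectory(NOVICE_PROFILE, 60, 50, seed=21),
            simulate_events(NOVICE_PROFILE, 60, seed=22),
        )
        assert vn.speed_peaks >= ve.speed_peaks
        assert vn.linear_path_length_mm >= ve.linear_path_length_mm
        assert vn.idle_time_s >= ve.idle_time_s

    def test_expert_cohort_finite_with_variance(self, cohort_opis):
        _, expert = cohort_opis
        assert len(expert) == 7
        table = np.array([[v for v in o.as_dict().values()] for o in expert.values()])
        assert np.isfinite(table).all()
        assert (table.std(axis=0) > 0).all()

    def test_opi_vector_validation(self):
        with pytest.raises(InvalidArgumentError):
            OpiVector(-1, 0.0, 0.0, 0.0, 0.0, 0)
        with pytest.raises(InvalidArgumentError):
            OpiVector(0, 0.0, 0.0, 0.0, 1.5, 0)
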