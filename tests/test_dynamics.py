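"""Tests of integration, crossing detection, and regime classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from daneuron import (
    MinimalParams,
    SolverSettings,
    Trajectory,
    detect_crossings,
    firing_summary,
    simulate,
)
from daneuron.dynamics import IntegrationError


def _synthetic_traj(times, v):
    states = np.column_stack([v, np.zeros_like(v)])
    return Trajectory(
        model="minimal",
        times=times,
        states=states,
        settings=SolverSettings(),
        initial_state=states[0],
        time_scale=1.0,
    )


def _oracle_upward(times, v, threshold):
    """Brute-force sign-change scan, independent of detect_crossings."""
    out = []
    for i in range(len(v) - 1):
        if v[i] < threshold <= v[i + 1]:
            s = (threshold - v[i]) / (v[i + 1] - v[i])
            out.append(times[i] + s * (times[i + 1] - times[i]))
    return np.array(out)


class TestCrossingDetection:
    def test_sinusoid_crossings(self):
        t = np.linspace(0, 1, 20001)
        traj = _synthetic_traj(t, np.sin(2 * np.pi * 5 * t))
        up = detect_crossings(traj, 0.0, "up")
        assert len(up) == 5
        assert np.allclose(up, [0.0, 0.2, 0.4, 0.6, 0.8], atol=1e-4)

    def test_constant_trace_has_no_crossings(self):
        t = np.linspace(0, 1, 100)
        traj = _synthetic_traj(t, np.full_like(t, -0.5))
        assert len(detect_crossings(traj, -0.4)) == 0

    def test_alternation_with_downward(self):
        t = np.linspace(0, 2, 40001)
        traj = _synthetic_traj(t, np.sin(2 * np.pi * 3 * t))
        up = detect_crossings(traj, 0.3, "up")
        down = detect_crossings(traj, 0.3, "down")
        assert len(up) == len(down) == 6
        # between consecutive upward crossings there is a downward one
        for a, b in zip(up[:-1], up[1:]):
            assert ((down > a) & (down < b)).any()

    @given(
        st.lists(st.floats(-1, 1), min_size=3, max_size=8),
        st.lists(st.floats(0.3, 3.0), min_size=3, max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle_on_random_signals(self, amps, freqs):
        t = np.linspace(0, 2, 4001)
        v = sum(a * np.sin(2 * np.pi * f * t) for a, f in zip(amps, freqs))
        v = np.asarray(v) - 0.1
        traj = _synthetic_traj(t, v)
        got = detect_crossings(traj, 0.0, "up")
        want = _oracle_upward(t, v, 0.0)
        assert len(got) == len(want)
        assert np.allclose(got, want)

    def test_matches_oracle_on_model_trajectory(self):
        traj = simulate("minimal", MinimalParams(), duration=20.0)
        got = detect_crossings(traj, -0.4, "up")
        want = _oracle_upward(traj.times, traj.v, -0.4)
        assert np.allclose(got, want)


class TestFiringSummary:
    def test_equally_spaced_crossings_give_rate(self):
        # 11 crossings spanning 1 s after the transient -> 10 Hz
        t = np.linspace(0, 11, 110001)
        v = np.sin(2 * np.pi * 10 * (t - 0.05)) - 0.2
        traj = _synthetic_traj(t, v)
        fs = firing_summary(traj, threshold=0.0, transient=10.0)
        assert fs.regime == "firing"
        assert fs.frequency == pytest.approx(10.0, rel=1e-3)

    def test_minimum_count_rule(self):
        t = np.linspace(0, 10, 10001)
        v = np.where(t < 2.0, np.sin(2 * np.pi * t), -0.5)
        traj = _synthetic_traj(t, v)
        fs = firing_summary(traj, threshold=0.0, transient=0.5,
                            amplitude_floor=0.01)
        assert fs.regime != "firing"
        assert fs.frequency is None

    def test_subthreshold_vs_quiescent(self):
        t = np.linspace(0, 20, 20001)
        small = _synthetic_traj(t, -0.6 + 0.05 * np.sin(2 * np.pi * t))
        flat = _synthetic_traj(t, np.full_like(t, -0.6))
        assert firing_summary(small, transient=10.0).regime == (
            "subthreshold_oscillation"
        )
        assert firing_summary(flat, transient=10.0).regime == "quiescent"

    def test_window_too_short_errors(self):
        traj = simulate("minimal", MinimalParams(), duration=5.0)
        with pytest.raises(ValueError, match="transient"):
            firing_summary(traj, transient=10.0)

    def test_frequency_vs_intervals_consistency(self):
        traj = simulate("minimal", MinimalParams(), duration=30.0)
        fs = firing_summary(traj)
        isi = np.diff(fs.crossing_times)
        assert fs.frequency * isi.mean() == pytest.approx(1.0, rel=1e-6)


class TestSimulate:
    def test_unstimulated_tonic_oscillation(self):
        traj = simulate("minimal", MinimalParams(), duration=20.0)
        up = detect_crossings(traj, -0.4, "up")
        assert len(up) > 10  # repeated crossings of the spike threshold

    def test_depolarization_block_at_large_ampa(self):
        p = MinimalParams(g_a=0.04)
        traj = simulate("minimal", p, duration=20.0)
        fs = firing_summary(traj, transient=10.0)
        assert fs.regime == "quiescent"
        # fixed point above the unstimulated oscillation trough
        trough = simulate("minimal", MinimalParams(), duration=20.0).v.min()
        assert traj.v[-1] > trough

    def test_tolerance_refinement_invariance(self):
        f = []
        for scale in (1.0, 0.5):
            traj = simulate(
                "minimal",
                MinimalParams(),
                duration=30.0,
                settings=SolverSettings(rtol=1e-8 * scale, atol=1e-10 * scale),
            )
            f.append(firing_summary(traj).frequency)
        assert abs(f[1] - f[0]) / f[0] < 0.01

    def test_deterministic_replay(self):
        a = simulate("minimal", MinimalParams(g_n=0.5), duration=5.0)
        b = simulate("minimal", MinimalParams(g_n=0.5), duration=5.0)
        assert (a.states == b.states).all()

    def test_initial_state_insensitivity(self):
        p = MinimalParams(g_n=0.6)
        f1 = firing_summary(simulate("minimal", p)).frequency
        f2 = firing_summary(simulate("minimal", p, init=[-0.2, 8.0])).frequency
        assert f2 == pytest.approx(f1, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate("minimal", MinimalParams(), duration=-1.0)
        with pytest.raises(TypeError):
            simulate("minimal", object())
        with pytest.raises(ValueError):
            simulate("unknown", MinimalParams())

    def test_divergent_system_reports_failure_time(self):
        # an unbounded cubic with flipped sign blows up in finite time
        p = MinimalParams(a1=1.0)
        with pytest.raises(IntegrationError):
            simulate("minimal", p, init=[0.5, 0.0], duration=10.0)
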