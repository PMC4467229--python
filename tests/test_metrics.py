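"""Amplitude, harmonic, and tuning statistics against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from omskit.metrics import (
    current_to_conductance,
    conductance_to_current,
    dsi,
    edge_amplitude,
    epoch_amplitude,
    harmonic_amplitudes,
    motion_selectivity,
    peak_window_amplitude,
    size_tuning,
    speed_tuning,
)
from omskit.traces import EpochedTrace

RATE = 10_000.0


def make_trace(samples, modality="voltage_mV", baseline=(0.0, 0.5), events=()):
    return EpochedTrace(samples=np.asarray(samples, float), rate=RATE,
                        modality=modality, baseline_window=baseline,
                        events=list(events))


class TestEpochAmplitude:
    def test_constant_trace_is_zero(self):
        tr = make_trace(np.full(20_000, 3.7))
        assert epoch_amplitude(tr, (1.0, 1.15)) == pytest.approx(0.0)

    def test_step_amplitude(self):
        x = np.zeros(20_000)
        x[10_000:] = 10.0
        tr = make_trace(x)
        assert epoch_amplitude(tr, (1.2, 1.35)) == pytest.approx(10.0)

    def test_alpha_transient_matches_analytic_window_mean(self):
        # response t*exp(-t/tau) from t0: window mean from the closed-form
        # antiderivative -(tau*t + tau^2)*exp(-t/tau)
        tau, t0 = 0.05, 1.0
        t = np.arange(20_000) / RATE
        x = np.where(t >= t0, (t - t0) * np.exp(-(t - t0) / tau), 0.0)
        tr = make_trace(x)
        a, b = 1.05, 1.2

        def F(u):  # antiderivative of u*exp(-u/tau)
            return -(tau * u + tau**2) * np.exp(-u / tau)

        expected = (F(b - t0) - F(a - t0)) / (b - a)
        assert epoch_amplitude(tr, (a, b)) == pytest.approx(expected, rel=1e-3)

    def test_window_outside_trace_rejected(self):
        tr = make_trace(np.zeros(10_000))
        with pytest.raises(ValueError):
            epoch_amplitude(tr, (0.9, 1.2))

    @given(a=hst.floats(-5, 5), b=hst.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, a, b):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=15_000), rng.normal(size=15_000)
        w = (0.8, 0.95)
        tx = make_trace(x)
        ty = make_trace(y)
        tz = make_trace(a * x + b * y)
        assert epoch_amplitude(tz, w) == pytest.approx(
            a * epoch_amplitude(tx, w) + b * epoch_amplitude(ty, w), abs=1e-9)

    def test_peak_window_is_signed(self):
        t = np.arange(20_000) / RATE
        x = np.where((t > 1.2) & (t < 1.5), -4.0, 0.0)  # suppression epoch
        tr = make_trace(x, events=[("seg", 1.0, 2.0)])
        assert peak_window_amplitude(tr, "seg") == pytest.approx(-4.0, rel=0.05)


class TestConductance:
    @pytest.mark.parametrize("i_pa,hold,rev,expected", [
        (-600.0, -60.0, 0.0, 10.0),
        (300.0, 0.0, -60.0, 5.0),
        (0.0, -60.0, 0.0, 0.0),
    ])
    def test_ohmic_identities(self, i_pa, hold, rev, expected):
        tr = make_trace(np.full(10_000, i_pa), modality="current_pA")
        g = current_to_conductance(tr, hold, rev)
        assert g.modality == "conductance_nS"
        assert g.samples[0] == pytest.approx(expected)

    def test_round_trip_exact_to_rounding(self):
        # one correctly-rounded division and one multiplication: the round
        # trip reproduces the current within a single ULP everywhere
        rng = np.random.default_rng(1)
        tr = make_trace(rng.normal(size=10_000) * 50, modality="current_pA")
        g = current_to_conductance(tr, -60.0, 0.0)
        back = conductance_to_current(g, -60.0, 0.0)
        assert np.all(np.abs(back.samples - tr.samples) <= np.spacing(np.abs(tr.samples)))

    def test_equal_potentials_rejected(self):
        tr = make_trace(np.zeros(10_000), modality="current_pA")
        with pytest.raises(ValueError):
            current_to_conductance(tr, -60.0, -60.0)


class TestHarmonics:
    def test_pure_tone(self):
        t = np.arange(50_000) / RATE
        res = harmonic_amplitudes((3.0 * np.sin(2 * np.pi * 2 * t), RATE), 2.0)
        assert res.f1_amplitude == pytest.approx(3.0, abs=1e-9)
        assert res.f2_amplitude == pytest.approx(0.0, abs=1e-9)
        assert res.f2_hz == 4.0

    def test_half_wave_rectified_sine_closed_form(self):
        t = np.arange(50_000) / RATE
        x = np.clip(np.sin(2 * np.pi * 2 * t), 0, None)
        res = harmonic_amplitudes((x, RATE), 2.0)
        assert res.f1_amplitude == pytest.approx(0.5, abs=1e-6)
        assert res.f2_amplitude == pytest.approx(2 / (3 * np.pi), abs=1e-6)

    def test_full_wave_rectified_sine_closed_form(self):
        t = np.arange(50_000) / RATE
        x = np.abs(np.sin(2 * np.pi * 2 * t))  # two anti-phase half-wave units
        res = harmonic_amplitudes((x, RATE), 2.0)
        assert res.f1_amplitude == pytest.approx(0.0, abs=1e-6)
        assert res.f2_amplitude == pytest.approx(4 / (3 * np.pi), abs=1e-6)

    def test_matches_brute_force_projection(self):
        rng = np.random.default_rng(2)
        t = np.arange(25_000) / RATE
        x = sum(a * np.sin(2 * np.pi * f * t + p)
                for a, f, p in [(2.0, 2.0, 0.3), (0.7, 4.0, 1.1), (0.2, 6.0, 2.0)])
        res = harmonic_amplitudes((x, RATE), 2.0)
        n = len(x)
        for f, got in ((2.0, res.f1_amplitude), (4.0, res.f2_amplitude)):
            c = np.sum(x * np.cos(2 * np.pi * f * t)) * 2 / n
            s = np.sum(x * np.sin(2 * np.pi * f * t)) * 2 / n
            assert got == pytest.approx(np.hypot(c, s), rel=1e-9)

    def test_truncates_to_whole_periods(self):
        t = np.arange(int(1.3 * RATE)) / RATE  # 2.6 periods at 2 Hz
        res = harmonic_amplitudes((np.sin(2 * np.pi * 2 * t), RATE), 2.0)
        assert res.f1_amplitude == pytest.approx(1.0, abs=1e-9)

    def test_less_than_one_period_rejected(self):
        with pytest.raises(ValueError):
            harmonic_amplitudes((np.zeros(1000), RATE), 2.0)


class TestDSI:
    def test_uniform_amplitudes_cancel(self):
        assert dsi(np.ones(8)) == pytest.approx(0.0, abs=1e-12)

    def test_single_direction_is_one(self):
        a = np.zeros(8)
        a[3] = 5.0
        assert dsi(a) == pytest.approx(1.0)

    def test_one_boosted_direction(self):
        assert dsi([2, 1, 1, 1, 1, 1, 1, 1]) == pytest.approx(1 / 9, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dsi(np.zeros(8))

    @given(scale=hst.floats(0.1, 50), shift=hst.integers(0, 7))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_scaling_and_rotation(self, scale, shift):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.1, 2.0, 8)
        base = dsi(a)
        assert dsi(scale * a) == pytest.approx(base, rel=1e-9)
        assert dsi(np.roll(a, shift)) == pytest.approx(base, rel=1e-9)


def bump_trace(center_s, amp, duration_s=4.0, width_s=0.3, events=()):
    """Boxcar transients (window means are exact at the plateau level)."""
    t = np.arange(int(duration_s * RATE)) / RATE
    x = np.zeros_like(t)
    for c, a in zip(np.atleast_1d(center_s), np.atleast_1d(amp)):
        x[(t >= c) & (t < c + width_s)] = a
    return make_trace(x, events=events)


class TestMotionSelectivity:
    def test_flat_traces_give_zero_triplet(self):
        evs = [("global", 1, 2), ("diff_center", 1, 2), ("diff_surround", 1, 2)]
        tr = {s: make_trace(np.zeros(30_000), events=[e]) for s, e in
              zip(("global", "diff_center", "diff_surround"), evs)}
        ms = motion_selectivity(tr)
        assert (ms.global_amp, ms.diff_center_amp, ms.diff_surround_amp) == (0, 0, 0)

    def test_missing_segment_rejected(self):
        tr = {"global": make_trace(np.zeros(30_000), events=[("global", 1, 2)])}
        with pytest.raises(ValueError, match="missing"):
            motion_selectivity(tr)


class TestEdgeTuning:
    def events_for(self, t_le, t_te):
        return [("leading_edge", t_le, t_le), ("trailing_edge", t_te, t_te)]

    def test_edge_amplitude_finds_bump_after_crossing(self):
        tr = bump_trace([1.6, 2.6], [8.0, 5.0], events=self.events_for(1.5, 2.5))
        assert edge_amplitude(tr, "leading_edge") == pytest.approx(8.0, rel=1e-6)
        assert edge_amplitude(tr, "trailing_edge") == pytest.approx(5.0, rel=1e-6)

    def test_size_tuning_suppression_index(self):
        traces = {
            200.0: bump_trace([1.55], [10.0], events=self.events_for(1.5, 3.0)),
            600.0: bump_trace([1.55], [4.0], events=self.events_for(1.5, 3.0)),
        }
        table, idx = size_tuning(traces)
        assert idx == pytest.approx(1 - 4.0 / 10.0, abs=0.02)
        assert set(table["edge"]) == {"leading_edge", "trailing_edge"}

    def test_size_tuning_requires_reference_heights(self):
        traces = {100.0: bump_trace([1.55], [1.0], events=self.events_for(1.5, 3.0))}
        with pytest.raises(ValueError):
            size_tuning(traces)

    def test_size_tuning_requires_edge_events(self):
        traces = {200.0: make_trace(np.zeros(30_000)),
                  600.0: make_trace(np.zeros(30_000))}
        with pytest.raises(ValueError, match="lacks"):
            size_tuning(traces)

    def test_speed_tuning_table(self):
        traces = {v: bump_trace([1.55, 1.55 + 800 / v], [6.0, 3.0],
                                events=self.events_for(1.5, 1.5 + 800 / v))
                  for v in (400.0, 800.0)}
        table = speed_tuning(traces)
        assert len(table) == 4
        lead = table[(table.speed_um_s == 400.0) & (table.edge == "leading_edge")]
        assert float(lead["amplitude"].iloc[0]) == pytest.approx(6.0, rel=1e-6)
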