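"""Resistive-pulse detection: filtering, baseline, thresholding, inversion."""

import math

import numpy as np
import pytest
from scipy import signal, stats

from rtfast import (
    CurrentTrace,
    CylindricalOligomer,
    detect_events,
    estimate_baseline,
    events_to_volume_map,
    lowpass_filter,
    relative_blockade,
)
from rtfast.event_detection import DegenerateBaselineError, TranslocationEvent

FS = 200_000.0


def make_trace(current, fs=FS, voltage=-500.0):
    return CurrentTrace(current_pA=current, sampling_rate_Hz=fs, applied_voltage_mV=voltage)


def flat_noise_trace(rng, n=200_000, level=-2000.0, sigma=5.0):
    return make_trace(level + rng.normal(0.0, sigma, n))


def inject_pulse(current, start, width, depth, toward_zero=True):
    sign = -np.sign(current[start]) if toward_zero else 1.0
    current[start : start + width] += sign * depth
    return current


class TestLowpassFilter:
    def test_constant_trace_unchanged(self):
        trace = make_trace(np.full(10_000, -1500.0))
        out = lowpass_filter(trace)
        assert np.allclose(out.current_pA, -1500.0)

    def test_sinusoid_attenuation_matches_transfer_function(self):
        # forward-backward order-1 Butterworth: |H|^2 at the test frequency
        f0, cutoff = 15_000.0, 20_000.0
        t = np.arange(200_000) / FS
        trace = make_trace(np.sin(2 * np.pi * f0 * t))
        out = lowpass_filter(trace, cutoff_Hz=cutoff, order=1)
        sos = signal.butter(1, cutoff, btype="low", fs=FS, output="sos")
        _w, h = signal.sosfreqz(sos, worN=[f0], fs=FS)
        expected = np.abs(h[0]) ** 2  # two passes
        measured = out.current_pA[50_000:150_000].std() * math.sqrt(2)
        assert measured == pytest.approx(expected, rel=0.01)

    def test_noise_variance_reduced(self, rng):
        trace = flat_noise_trace(rng)
        out = lowpass_filter(trace)
        assert out.current_pA.var() < trace.current_pA.var()

    def test_cutoff_at_nyquist_rejected(self, rng):
        with pytest.raises(ValueError):
            lowpass_filter(flat_noise_trace(rng, n=1000), cutoff_Hz=FS / 2)


class TestEstimateBaseline:
    def test_linear_ramp_reproduced_exactly(self):
        ramp = -2000.0 + 0.01 * np.arange(50_000)
        model = estimate_baseline(make_trace(ramp), window=5_001)
        assert np.allclose(model.baseline_pA, ramp, atol=1e-6)
        assert model.sigma_pA == pytest.approx(0.0, abs=1e-9)

    def test_known_noise_recovered(self, rng):
        ramp = -2000.0 + 0.01 * np.arange(400_000)
        trace = make_trace(ramp + rng.normal(0.0, 2.0, ramp.size))
        model = estimate_baseline(trace, window=50_001)
        assert model.sigma_pA == pytest.approx(2.0, rel=0.10)

    def test_matches_scipy_savgol(self, rng):
        # dual route: the O(N) implementation vs scipy's direct SG filter
        x = rng.normal(0.0, 1.0, 2_000).cumsum()
        model = estimate_baseline(make_trace(x), window=101)
        expected = signal.savgol_filter(x, window_length=101, polyorder=1, mode="interp")
        assert np.allclose(model.baseline_pA, expected, atol=1e-8)

    @pytest.mark.parametrize("window", [100, 1])
    def test_bad_window_rejected(self, window, rng):
        with pytest.raises(ValueError):
            estimate_baseline(flat_noise_trace(rng, n=10_000), window=window)

    def test_degenerate_constant_trace_flagged_at_detection(self):
        trace = make_trace(np.full(10_000, -1500.0))
        model = estimate_baseline(trace, window=1_001)
        assert model.sigma_pA == 0.0
        with pytest.raises(DegenerateBaselineError):
            detect_events(trace, model)


class TestDetectEvents:
    def test_injected_pulses_recovered(self, rng):
        sigma = 5.0
        current = -2000.0 + rng.normal(0.0, sigma, 400_000)
        width = int(1e-3 * FS)  # 1 ms
        starts = [50_000, 150_000, 300_000]
        for s in starts:
            inject_pulse(current, s, width, 8 * sigma)
        trace = lowpass_filter(make_trace(current))
        model = estimate_baseline(trace, window=50_001)
        # min duration 0.2 ms: an order of magnitude below the pulse width,
        # far above the correlation time of the filtered noise
        events = detect_events(trace, model, min_duration=40)
        assert len(events) == 3
        for ev, s in zip(events, starts):
            assert ev.peak_index == pytest.approx(s + width / 2, abs=width)
            assert ev.depth_pA == pytest.approx(8 * sigma, rel=0.15)
            assert ev.dwell_s == pytest.approx(width / FS, rel=0.5)

    def test_flat_trace_no_events(self, rng):
        trace = flat_noise_trace(rng)
        model = estimate_baseline(trace, window=50_001)
        assert detect_events(trace, model) == []

    def test_false_positive_rate_bounded_by_gaussian_tail(self, rng):
        # at reduced k the count of threshold-crossing runs is bounded by the
        # expected number of supra-threshold samples from the one-sided tail
        trace = flat_noise_trace(rng, n=500_000)
        model = estimate_baseline(trace, window=50_001)
        k = 3.0
        events = detect_events(trace, model, k=k, min_duration=1)
        expected_samples = 500_000 * stats.norm.sf(k)
        assert 0 < len(events) <= 2 * expected_samples

    def test_count_monotone_in_threshold(self, rng):
        current = -2000.0 + rng.normal(0.0, 5.0, 400_000)
        for s in range(20_000, 380_000, 20_000):
            inject_pulse(current, s, 200, rng.uniform(15.0, 60.0))
        trace = make_trace(current)
        model = estimate_baseline(trace, window=50_001)
        counts = [len(detect_events(trace, model, k=k, min_duration=1)) for k in (2, 3, 4, 6, 10)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_time_reversal_symmetry(self, rng):
        current = -2000.0 + rng.normal(0.0, 5.0, 200_000)
        inject_pulse(current, 60_000, 300, 50.0)
        inject_pulse(current, 130_000, 150, 40.0)
        fwd = lowpass_filter(make_trace(current))
        rev = lowpass_filter(make_trace(current[::-1].copy()))
        ev_f = detect_events(fwd, estimate_baseline(fwd, window=20_001), min_duration=40)
        ev_r = detect_events(rev, estimate_baseline(rev, window=20_001), min_duration=40)
        assert len(ev_f) == len(ev_r) == 2
        n = 200_000
        mirrored = sorted(n - 1 - e.end_index for e in ev_r)
        assert sorted(e.start_index for e in ev_f) == mirrored

    def test_min_duration_enforced(self, rng):
        trace = flat_noise_trace(rng, n=300_000)
        model = estimate_baseline(trace, window=50_001)
        for ev in detect_events(trace, model, k=2.5, min_duration=4):
            assert ev.dwell_s >= 4 / FS

    def test_empty_trace(self):
        from rtfast import BaselineModel

        trace = make_trace(np.array([]))
        assert detect_events(trace, BaselineModel(np.array([]), 1.0)) == []


class TestVolumeMap:
    def _event(self, rel, dwell=1e-3):
        return TranslocationEvent(
            start_time_s=0.1,
            dwell_s=dwell,
            depth_pA=rel * 2000.0,
            relative_blockade=rel,
            peak_index=0,
            start_index=0,
            end_index=10,
        )

    def test_forward_model_roundtrip(self, geometry):
        rel = relative_blockade(geometry, CylindricalOligomer(5.0))
        result = events_to_volume_map([self._event(rel)], geometry)
        assert len(result.table) == 1
        assert result.table.loc[0, "volume_nm3"] == pytest.approx(2 * math.pi * 125.0, rel=0.01)
        assert result.table.loc[0, "size_nm"] == pytest.approx(10.0, rel=0.01)

    def test_empty_events(self, geometry):
        result = events_to_volume_map([], geometry)
        assert result.table.empty and result.n_non_invertible == 0

    def test_saturating_event_reported_not_fatal(self, geometry):
        rel_ok = relative_blockade(geometry, CylindricalOligomer(5.0))
        with pytest.warns(UserWarning, match="non.invertible|not invertible"):
            result = events_to_volume_map(
                [self._event(rel_ok), self._event(0.999)], geometry
            )
        assert len(result.table) == 1
        assert result.n_non_invertible == 1
        assert "saturation" in result.non_invertible.loc[0, "reason"]
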