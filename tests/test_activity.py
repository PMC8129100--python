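"""dF/F pipeline, burst metrics and LFP initiation analysis."""

import numpy as np
import pytest

from neuroaggsim import activity as act
from neuroaggsim import fixtures as fx


class TestBaseline:
    def test_constant_trace_exact(self):
        y = np.full(200, 87.5)
        z = act.baseline(y)
        assert np.allclose(z, 87.5, atol=1e-6)

    def test_linear_ramp(self):
        """Second differences of a line are penalty-free: fit is the ramp."""
        y = np.linspace(50, 150, 300)
        z = act.baseline(y)
        assert np.abs(z - y).max() < 0.01 * (y.max() - y.min())

    def test_ramp_with_sparse_spikes(self, rng):
        ramp = np.linspace(100, 120, 500)
        y = ramp.copy()
        spikes = [60, 200, 340, 450]
        for s in spikes:
            y[s : s + 8] += 80.0
        z = act.baseline(y)
        for s in spikes:
            assert abs(z[s] - ramp[s]) < 0.05 * 80.0

    def test_parameter_validation(self):
        y = np.ones(50)
        with pytest.raises(ValueError):
            act.baseline(y, smoothness=-1.0)
        with pytest.raises(ValueError):
            act.baseline(y, asymmetry=1.5)
        with pytest.raises(ValueError):
            act.baseline(np.ones(5))


class TestDff:
    def test_identity_and_doubling(self):
        F0 = np.full(20, 50.0)
        assert np.allclose(act.dff(F0.copy(), F0), 0.0)
        assert np.allclose(act.dff(2 * F0, F0), 1.0)

    def test_arithmetic_example(self):
        out = act.dff(np.array([156.8]), np.array([87.7]))
        assert out[0] == pytest.approx((156.8 - 87.7) / 87.7, rel=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="index 1"):
            act.dff(np.ones(3), np.array([1.0, 0.0, 1.0]))

    def test_dff_of_pure_baseline_trace_is_small(self):
        """A transient-free drifting trace yields |dF/F| < 0.01.

        The second-difference penalty has natural boundary conditions, so
        the first/last ~10 s of a drifting trace carry a slightly larger
        fit error; the bound is checked on the interior and a looser one
        at the edges.
        """
        spec = fx.CaTraceSpec(burst_amplitude=0.0, noise_sigma=0.0)
        trace, _ = fx.make_ca_trace(spec, seed=0)
        series = act.dff(trace, act.baseline(trace))
        assert np.abs(series[50:-50]).max() < 0.01
        assert np.abs(series).max() < 0.02


class TestDetectBursts:
    def test_rectangular_pulse(self, rng):
        x = rng.normal(0, 0.01, 500)
        x[100:110] += 5 * 0.01 * 5  # well above 3 sigma
        events, summary = act.detect_bursts(x, frame_interval=0.2)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(2.0)
        assert events[0].onset == pytest.approx(100 * 0.2)
        assert summary["n_bursts"] == 1

    def test_subthreshold_noise(self, rng):
        x = rng.normal(0, 0.01, 400)
        events, summary = act.detect_bursts(x)
        assert events == []
        assert summary["active_time_fraction"] == 0.0

    def test_triangular_pulse_auc(self):
        h, w, dt = 2.0, 8.0, 0.2
        n = int(w / dt)
        x = np.zeros(2000)
        tri = h * (1 - np.abs(np.linspace(-1, 1, n)))
        x[500 : 500 + n] = tri
        x += 1e-6 * np.sin(np.arange(2000))  # nonzero variance off-burst
        events, _ = act.detect_bursts(x, frame_interval=dt)
        assert len(events) == 1
        assert events[0].auc == pytest.approx(h * w / 2, abs=2 * h * dt)

    def test_scale_invariant_burst_count(self, rng):
        x = rng.normal(0, 0.01, 800)
        x[200:230] += 0.2
        x[500:540] += 0.3
        e1, _ = act.detect_bursts(x)
        e2, _ = act.detect_bursts(x * 37.0)
        assert len(e1) == len(e2) == 2
        assert [b.onset for b in e1] == [b.onset for b in e2]

    def test_partition_property(self, rng):
        x = rng.normal(0, 0.01, 1000)
        x[100:200] += 0.5
        x[600:650] += 0.5
        dt = 0.2
        events, summary = act.detect_bursts(x, frame_interval=dt)
        burst_time = sum(e.duration for e in events)
        assert burst_time + (1 - summary["active_time_fraction"]) * len(x) * dt == pytest.approx(
            len(x) * dt
        )

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            events, summary = act.detect_bursts(np.zeros(100))
        assert events == []


class TestSegmentBaselineProfile:
    def test_identical_segments(self):
        tr = act.FluorescenceTrace(np.full(300, 120.0) + np.sin(np.arange(300)) * 0.0)
        out = act.segment_baseline_profile([tr] * 7)
        assert np.allclose(out, 1.0)

    def test_known_gradient(self):
        traces = [act.FluorescenceTrace(np.full(200, level)) for level in (100.0, 90.0, 80.0)]
        out = act.segment_baseline_profile(traces)
        assert np.allclose(out, [1.0, 0.9, 0.8])

    def test_edge_high_gradient_recovered(self, rng):
        """Edge-to-center brightness gradient appears monotone in the profile."""
        levels = [100, 95, 90, 85, 90, 95, 100]  # seven segments, edges bright
        traces = []
        for i, lvl in enumerate(levels):
            y = lvl + rng.normal(0, 0.3, 400)
            y[150:170] += 40.0  # shared burst, masked out as active
            traces.append(act.FluorescenceTrace(np.clip(y, 0, None)))
        out = act.segment_baseline_profile(traces)
        center = out[3]
        assert out[0] > center and out[6] > center
        assert np.all(np.diff(out[:4]) < 0) and np.all(np.diff(out[3:]) > 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            act.segment_baseline_profile([])


class TestLfpPreprocess:
    def test_mains_attenuation(self):
        fs = 6000.0
        t = np.arange(int(2 * fs)) / fs
        hum = np.sin(2 * np.pi * 60.0 * t)
        out = act.lfp_preprocess(act.LfpTrace(hum, fs)).values
        # compare steady-state RMS, discarding filter edges
        sl = slice(2000, -2000)
        atten_db = 20 * np.log10(np.std(hum[sl]) / max(np.std(out[sl]), 1e-300))
        assert atten_db >= 40.0

    def test_passband_preserved(self):
        fs = 6000.0
        t = np.arange(int(2 * fs)) / fs
        sig = np.sin(2 * np.pi * 700.0 * t)
        out = act.lfp_preprocess(act.LfpTrace(sig, fs)).values
        sl = slice(2000, -2000)
        assert np.std(out[sl]) > 0.7 * np.std(sig[sl])


class TestBurstInitiation:
    def _trace(self, x, fs=1000.0):
        return act.LfpTrace(x, fs)

    def test_long_pulse_single_initiation(self):
        x = np.zeros(1000)
        x[200:250] = 5.0  # 50 ms at 1 kHz
        times = act.burst_initiation_time(self._trace(x), threshold=1.0)
        assert np.allclose(times, [0.2])

    def test_short_excursion_excluded(self):
        x = np.zeros(1000)
        x[200:205] = 5.0  # 5 ms, below the 10 ms persistence rule
        assert len(act.burst_initiation_time(self._trace(x), threshold=1.0)) == 0

    def test_rearm_after_gap(self):
        x = np.zeros(2000)
        x[200:280] = 5.0
        x[700:790] = 5.0
        times = act.burst_initiation_time(self._trace(x), threshold=1.0)
        assert np.allclose(times, [0.2, 0.7])

    def test_no_retrigger_within_burst(self):
        x = np.zeros(1000)
        x[100:400] = 5.0
        times = act.burst_initiation_time(self._trace(x), threshold=1.0)
        assert len(times) == 1

    def test_times_sorted_and_separated(self, rng):
        x = np.abs(rng.normal(0, 1, 6000))
        x[1000:1100] += 10
        x[3000:3100] += 10
        times = act.burst_initiation_time(self._trace(x, 6000.0), threshold=5.0)
        assert np.all(np.diff(times) > 0)

    def test_persistence_validation(self):
        with pytest.raises(ValueError):
            act.burst_initiation_time(self._trace(np.zeros(100), fs=10.0), 1.0, persistence=0.01)


class TestInitiationDelay:
    def test_shifted_copy(self):
        fs = 1000.0
        center = np.zeros(5000)
        for onset in (500, 2000, 3500):
            center[onset : onset + 100] = 5.0
        edge = np.roll(center, 30)  # center leads by 30 ms
        delays, frac, info = act.initiation_delay(
            act.LfpTrace(edge, fs), act.LfpTrace(center, fs),
            edge_threshold=1.0, center_threshold=1.0,
        )
        assert np.allclose(delays, 0.030)
        assert frac == 1.0
        assert info["n_matched"] == 3

    def test_identical_traces_are_ties(self):
        fs = 1000.0
        x = np.zeros(3000)
        x[500:600] = 5.0
        delays, frac, info = act.initiation_delay(
            act.LfpTrace(x, fs), act.LfpTrace(x.copy(), fs),
            edge_threshold=1.0, center_threshold=1.0,
        )
        assert np.allclose(delays, 0.0)
        assert np.isnan(frac)  # ties excluded from both sides of the fraction
        assert info["n_ties"] == 1

    def test_generator_fraction_recovered(self):
        spec = fx.LfpPairSpec(duration_s=240.0, n_bursts=16, center_lead_prob=0.92)
        edge, center, truth = fx.make_lfp_pair(spec, seed=8)
        delays, frac, info = act.initiation_delay(edge, center)
        assert info["n_matched"] == 16
        expected = truth["center_lead"].mean()
        # binomial CI at n=16
        assert abs(frac - expected) <= 3 * np.sqrt(expected * (1 - expected) / 16) + 1e-9


class TestAutoThreshold:
    def test_quietest_window_std(self, rng):
        fs = 1000.0
        x = rng.normal(0, 1.0, 4000)
        x[1000:1100] = rng.normal(0, 0.1, 100)  # quiet 100 ms window
        thr = act.auto_threshold(act.LfpTrace(x, fs))
        assert 0.05 < thr < 0.2
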