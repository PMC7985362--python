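"""Detector: baseline estimation, normalization, event recovery, IPR readout."""

import dataclasses

import numpy as np
import pytest

from qbead import (
    SampleSpec,
    TraceSet,
    detect_events,
    extract_ipr,
    simulate_traces,
)
from qbead.detect import estimate_baseline, normalize, robust_noise_scale

from conftest import TRANSIT, duration_for, fast_settings


def match_events(events, gt, tol):
    """Greedy apex-time matching of detected events to ground truth."""
    det = np.array([e.apex_time for e in events.events])
    truth = gt.t_apex.to_numpy()
    used = np.zeros(det.size, dtype=bool)
    hits = 0
    for t in truth:
        d = np.abs(det - t)
        d[used] = np.inf
        if d.size and d.min() < tol:
            used[int(np.argmin(d))] = True
            hits += 1
    return hits, int((~used).sum())  # true positives, unmatched detections


class TestBaseline:
    def test_constant_trace(self):
        x = np.full(2000, 3.7)
        np.testing.assert_allclose(estimate_baseline(x, 101), 3.7)

    def test_median_robust_to_narrow_pulse(self):
        x = np.full(4000, 2.0)
        x[2000:2060] += 1.0  # pulse occupies < 10% of the window
        np.testing.assert_allclose(estimate_baseline(x, 801), 2.0)

    def test_ramp_lag_bound(self):
        """Centered median of a linear ramp tracks it; edge error <= slope*window/2."""
        slope = 0.5
        x = 10.0 + slope * np.arange(3000)
        win = 301
        b = estimate_baseline(x, win)
        interior = slice(win, 3000 - win)
        np.testing.assert_allclose(b[interior], x[interior], atol=1e-9)
        assert np.max(np.abs(b - x)) <= slope * win / 2 + 1e-9

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline(np.ones(100), 100)


class TestNormalize:
    def test_identity_channel(self):
        b = np.full(50, 2.0)
        np.testing.assert_allclose(normalize(b.copy(), b), 0.0)

    def test_single_deviation(self):
        b = np.full(50, 2.0)
        c = b.copy()
        c[10] = 2.0 * 1.05
        out = normalize(c, b)
        assert out[10] == pytest.approx(0.05)
        assert np.count_nonzero(out) == 1

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(FloatingPointError):
            normalize(np.ones(10), np.zeros(10))


class TestNoiseScale:
    def test_gaussian_noise_recovered(self):
        x = np.random.default_rng(0).normal(0, 2.5, 100_000)
        assert robust_noise_scale(x, 5.0) == pytest.approx(2.5, rel=0.02)

    def test_insensitive_to_sparse_events(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1.0, 100_000)
        x[::200] += 50.0  # 0.5% contamination
        assert robust_noise_scale(x, 5.0) == pytest.approx(1.0, rel=0.03)


class TestDetectEvents:
    def test_flat_noiseless_trace_no_events(self, detector, panel):
        acq = fast_settings(duration=5.0, noise_sd=0.0, drift_amplitude=0.0)
        n = int(acq.duration * acq.sampling_rate)
        traces = TraceSet(
            np.arange(n) / acq.sampling_rate,
            np.ones((len(panel), n)),
            panel,
            acq,
        )
        assert len(detect_events(traces, detector)) == 0

    def test_recovers_injected_events(self, bare_traces_50, detector):
        events = detect_events(bare_traces_50, detector)
        gt = bare_traces_50.ground_truth
        tp, fp = match_events(events, gt, tol=TRANSIT)
        assert tp == len(gt) == 50
        assert fp == 0
        assert all(not e.doublet_flag for e in events.events)

    def test_double_peak_yields_single_event(self, noisefree_traces_20, detector):
        """Each two-lobed pulse is one bead: one event per injected transit."""
        events = detect_events(noisefree_traces_20, detector)
        assert len(events) == len(noisefree_traces_20.ground_truth)

    def test_threshold_monotonicity(self, bare_traces_50, detector):
        counts = [
            len(detect_events(bare_traces_50, dataclasses.replace(detector, threshold_k=k)))
            for k in (3.0, 5.0, 8.0, 12.0, 20.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_detection_idempotent_on_reconstruction(self, bare_traces_50, detector):
        """Re-detecting a trace rebuilt from detected events preserves them."""
        events = detect_events(bare_traces_50, detector)
        traces = bare_traces_50
        rate = traces.settings.sampling_rate
        from qbead import make_template

        tmpl = make_template(TRANSIT, rate).waveform
        n = traces.n_samples
        channels = np.ones((traces.channels.shape[0], n))
        for e in events.events:
            s = int(round(e.apex_time * rate)) - int(np.argmax(tmpl))
            s = max(s, 0)
            sl = slice(s, min(s + tmpl.size, n))
            channels[:, sl] += e.ipr[:, None] * tmpl[None, : sl.stop - sl.start]
        rebuilt = TraceSet(traces.time, channels, traces.panel, traces.settings)
        re_events = detect_events(rebuilt, detector)
        assert len(re_events) == len(events)
        apex_a = np.array([e.apex_time for e in events.events])
        apex_b = np.array([e.apex_time for e in re_events.events])
        np.testing.assert_allclose(apex_b, apex_a, atol=TRANSIT / 2)

    def test_doublets_flagged(self, circuit, panel, shell_map):
        spec = SampleSpec("s", 0, 0.0, 60)
        acq = fast_settings(
            duration=duration_for(60), doublet_probability=0.35, seed=19
        )
        traces = simulate_traces(spec, circuit, acq, panel, shell_map)
        assert traces.ground_truth.doublet.any()
        events = detect_events(traces)
        assert any(e.doublet_flag for e in events.events)
        assert events.n_beads < len(events)

    def test_empty_trace_rejected(self, detector, panel):
        acq = fast_settings(duration=5.0)
        with pytest.raises(ValueError):
            detect_events(
                TraceSet(np.empty(0), np.empty((len(panel), 0)), panel, acq), detector
            )


class TestExtractIpr:
    def test_noise_free_ipr_exact(self, noisefree_traces_20, detector):
        """Without noise the extracted IPR equals the injected amplitude."""
        events = detect_events(noisefree_traces_20, detector)
        gt = noisefree_traces_20.ground_truth
        amps = noisefree_traces_20.true_amplitudes()
        assert len(events) == len(gt)
        for e, a in zip(events.events, amps):
            np.testing.assert_allclose(e.ipr, a, rtol=1e-6)

    def test_extract_matches_detect(self, noisefree_traces_20, detector):
        events = detect_events(noisefree_traces_20, detector)
        e = events.events[0]
        np.testing.assert_allclose(
            extract_ipr(e, noisefree_traces_20, detector), e.ipr, rtol=1e-12
        )

    def test_scaling_linearity(self, noisefree_traces_20, detector):
        """Doubling all channel deviations doubles every IPR."""
        traces = noisefree_traces_20
        scaled = TraceSet(
            traces.time,
            1.0 + 2.0 * (traces.channels - 1.0),
            traces.panel,
            traces.settings,
            traces.ground_truth,
        )
        a = detect_events(traces, detector)
        b = detect_events(scaled, detector)
        assert len(a) == len(b)
        np.testing.assert_allclose(b.ipr_matrix(), 2 * a.ipr_matrix(), rtol=1e-6)

    def test_out_of_bounds_window_rejected(self, noisefree_traces_20, detector):
        from qbead import Event

        ev = Event(0, noisefree_traces_20.n_samples + 10, 0.0, 0.1, np.zeros(8))
        with pytest.raises(ValueError):
            extract_ipr(ev, noisefree_traces_20, detector)
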