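"""SPV extraction: quick-phase handling, event detection, period statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvslab import (
    SPVTrace,
    compute_spv,
    detect_events,
    detect_quick_phases,
    extract_spv,
    period_summaries,
    run_paradigm,
    synth_eye_trace,
)
from mvslab.errors import EventNotFoundError, UnsupportedInputError, WindowError
from mvslab.synth import SubjectParams

FS = 100.0


def _subject(noise=0.0, ecc=5.0):
    return SubjectParams(gain=1.0, bias=0.0, ecc_limit=ecc, noise_sd=noise,
                         vertigo_offset=0.0)


def _sawtooth(duration=60.0, spv=-15.0, ecc=5.0, seed=0):
    t = np.arange(int(duration * FS) + 1) / FS
    profile = np.full(t.size, spv)
    rng = np.random.default_rng(seed)
    pos, qp = synth_eye_trace(t, profile, _subject(ecc=ecc), rng)
    return t, pos, qp, profile


class TestQuickPhaseDetection:
    def test_pure_drift_not_flagged(self):
        t = np.arange(0, 10, 1 / FS)
        pos = 10.0 * t  # 10 deg/s drift, well under threshold
        assert detect_quick_phases(t, pos).shape == (0, 2)

    @given(slope=st.floats(-40.0, 40.0))
    @settings(max_examples=25, deadline=None)
    def test_subthreshold_drift_never_flagged(self, slope):
        t = np.arange(0, 5, 1 / FS)
        assert detect_quick_phases(t, slope * t).size == 0

    def test_constant_position_empty(self):
        t = np.arange(0, 10, 1 / FS)
        assert detect_quick_phases(t, np.zeros_like(t)).size == 0

    def test_sawtooth_resets_all_detected_no_spurious(self):
        t, pos, qp_true, _ = _sawtooth()
        detected = detect_quick_phases(t, pos)
        assert detected.shape[0] == qp_true.shape[0]
        for (a, b), (c, d) in zip(qp_true, detected):
            assert max(a, c) < min(b, d)  # intervals overlap

    def test_sparse_sampling_rejected(self):
        t = np.arange(0, 10, 0.1)  # 10 Hz
        with pytest.raises(UnsupportedInputError):
            detect_quick_phases(t, np.zeros_like(t))


class TestComputeSPV:
    def test_sawtooth_recovery(self):
        t, pos, qp, profile = _sawtooth()
        trace = compute_spv(t, pos, qp)
        core = slice(int(2 * FS), int(58 * FS))
        rmse = np.sqrt(np.mean((trace.spv[core] - profile[core]) ** 2))
        assert rmse < 1.0

    def test_static_eye_gives_zero(self):
        t = np.arange(0, 20, 1 / FS)
        trace = compute_spv(t, np.zeros_like(t), np.empty((0, 2), int))
        assert np.allclose(trace.spv, 0.0, atol=1e-9)

    def test_mask_conservation(self):
        t, pos, qp, _ = _sawtooth()
        detected = detect_quick_phases(t, pos)
        trace = compute_spv(t, pos, detected)
        excised = int((~trace.mask).sum())
        assert excised == int(sum(b - a for a, b in detected))

    def test_model_trace_round_trip(self, params, rng):
        res = run_paradigm(params, entry_s=20.0, dwell_s=120.0, exit_s=20.0,
                           pre_s=60.0, post_s=60.0)
        t = np.arange(int(res.time[-1] * FS) + 1) / FS
        profile = np.interp(t, res.time, res.horizontal)
        pos, _ = synth_eye_trace(t, profile, _subject(), rng)
        trace = extract_spv(t, pos)
        core = slice(int(2 * FS), -int(2 * FS))
        rmse = np.sqrt(np.mean((trace.spv[core] - profile[core]) ** 2))
        assert rmse < 1.0

    def test_desaccading_bias_insensitive_to_quick_phase_rate(self, rng):
        """Doubling the quick-phase rate changes the recovered mean by < 5%."""
        means = {}
        for ecc in (5.0, 2.5):
            t, pos, qp, _ = _sawtooth(ecc=ecc)
            trace = compute_spv(t, pos, detect_quick_phases(t, pos))
            means[ecc] = trace.spv[int(5 * FS):int(55 * FS)].mean()
        assert means[2.5] == pytest.approx(means[5.0], rel=0.05)


class TestEventDetection:
    @staticmethod
    def _trapezoid(entry=20.0, dwell=120.0, exit_=20.0, pre=60.0, post=60.0,
                   b0=7.0, base=0.5):
        t = np.arange(0, pre + entry + dwell + exit_ + post, 1 / FS)
        b = np.full(t.size, base)
        t1, t2, t3, t4 = pre, pre + entry, pre + entry + dwell, pre + entry + dwell + exit_
        m = (t >= t1) & (t < t2)
        b[m] = base + (b0 - base) * (t[m] - t1) / entry
        b[(t >= t2) & (t < t3)] = b0
        m = (t >= t3) & (t < t4)
        b[m] = b0 + (base - b0) * (t[m] - t3) / exit_
        return t, b, {"entry_start": t1, "entry_end": t2, "exit_start": t3,
                      "exit_end": t4}

    def test_trapezoid_events_recovered(self):
        """Detected events land within one sample of the analytic threshold
        crossings of the trapezoidal field profile."""
        b0, base, entry = 7.0, 0.5, 20.0
        t, b, truth = self._trapezoid(b0=b0, base=base, entry=entry)
        ev = detect_events(t, b, b0)
        lo = base + 0.05 * (b0 - base)
        hi = 0.95 * b0
        lo_frac = (lo - base) / (b0 - base)
        hi_frac = (hi - base) / (b0 - base)
        assert ev["entry_start"] == pytest.approx(
            truth["entry_start"] + lo_frac * entry, abs=1.5 / FS)
        assert ev["entry_end"] == pytest.approx(
            truth["entry_start"] + hi_frac * entry, abs=1.5 / FS)
        assert ev["exit_start"] == pytest.approx(
            truth["exit_start"] + (1.0 - hi_frac) * entry, abs=1.5 / FS)
        assert ev["exit_end"] == pytest.approx(
            truth["exit_start"] + (1.0 - lo_frac) * entry, abs=1.5 / FS)

    def test_constant_field_raises(self):
        t = np.arange(0, 100, 1 / FS)
        with pytest.raises(EventNotFoundError):
            detect_events(t, np.full(t.size, 0.5), 7.0)

    def test_monotone_rise_entry_found_exit_missing(self):
        t = np.arange(0, 100, 1 / FS)
        b = 0.5 + (7.0 - 0.5) * np.clip((t - 30.0) / 40.0, 0.0, 1.0)
        with pytest.raises(EventNotFoundError, match="exit"):
            detect_events(t, b, 7.0)


class TestPeriodSummaries:
    @staticmethod
    def _trace_from(t, spv):
        return SPVTrace(time=t, spv=spv, mask=np.ones(t.size, bool), fs=FS)

    def test_piecewise_constant_contract(self):
        t = np.arange(0, 500, 1 / FS)
        ev = {"entry_start": 100.0, "entry_end": 120.0,
              "exit_start": 350.0, "exit_end": 370.0}
        spv = np.where((t >= 100.0) & (t < 370.0), -10.0, 0.0)
        s = period_summaries(self._trace_from(t, spv), ev)
        assert s.baseline_mean == pytest.approx(0.0)
        assert s.per_steady_mean == pytest.approx(-10.0)
        assert s.per_peak == pytest.approx(-10.0)
        assert s.direction == -1

    def test_peaks_match_direct_scan_oracle(self, params):
        """Directional extrema equal a brute-force scan of the raw trace."""
        res = run_paradigm(params, entry_s=20.0, dwell_s=300.0, exit_s=20.0)
        t, h, dt = res.time, res.horizontal, res.dt
        trace = self._trace_from(t, h)
        s = period_summaries(trace, res.events)
        ev = res.events
        per_scan = h[int(ev["entry_start"] / dt):int((ev["entry_end"] + 60) / dt) + 1].min()
        post_scan = h[int(ev["exit_start"] / dt):int((ev["exit_end"] + 60) / dt) + 1].max()
        assert s.per_peak == per_scan
        assert s.post_peak == post_scan

    def test_peaks_have_opposite_signs_across_paradigms(self, both_sweep):
        assert np.all(both_sweep["per_peak"] * both_sweep["post_peak"] < 0)

    def test_insufficient_baseline_raises(self):
        t = np.arange(0, 200, 1 / FS)
        ev = {"entry_start": 10.0, "entry_end": 30.0,
              "exit_start": 150.0, "exit_end": 170.0}
        with pytest.raises(WindowError):
            period_summaries(self._trace_from(t, np.zeros(t.size)), ev)
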