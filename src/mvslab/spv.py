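"""Slow-phase velocity extraction and period statistics.

Nystagmus alternates slow compensatory drifts with fast resetting quick
phases.  The analysis pipeline differentiates eye position, excises the
quick phases (velocity above a saccadic threshold, dilated by a guard
margin), fills the gaps by interpolation and smooths with a running median.
Sign convention: right-beating nystagmus (slow phase to the left) is
reported as *negative* horizontal SPV, so the in-bore response of a supine
subject in a superconducting magnet is negative and the post-exit
aftereffect positive.

Four period statistics summarize each trial: the 30-s mean before entry
(baseline), the signed extremum after entry (per-peak), the 30-s mean
before exit (per-steady), and the signed extremum after exit (post-peak).
The two peaks are searched in the direction of, respectively, the in-bore
response and its reversal, so a slowly decaying in-bore tail is never
mistaken for the aftereffect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import butter, sosfiltfilt

from .errors import (
    EventNotFoundError,
    InsufficientDataError,
    UnsupportedInputError,
    WindowError,
)

#: Physiological bound on slow-phase velocity, deg/s.
SPV_BOUND = 100.0


@dataclass
class SPVTrace:
    """Desaccaded slow-phase velocity (deg/s) with a validity mask.

    ``mask`` is False wherever samples were excised (quick phases); the
    values there are interpolated placeholders.
    """

    time: np.ndarray
    spv: np.ndarray
    mask: np.ndarray
    fs: float


@dataclass
class PeriodSummary:
    """The four per-trial period statistics (deg/s) and the event times used."""

    baseline_mean: float
    per_peak: float
    per_steady_mean: float
    post_peak: float
    events: dict
    direction: int  # sign of the in-bore response (-1: right-beating)


def _sampling_rate(time: np.ndarray) -> float:
    steps = np.diff(time)
    if steps.size == 0 or not np.allclose(steps, steps[0], rtol=1e-4, atol=1e-9):
        raise UnsupportedInputError("trace must be uniformly sampled")
    return 1.0 / float(steps[0])


def detect_quick_phases(
    time: np.ndarray,
    position: np.ndarray,
    velocity_threshold: float = 60.0,
    min_separation: float = 0.05,
    guard: float = 0.02,
) -> np.ndarray:
    """Locate quick-phase (saccadic) intervals in an eye-position trace.

    Returns an (k, 2) integer array of half-open sample intervals
    ``[start, stop)``, sorted and non-overlapping.  Intervals are grown by
    ``guard`` seconds on each side and merged when closer than
    ``min_separation`` seconds.  Requires sampling at >= 50 Hz so that
    saccades are resolvable.
    """
    fs = _sampling_rate(time)
    if fs < 50.0:
        raise UnsupportedInputError(
            f"sampling rate {fs:.1f} Hz too sparse for quick-phase detection (need >= 50 Hz)"
        )
    vel = np.gradient(np.asarray(position, float), time)
    above = np.abs(vel) > velocity_threshold
    if not above.any():
        return np.empty((0, 2), dtype=int)
    guard_n = int(round(guard * fs))
    gap_n = int(round(min_separation * fs))
    idx = np.flatnonzero(above)
    starts = [idx[0]]
    stops = []
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a > 1:
            stops.append(a + 1)
            starts.append(b)
    stops.append(idx[-1] + 1)
    intervals = []
    for a, b in zip(starts, stops):
        a = max(0, a - guard_n)
        b = min(position.size, b + guard_n)
        if intervals and a - intervals[-1][1] <= gap_n:
            intervals[-1][1] = b
        else:
            intervals.append([a, b])
    return np.array(intervals, dtype=int)


def compute_spv(
    time: np.ndarray,
    position: np.ndarray,
    quick_phase_intervals: np.ndarray,
    smooth_window: float = 1.0,
    lowpass_hz: Optional[float] = 0.1,
    bound: float = SPV_BOUND,
) -> SPVTrace:
    """Differentiate, excise quick phases, interpolate and smooth.

    Smoothing is a running median (robust to residual quick-phase edges)
    followed by a zero-phase second-order Butterworth low-pass: slow-phase
    velocity in this paradigm evolves on tens of seconds (the fastest system
    time constant is the 16-s storage integrator), while position
    measurement noise differentiates into broadband velocity noise that
    would otherwise bias extremum searches outward.  Set ``lowpass_hz`` to
    None to disable the second stage.
    """
    fs = _sampling_rate(time)
    vel = np.gradient(np.asarray(position, float), time)
    mask = np.ones(vel.size, dtype=bool)
    for a, b in np.asarray(quick_phase_intervals, dtype=int).reshape(-1, 2):
        mask[a:b] = False
    if mask.any() and not mask.all():
        valid_idx = np.flatnonzero(mask)
        vel = np.interp(np.arange(vel.size), valid_idx, vel[valid_idx])
    size = int(round(smooth_window * fs))
    size = max(size | 1, 1)  # odd kernel
    if size > 1:
        vel = median_filter(vel, size=size, mode="nearest")
    if lowpass_hz is not None and lowpass_hz < fs / 2.0:
        sos = butter(2, lowpass_hz, btype="low", fs=fs, output="sos")
        padlen = min(3 * int(fs / lowpass_hz), vel.size - 1)
        if padlen > 12:
            vel = sosfiltfilt(sos, vel, padlen=padlen)
    vel = np.clip(vel, -bound, bound)
    return SPVTrace(time=np.asarray(time, float), spv=vel, mask=mask, fs=fs)


def extract_spv(
    time: np.ndarray,
    position: np.ndarray,
    velocity_threshold: float = 60.0,
    smooth_window: float = 1.0,
) -> SPVTrace:
    """Convenience wrapper: quick-phase detection followed by SPV computation."""
    intervals = detect_quick_phases(time, position, velocity_threshold=velocity_threshold)
    return compute_spv(time, position, intervals, smooth_window=smooth_window)


def detect_events(time: np.ndarray, field: np.ndarray, b0: float) -> dict:
    """Locate entry/exit times from the magnetometer channel.

    Entry runs from the first crossing of a low threshold (baseline plus 5%
    of the baseline-to-B0 span) to the first sample at 95% of ``b0``; exit
    from the last sample at 95% of ``b0`` to the next return below the low
    threshold.  Raises :class:`EventNotFoundError` naming the missing event.
    """
    t = np.asarray(time, float)
    b = np.asarray(field, float)
    base = float(np.median(b[t <= t[0] + 10.0]))
    lo = base + 0.05 * (b0 - base)
    hi = 0.95 * b0
    if lo >= hi:
        raise EventNotFoundError("baseline field too close to b0 to separate events")
    high = np.flatnonzero(b >= hi)
    if high.size == 0:
        raise EventNotFoundError("entry not found: field never reaches 95% of b0")
    above_lo = np.flatnonzero(b >= lo)
    entry_start_i = int(above_lo[0])
    entry_end_i = int(high[0])
    exit_start_i = int(high[-1])
    below = np.flatnonzero(b[exit_start_i:] <= lo)
    if below.size == 0:
        raise EventNotFoundError("exit not found: field never returns to baseline")
    exit_end_i = exit_start_i + int(below[0])
    return {
        "entry_start": float(t[entry_start_i]),
        "entry_end": float(t[entry_end_i]),
        "exit_start": float(t[exit_start_i]),
        "exit_end": float(t[exit_end_i]),
    }


def _window_indices(time: np.ndarray, t0: float, t1: float,
                    end_exclusive: bool = False) -> slice:
    i0 = int(np.searchsorted(time, t0, side="left"))
    i1 = int(np.searchsorted(time, t1, side="left" if end_exclusive else "right"))
    return slice(i0, i1)


def _masked_mean(trace: SPVTrace, sl: slice) -> float:
    vals = trace.spv[sl]
    m = trace.mask[sl]
    if not m.any():
        raise InsufficientDataError("no valid samples in summary window")
    return float(vals[m].mean())


def period_summaries(
    trace: SPVTrace,
    events: dict,
    baseline_window: float = 30.0,
    steady_window: float = 30.0,
    search_window: float = 60.0,
) -> PeriodSummary:
    """Compute baseline, per-peak, per-steady and post-peak for one trial.

    Means use valid (non-excised) samples only; peaks are scanned on the
    smoothed trace.  The in-bore response direction is the sign of the dwell
    mean relative to baseline; the post-peak is searched in the opposite
    direction (the aftereffect reverses).
    """
    t = trace.time
    ev = events
    for key in ("entry_start", "entry_end", "exit_start", "exit_end"):
        if key not in ev:
            raise WindowError(f"events missing {key!r}")
    if ev["entry_start"] - t[0] < baseline_window - 1e-9:
        raise WindowError(
            f"need >= {baseline_window:.0f} s of data before entry "
            f"(have {ev['entry_start'] - t[0]:.1f} s)"
        )
    if ev["exit_start"] - ev["entry_end"] < steady_window - 1e-9:
        raise WindowError(
            f"need >= {steady_window:.0f} s of dwell before exit for the per-steady mean"
        )
    baseline = _masked_mean(trace, _window_indices(t, ev["entry_start"] - baseline_window,
                                                   ev["entry_start"], end_exclusive=True))
    per_steady = _masked_mean(trace, _window_indices(t, ev["exit_start"] - steady_window,
                                                     ev["exit_start"], end_exclusive=True))
    dwell_mean = _masked_mean(trace, _window_indices(t, ev["entry_end"], ev["exit_start"]))
    rel = dwell_mean - baseline
    direction = -1 if rel < 0 or abs(rel) < 1e-12 else 1

    per_sl = _window_indices(t, ev["entry_start"], ev["entry_end"] + search_window)
    per_seg = trace.spv[per_sl]
    per_peak = float(direction * np.max(direction * per_seg))

    post_sl = _window_indices(t, ev["exit_start"], ev["exit_end"] + search_window)
    post_seg = trace.spv[post_sl]
    post_peak = float(-direction * np.max(-direction * post_seg))

    return PeriodSummary(
        baseline_mean=baseline,
        per_peak=per_peak,
        per_steady_mean=per_steady,
        post_peak=post_peak,
        events=dict(ev),
        direction=direction,
    )
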