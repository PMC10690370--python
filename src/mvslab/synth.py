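"""Synthetic cohorts of MVS recordings with hidden ground truth.

The generator emulates the structure of a 7-T entry-duration experiment:
eight subjects, three entry/exit durations (20, 120, 300 s) in randomized
order within a session, 2 min of fringe-field baseline, a 5-min dwell at
isocenter and 4 min after exit.  Each trial's true slow-phase velocity
profile is the control-systems model's output for that condition, scaled by
a per-subject gain and anchored (per condition) to the cohort-mean per-peak
and post-peak amplitudes the study conditions define; a small negative
baseline bias reproduces the direction-biasing effect of the fringe field.
Eye-position channels are synthesized by integrating the SPV and inserting
resetting quick phases, and ordinal vertigo ratings are drawn from a latent
logistic model driven by the true peak amplitude.

Ground truth (true profiles, peaks, latent vertigo) is retained so that the
extraction and statistics stages can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .field import FieldMap, build_field_map
from .io import RECORDING_COLUMNS, Recording, write_recording
from .model import ModelParams, default_params, run_paradigm
from .spv import SPVTrace, period_summaries

#: Cohort-mean peak anchors per entry/exit duration condition (deg/s):
#: (per-peak, post-peak).  These are the condition means the synthetic study
#: is built around.
DEFAULT_PEAK_ANCHORS = {
    20.0: (-15.5, 5.4),
    120.0: (-12.9, 4.0),
    300.0: (-9.0, 2.2),
}

VERTIGO_CATEGORIES = ("none", "low", "moderate", "high")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generative parameters."""

    gain: float            # multiplicative response gain (log-normal across subjects)
    bias: float            # baseline SPV bias in the fringe field, deg/s
    ecc_limit: float       # eye eccentricity (deg) at which a quick phase resets
    noise_sd: float        # position measurement noise, deg
    vertigo_offset: float  # subject offset on the latent vertigo scale

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.noise_sd < 0 or self.ecc_limit <= 0:
            raise InvalidParameterError("gain and ecc_limit must be > 0, noise_sd >= 0")


@dataclass(frozen=True)
class VertigoParams:
    """Latent-scale cumulative model generating ordinal intensity ratings.

    latent = b0 + b_log_peak * log(1 + |peak|) + b_exit * [phase == exit]
             + subject offset + logistic(0, 1) noise,

    cut at increasing thresholds into none / low / moderate / high.  The
    defaults are moment-matched to two anchors: a zero peak is rated "none"
    with probability > 0.95, and the 20-s-condition entry peak (~15.5 deg/s)
    is rated moderate-or-high for nearly all subjects while the 300-s entry
    peak (~9 deg/s) is rated "none" for roughly three quarters.
    """

    b0: float = 0.0
    b_log_peak: float = 20.0
    b_exit: float = -3.0
    cuts: tuple = (47.4, 53.2, 56.7)
    duration_log_mean: float = math.log(75.0)
    duration_log_sd: float = 0.5
    exit_duration_factor: float = 0.6

    def __post_init__(self) -> None:
        if not (self.cuts[0] < self.cuts[1] < self.cuts[2]):
            raise InvalidParameterError("vertigo cuts must be strictly increasing")


@dataclass
class CohortTruth:
    """Hidden ground truth for a generated cohort.

    ``trials`` has one row per recording (subject, condition, order, true
    period statistics); ``ratings`` one row per trial x phase with the true
    latent value and category; ``profiles`` maps trial id to the true SPV
    profile on the recording grid.
    """

    trials: pd.DataFrame
    ratings: pd.DataFrame
    profiles: dict
    manifest: dict


def draw_subject_params(
    rng: np.random.Generator,
    gain_log_sd: float = 0.25,
    bias_mean: float = -0.33,
    bias_sd: float = 0.2,
    noise_sd: float = 0.1,
    vertigo_offset_sd: float = 1.0,
) -> SubjectParams:
    """Draw one subject.  The gain is log-normal with unit mean.

    The fringe-bias mean (-0.33 deg/s) combines with the model's own settled
    fringe-field response (about -0.27 deg/s at table home) to give cohort
    baselines near the -0.6 deg/s the study conditions define.
    """
    gain = float(np.exp(rng.normal(-0.5 * gain_log_sd**2, gain_log_sd)))
    return SubjectParams(
        gain=gain,
        bias=float(rng.normal(bias_mean, bias_sd)),
        ecc_limit=float(rng.uniform(3.5, 6.0)),
        noise_sd=noise_sd,
        vertigo_offset=float(rng.normal(0.0, vertigo_offset_sd)),
    )


def synth_eye_trace(
    time: np.ndarray,
    spv: np.ndarray,
    subject: SubjectParams,
    rng: np.random.Generator,
    saccade_speed: float = 300.0,
):
    """Integrate SPV into eye position with resetting quick phases.

    Whenever the eye drifts past the subject's eccentricity limit a quick
    phase at saccadic speed resets it toward zero.  Returns
    ``(position, quick_phase_intervals)`` where the intervals are half-open
    sample index pairs (the generator's ground truth for desaccading tests).
    White measurement noise is *not* added here so that callers can overlay
    independent noise per eye.
    """
    dt = float(time[1] - time[0])
    n = time.size
    pos = np.empty(n)
    pos[0] = 0.0
    intervals = []
    i = 1
    while i < n:
        p = pos[i - 1] + spv[i - 1] * dt
        if abs(p) > subject.ecc_limit:
            # quick phase: constant saccadic velocity back toward zero
            start = i
            direction = -np.sign(p)
            while i < n and p * direction < 0:
                step = direction * saccade_speed * dt
                if abs(step) >= abs(p):
                    p = 0.0
                else:
                    p += step
                pos[i] = p
                i += 1
            intervals.append([start - 1, min(i + 1, n)])
            continue
        pos[i] = p
        i += 1
    return pos, np.array(intervals, dtype=int).reshape(-1, 2)


def synth_vertigo(
    true_peak: float,
    phase: str,
    subject: SubjectParams,
    rng: np.random.Generator,
    params: Optional[VertigoParams] = None,
):
    """Draw an ordinal intensity rating and sensation duration for one peak.

    Returns ``(category, duration_s, latent)``; duration is zero when the
    rating is "none", and exits produce shorter sensations than entries.
    """
    vp = params or VertigoParams()
    if phase not in ("entry", "exit"):
        raise InvalidParameterError("phase must be 'entry' or 'exit'")
    latent = (
        vp.b0
        + vp.b_log_peak * math.log1p(abs(true_peak))
        + (vp.b_exit if phase == "exit" else 0.0)
        + subject.vertigo_offset
        + float(rng.logistic(0.0, 1.0))
    )
    k = int(np.searchsorted(np.asarray(vp.cuts), latent, side="left"))
    category = VERTIGO_CATEGORIES[k]
    if category == "none":
        duration = 0.0
    else:
        duration = float(rng.lognormal(vp.duration_log_mean, vp.duration_log_sd))
        if phase == "exit":
            duration *= vp.exit_duration_factor
    return category, duration, latent


def _anchored_scale(
    time: np.ndarray,
    events: dict,
    s_per: float,
    s_post: float,
) -> np.ndarray:
    """Time-varying scale factor blending from s_per to s_post over the exit."""
    scale = np.full(time.size, s_per)
    t3, t4 = events["exit_start"], events["exit_end"]
    if t4 > t3:
        m = (time >= t3) & (time <= t4)
        scale[m] = s_per + (s_post - s_per) * (time[m] - t3) / (t4 - t3)
    scale[time > t4] = s_post
    return scale


def generate_cohort(
    n_subjects: int = 8,
    conditions: Sequence[float] = (20.0, 120.0, 300.0),
    model_params: Optional[ModelParams] = None,
    seed: int = 0,
    fs: float = 100.0,
    dwell_s: float = 300.0,
    pre_s: float = 120.0,
    post_s: float = 240.0,
    fieldmap: Optional[FieldMap] = None,
    peak_anchors: Optional[dict] = DEFAULT_PEAK_ANCHORS,
    vertigo_params: Optional[VertigoParams] = None,
    out_dir=None,
):
    """Generate a full synthetic cohort.

    Every subject completes each condition once, in an order randomized per
    subject.  Returns ``(recordings, truth)`` where ``recordings`` is a list
    of (filename, :class:`~mvslab.io.Recording`) pairs (also written to
    ``out_dir`` when given) and ``truth`` is a :class:`CohortTruth`.

    ``peak_anchors`` maps condition duration to the cohort-mean (per-peak,
    post-peak) amplitudes; conditions without an anchor use the raw model
    amplitudes.  Deterministic given ``seed``.
    """
    if n_subjects < 2:
        raise InvalidParameterError("need at least 2 subjects")
    params = model_params or default_params()
    fmap = fieldmap or build_field_map()
    vp = vertigo_params or VertigoParams()
    rng = np.random.default_rng(seed)

    # one model run per condition, shared across subjects
    cond_profiles = {}
    for cond in conditions:
        res = run_paradigm(
            params, fieldmap=fmap, entry_s=float(cond), dwell_s=dwell_s,
            exit_s=float(cond), b0=fmap.b0, pre_s=pre_s, post_s=post_s,
        )
        t_out = np.round(np.arange(int(round(res.time[-1] * fs)) + 1) / fs, 9)
        spv_h = np.interp(t_out, res.time, res.horizontal)
        cond_profiles[cond] = (t_out, spv_h, res)

    subjects = [draw_subject_params(rng) for _ in range(n_subjects)]
    # normalize gains to unit sample mean: the anchored amplitudes are the
    # *cohort* condition means, so the drawn cohort must realize them
    import dataclasses as _dc

    mean_gain = float(np.mean([s.gain for s in subjects]))
    subjects = [_dc.replace(s, gain=s.gain / mean_gain) for s in subjects]
    orders = [rng.permutation(len(conditions)) for _ in range(n_subjects)]

    recordings = []
    trial_rows = []
    rating_rows = []
    profiles = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for s_idx, (subj, order) in enumerate(zip(subjects, orders)):
        for slot, cond_idx in enumerate(order):
            cond = float(conditions[cond_idx])
            t_out, spv_model, res = cond_profiles[cond]
            events = dict(res.events)
            clean = SPVTrace(time=res.time, spv=res.horizontal,
                             mask=np.ones(res.time.size, bool), fs=1.0 / res.dt)
            model_summ = period_summaries(clean, events)
            if peak_anchors is not None and cond in peak_anchors:
                a_per, a_post = peak_anchors[cond]
                s_per = a_per / model_summ.per_peak
                s_post = a_post / model_summ.post_peak
            else:
                s_per = s_post = 1.0
            scale = _anchored_scale(t_out, events, s_per, s_post)
            true_spv = subj.gain * scale * spv_model + subj.bias

            pos, qp = synth_eye_trace(t_out, true_spv, subj, rng)
            lh = pos + rng.normal(0.0, subj.noise_sd, pos.size)
            rh = pos + rng.normal(0.0, subj.noise_sd, pos.size)
            lv = rng.normal(0.0, subj.noise_sd, pos.size)
            rv = rng.normal(0.0, subj.noise_sd, pos.size)
            lt = rng.normal(0.0, subj.noise_sd, pos.size)
            rt = rng.normal(0.0, subj.noise_sd, pos.size)
            b_head = np.interp(t_out, res.time,
                               _b_head_from_events(res.time, events, fmap))
            b_meas = np.clip(b_head + rng.normal(0.0, 0.005, t_out.size), 0.0, None)
            accel = np.column_stack([
                -1.0 + rng.normal(0.0, 0.005, t_out.size),
                rng.normal(0.0, 0.005, t_out.size),
                rng.normal(0.0, 0.005, t_out.size),
            ])

            trial_id = f"s{s_idx:02d}_c{int(cond):03d}"
            truth_trace = SPVTrace(time=t_out, spv=true_spv,
                                   mask=np.ones(t_out.size, bool), fs=fs)
            truth_summ = period_summaries(truth_trace, events)
            trial_rows.append({
                "trial_id": trial_id,
                "subject": f"S{s_idx:02d}",
                "condition": cond,
                "order_position": slot,
                "gain": subj.gain,
                "bias": subj.bias,
                "true_baseline": truth_summ.baseline_mean,
                "true_per_peak": truth_summ.per_peak,
                "true_per_steady": truth_summ.per_steady_mean,
                "true_post_peak": truth_summ.post_peak,
                "n_quick_phases": int(qp.shape[0]),
            })
            profiles[trial_id] = (t_out, true_spv, events)

            for phase, peak in (("entry", truth_summ.per_peak),
                                ("exit", truth_summ.post_peak)):
                cat, dur, latent = synth_vertigo(peak, phase, subj, rng, vp)
                rating_rows.append({
                    "trial_id": trial_id,
                    "subject": f"S{s_idx:02d}",
                    "condition": cond,
                    "phase": phase,
                    "rating": cat,
                    "duration_s": dur,
                    "latent": latent,
                })

            df = pd.DataFrame({
                "time_s": t_out, "lh": lh, "lv": lv, "lt": lt,
                "rh": rh, "rv": rv, "rt": rt,
                "ax": accel[:, 0], "ay": accel[:, 1], "az": accel[:, 2],
                "b_tesla": b_meas,
            })[RECORDING_COLUMNS]
            rec = Recording(data=df, fs=fs, meta={
                "subject": f"S{s_idx:02d}", "condition": f"{cond:g}",
                "order_position": str(slot), "seed": str(seed), "b0": f"{fmap.b0:g}",
            })
            fname = f"{trial_id}.csv"
            if out_path is not None:
                write_recording(out_path / fname, rec)
            recordings.append((fname, rec))

    truth = CohortTruth(
        trials=pd.DataFrame(trial_rows),
        ratings=pd.DataFrame(rating_rows),
        profiles=profiles,
        manifest={
            "seed": seed, "n_subjects": n_subjects,
            "conditions": [float(c) for c in conditions],
            "fs": fs, "dwell_s": dwell_s, "pre_s": pre_s, "post_s": post_s,
            "b0": fmap.b0,
            "files": [f for f, _ in recordings],
        },
    )
    return recordings, truth


def _b_head_from_events(time: np.ndarray, events: dict, fmap: FieldMap) -> np.ndarray:
    """Reconstruct the field-at-head trace for a constant-rate paradigm."""
    from .field import HOME_POSITION_CM

    b_home = float(fmap.field_at(HOME_POSITION_CM))
    b = np.full(time.size, b_home)
    t1, t2 = events["entry_start"], events["entry_end"]
    t3, t4 = events["exit_start"], events["exit_end"]
    if t2 > t1:
        m = (time >= t1) & (time < t2)
        b[m] = b_home + (fmap.b0 - b_home) * (time[m] - t1) / (t2 - t1)
    b[(time >= t2) & (time < t3)] = fmap.b0
    if t4 > t3:
        m = (time >= t3) & (time < t4)
        b[m] = fmap.b0 + (b_home - fmap.b0) * (time[m] - t3) / (t4 - t3)
    b[time >= t4] = b_home
    return b


def sample_peak_table(
    n_subjects: int = 8,
    condition_means: Optional[dict] = None,
    subject_sd: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    return_truth: bool = False,
):
    """Summary-level cohort sampler for statistical validation.

    Draws one peak value per subject x condition as
    ``condition mean + subject offset + N(0, noise_sd)``, the additive
    structure the condition-effect model assumes.  Used for Monte-Carlo
    coverage and type-I-error studies where synthesizing full recordings
    would be pointless.

    With ``return_truth=True`` also returns the cohort's realized true
    condition means (population mean plus this cohort's mean subject
    offset) — the estimand of a fixed-subject-effects fit.
    """
    means = condition_means or {c: a[0] for c, a in DEFAULT_PEAK_ANCHORS.items()}
    rng = np.random.default_rng(seed)
    rows = []
    offsets = rng.normal(0.0, subject_sd, n_subjects)
    for s in range(n_subjects):
        for cond, mu in means.items():
            rows.append({
                "subject": f"S{s:02d}",
                "condition": float(cond),
                "value": mu + offsets[s] + rng.normal(0.0, noise_sd),
            })
    df = pd.DataFrame(rows)
    if return_truth:
        realized = {float(c): mu + float(np.mean(offsets)) for c, mu in means.items()}
        return df, realized
    return df
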