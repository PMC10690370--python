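"""Table-motion profiles and the Lorentz-force stimulus they induce.

Two entry strategies are modelled.  A *constant table velocity* profile is
what the scanner's motorized bed provides; because the fringe field is
non-linear in position, the field at the head then rises non-linearly in
time.  A *constant Tesla-rate* profile makes the field at the head linear in
time, which requires a sigmoid table-velocity profile obtained by inverting
the field map.

The inner-ear stimulus is a Lorentz force on the endolymph that scales
linearly with field strength.  Current-path geometry and current density are
lumped into a single gain ``kappa`` expressed as equivalent angular
acceleration per Tesla, so the model input is simply
``alpha(t) = kappa * B_head(t) * axis_unit``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import FieldRangeError, InvalidParameterError
from .field import HOME_POSITION_CM, FieldMap

#: Stimulated rotation axis for a supine subject: the head-yaw axis, which
#: produces horizontal nystagmus.  The sign convention makes a positive field
#: drive right-beating (negative horizontal SPV) nystagmus.
DEFAULT_AXIS = np.array([0.0, 0.0, 1.0])

#: Head-frame direction of gravity for a supine subject (toward the occiput,
#: i.e. the negative naso-occipital axis).
SUPINE_GRAVITY = np.array([-1.0, 0.0, 0.0])


@dataclass
class MotionProfile:
    """Head position versus time on a uniform grid.

    ``phase`` labels each sample as one of ``pre/entry/dwell/exit/post``;
    ``events`` holds the phase-boundary times actually present.
    """

    time: np.ndarray
    position: np.ndarray
    phase: np.ndarray
    dt: float
    events: dict

    @property
    def speed(self) -> np.ndarray:
        """Instantaneous table speed, cm/s (unsigned)."""
        return np.abs(np.gradient(self.position, self.time))

    def to_text(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time_s": self.time, "position_cm": self.position, "phase": self.phase}
        ).to_csv(path, index=False, float_format="%.6f")


@dataclass
class StimulusTrace:
    """Field at the head and the equivalent angular-acceleration input.

    ``alpha`` has shape (n, 3) in head coordinates, deg/s^2, and satisfies
    ``alpha[i] = kappa * b_head[i] * axis_unit`` at every sample.
    """

    time: np.ndarray
    b_head: np.ndarray
    alpha: np.ndarray
    kappa: float
    axis_unit: np.ndarray
    dt: float
    events: dict


def _time_grid(total: float, dt: float) -> np.ndarray:
    n = int(round(total / dt))
    return np.arange(n + 1) * dt


def constant_velocity_profile(travel: float, duration: float, dt: float = 0.05) -> MotionProfile:
    """Entry at uniform table speed, ending at the isocenter.

    The standard motorized 20-s entry covers 216 cm at 10.8 cm/s; the manual
    longer entries cover the 125 cm from the 1-T line at 1.04 and 0.417 cm/s.
    """
    if travel <= 0 or duration <= 0 or dt <= 0:
        raise InvalidParameterError("travel, duration and dt must be positive")
    t = _time_grid(duration, dt)
    pos = travel * (1.0 - t / duration)
    pos[-1] = 0.0
    phase = np.full(t.shape, "entry", dtype="<U5")
    return MotionProfile(
        time=t,
        position=pos,
        phase=phase,
        dt=dt,
        events={"entry_start": 0.0, "entry_end": duration},
    )


def constant_rate_profile(
    fieldmap: FieldMap,
    b_start: float,
    b_end: float,
    duration: float,
    dt: float = 0.05,
) -> MotionProfile:
    """Entry (or exit) at a constant Tesla rate.

    The field at the head is linear in time between ``b_start`` and
    ``b_end``; the table position follows the inverse of the field map, a
    sigmoid velocity profile.
    """
    if duration <= 0 or dt <= 0:
        raise InvalidParameterError("duration and dt must be positive")
    for b in (b_start, b_end):
        if b <= 0 or b > fieldmap.b0:
            raise FieldRangeError(
                f"field {b} T outside the map range (0, {fieldmap.b0}] T"
            )
    t = _time_grid(duration, dt)
    b = b_start + (b_end - b_start) * t / duration
    pos = fieldmap.position_at(b)
    label = "entry" if b_end >= b_start else "exit"
    events = (
        {"entry_start": 0.0, "entry_end": duration}
        if label == "entry"
        else {"exit_start": 0.0, "exit_end": duration}
    )
    return MotionProfile(
        time=t,
        position=pos,
        phase=np.full(t.shape, label, dtype="<U5"),
        dt=dt,
        events=events,
    )


def assemble_paradigm(
    fieldmap: FieldMap,
    entry_s: float,
    dwell_s: float,
    exit_s: float,
    pre_s: float = 120.0,
    post_s: float = 240.0,
    mode: str = "constant_rate",
    dt: float = 0.05,
    home_position: float = HOME_POSITION_CM,
) -> MotionProfile:
    """Concatenate pre -> entry -> dwell -> exit -> post on one uniform grid.

    During pre and post the head rests at ``home_position`` in the fringe
    field; the dwell is at the isocenter.  ``mode`` selects how the moving
    segments are shaped (``constant_rate`` or ``constant_velocity``).
    """
    if entry_s <= 0 or exit_s <= 0:
        raise InvalidParameterError("entry_s and exit_s must be positive")
    if min(dwell_s, pre_s, post_s) < 0 or dt <= 0:
        raise InvalidParameterError("durations must be >= 0 and dt > 0")
    if mode not in ("constant_rate", "constant_velocity"):
        raise InvalidParameterError(f"unknown mode {mode!r}")

    total = pre_s + entry_s + dwell_s + exit_s + post_s
    t = _time_grid(total, dt)
    t1, t2 = pre_s, pre_s + entry_s
    t3, t4 = t2 + dwell_s, t2 + dwell_s + exit_s
    b_home = float(fieldmap.field_at(home_position))

    pos = np.empty_like(t)
    phase = np.full(t.shape, "post", dtype="<U5")
    pre_m = t < t1
    ent_m = (t >= t1) & (t < t2)
    dwe_m = (t >= t2) & (t < t3)
    exi_m = (t >= t3) & (t < t4)
    pos[pre_m] = home_position
    pos[dwe_m] = 0.0
    pos[t >= t4] = home_position
    phase[pre_m] = "pre"
    phase[ent_m] = "entry"
    phase[dwe_m] = "dwell"
    phase[exi_m] = "exit"

    if mode == "constant_rate":
        frac_in = (t[ent_m] - t1) / entry_s
        pos[ent_m] = fieldmap.position_at(b_home + (fieldmap.b0 - b_home) * frac_in)
        frac_out = (t[exi_m] - t3) / exit_s
        pos[exi_m] = fieldmap.position_at(fieldmap.b0 + (b_home - fieldmap.b0) * frac_out)
    else:
        pos[ent_m] = home_position * (1.0 - (t[ent_m] - t1) / entry_s)
        pos[exi_m] = home_position * (t[exi_m] - t3) / exit_s

    events = {"entry_start": t1, "entry_end": t2, "exit_start": t3, "exit_end": t4}
    return MotionProfile(time=t, position=pos, phase=phase, dt=dt, events=events)


def stimulus_from_profile(
    profile: MotionProfile,
    fieldmap: FieldMap,
    kappa: float,
    axis_unit: Optional[np.ndarray] = None,
) -> StimulusTrace:
    """Convert head motion through the field into the model's input trace."""
    axis = DEFAULT_AXIS if axis_unit is None else np.asarray(axis_unit, dtype=float)
    norm = np.linalg.norm(axis)
    if not np.isclose(norm, 1.0, atol=1e-8):
        raise InvalidParameterError("axis_unit must be a unit vector")
    b = np.asarray(fieldmap.field_at(profile.position), dtype=float)
    alpha = kappa * b[:, None] * axis[None, :]
    return StimulusTrace(
        time=profile.time,
        b_head=b,
        alpha=alpha,
        kappa=kappa,
        axis_unit=axis,
        dt=profile.dt,
        events=dict(profile.events),
    )


def ramp_stimulus(
    b0: float,
    entry_s: float,
    dwell_s: float,
    exit_s: float,
    pre_s: float = 120.0,
    post_s: float = 240.0,
    kappa: float = 1.0,
    axis_unit: Optional[np.ndarray] = None,
    dt: float = 0.05,
    pre_field: float = 0.0,
) -> StimulusTrace:
    """Idealized stimulus: field at the head piecewise linear in time.

    This is the model-study path: the field ramps linearly from ``pre_field``
    to ``b0`` over the entry, dwells, and ramps back over the exit.  Entry or
    exit duration 0 produces a step (the "null-position" entry, where the
    stimulus switches on instantaneously).
    """
    if b0 <= 0 or dt <= 0 or min(entry_s, dwell_s, exit_s, pre_s, post_s) < 0:
        raise InvalidParameterError("b0 and dt must be positive; durations >= 0")
    axis = DEFAULT_AXIS if axis_unit is None else np.asarray(axis_unit, dtype=float)
    if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-8):
        raise InvalidParameterError("axis_unit must be a unit vector")

    total = pre_s + entry_s + dwell_s + exit_s + post_s
    t = _time_grid(total, dt)
    t1, t2 = pre_s, pre_s + entry_s
    t3, t4 = t2 + dwell_s, t2 + dwell_s + exit_s
    b = np.full(t.shape, pre_field, dtype=float)
    if entry_s > 0:
        m = (t >= t1) & (t < t2)
        b[m] = pre_field + (b0 - pre_field) * (t[m] - t1) / entry_s
    m = (t >= t2) & (t < t3) if dwell_s > 0 else np.zeros(t.shape, bool)
    b[m] = b0
    if exit_s > 0:
        m = (t >= t3) & (t < t4)
        b[m] = b0 + (pre_field - b0) * (t[m] - t3) / exit_s
    b[t >= t4] = pre_field
    if dwell_s > 0 and entry_s == 0:
        b[(t >= t1) & (t < t3)] = b0

    alpha = kappa * b[:, None] * axis[None, :]
    events = {"entry_start": t1, "entry_end": t2, "exit_start": t3, "exit_end": t4}
    return StimulusTrace(
        time=t, b_head=b, alpha=alpha, kappa=kappa, axis_unit=axis, dt=dt, events=events
    )
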