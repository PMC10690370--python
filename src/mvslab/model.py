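"""3D control-systems model of the VOR response to magnetic vestibular stimulation.

The model is a minimal realization of the elements classically invoked for
MVS nystagmus and its decay:

* semicircular-canal / afferent dynamics — a first-order lag driven by the
  equivalent angular acceleration of the Lorentz stimulus;
* **set-point adaptation** — three leaky operators in series with
  increasingly long time constants (80, 300, 3000 s).  Each operator removes
  only a *fraction* of its input (its adaptation weight), so adaptation is
  partial on experimental time scales: the in-bore response decays toward a
  plateau rather than to zero, and on exit the stored charge discharges as
  an oppositely-directed aftereffect;
* **velocity storage** — a leaky integrator (16 s) that prolongs the
  response beyond the canal signal;
* two cross-product loops — *tilt estimation*, which rotates an internal
  gravity estimate by the estimated head velocity and pulls it toward the
  otolith-sensed gravity, and *rotational feedback*, which suppresses stored
  velocity about earth-horizontal axes whenever the estimated gravity
  direction conflicts with the sensed one.  For a supine subject the
  stimulated yaw axis is earth-horizontal, so this loop actively quenches
  the MVS response.

State (18 components, all 3-vectors in head coordinates): canal afferent
``c``, adaptation charges ``a1..a3``, stored velocity ``V``, gravity
estimate ``g_hat``.  The slow-phase velocity output is
``SPV = -(g_direct * v + V)`` with ``v`` the adapted canal signal.

Equations (deg/s units; ``DEG`` converts the velocity estimate to rad/s
where it rotates the unit gravity estimate)::

    dc/dt   = alpha(t) - c / T_canal
    u0 = c;  u_i = u_{i-1} - a_i
    da_i/dt = (w_i * u_{i-1} - a_i) / T_adapt_i          i = 1..3
    dV/dt   = (g_store * u3 - V) / T_vs + k_rf * (g_unit x g_hat)
    dg_hat/dt = -(DEG * Omega) x g_hat + k_somato * (g_unit - g_hat)
    Omega   = g_direct * u3 + V;   SPV = -Omega

The rotational-feedback cross product is oriented so that a gravity-estimate
mismatch *opposes* the stored velocity (suppression), which is the stabilizing
orientation for a supine subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, fsolve

from .errors import CalibrationError, IntegrationError, InvalidParameterError
from .field import FieldMap
from .stimulus import (
    DEFAULT_AXIS,
    SUPINE_GRAVITY,
    StimulusTrace,
    assemble_paradigm,
    ramp_stimulus,
    stimulus_from_profile,
)

_DEG = math.pi / 180.0

#: Lumped Lorentz stimulus gain, (deg/s^2)/T.  Calibrated once with
#: :func:`calibrate_kappa` so that the standard 20-s, 7-T paradigm with a
#: 5-min dwell produces a -15.5 deg/s per-entry peak (the observed cohort
#: mean for that condition).
DEFAULT_KAPPA = 0.27017


@dataclass(frozen=True)
class ModelParams:
    """Time constants, gains and geometry of the VOR model.

    All time constants are in seconds; ``kappa`` is in (deg/s^2)/T.
    ``adapt_weights`` are the fractions of the signal each serial adaptation
    operator removes at steady state (partial set-point adaptation).
    """

    t_canal: float = 6.0
    t_vs: float = 16.0
    t_adapt: tuple = (80.0, 300.0, 3000.0)
    adapt_weights: tuple = (0.6, 0.2, 0.3)
    g_direct: float = 0.9
    g_store: float = 1.0
    k_somato: float = 0.1
    k_rf: float = 0.1
    gravity: tuple = (-1.0, 0.0, 0.0)
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        if min(self.t_canal, self.t_vs) <= 0 or min(self.t_adapt) <= 0:
            raise InvalidParameterError("all time constants must be positive")
        if not (self.t_adapt[0] < self.t_adapt[1] < self.t_adapt[2]):
            raise InvalidParameterError("t_adapt must be strictly increasing")
        if min(self.g_direct, self.g_store, self.k_somato, self.k_rf) < 0:
            raise InvalidParameterError("gains must be >= 0")
        if any(not (0.0 <= w <= 1.0) for w in self.adapt_weights):
            raise InvalidParameterError("adapt_weights must lie in [0, 1]")
        if np.linalg.norm(self.gravity) == 0:
            raise InvalidParameterError("gravity vector must be nonzero")

    @property
    def g_unit(self) -> np.ndarray:
        g = np.asarray(self.gravity, dtype=float)
        return g / np.linalg.norm(g)


@dataclass
class ModelState:
    """Dynamical state: all 3-vectors in head coordinates, deg/s (g_hat unitless)."""

    c: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    a3: np.ndarray
    V: np.ndarray
    g_hat: np.ndarray

    @classmethod
    def zero(cls, params: ModelParams) -> "ModelState":
        z = np.zeros(3)
        return cls(c=z.copy(), a1=z.copy(), a2=z.copy(), a3=z.copy(),
                   V=z.copy(), g_hat=params.g_unit.copy())

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.c, self.a1, self.a2, self.a3, self.V, self.g_hat])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "ModelState":
        return cls(c=y[0:3].copy(), a1=y[3:6].copy(), a2=y[6:9].copy(),
                   a3=y[9:12].copy(), V=y[12:15].copy(), g_hat=y[15:18].copy())


@dataclass
class SimResult:
    """Simulated slow-phase velocity on the stimulus grid.

    ``spv`` has shape (n, 3) with columns (horizontal, vertical, torsional),
    i.e. the eye-movement components driven by rotation about the yaw, pitch
    and roll axes respectively.
    """

    time: np.ndarray
    spv: np.ndarray
    events: dict
    dt: float
    final_state: ModelState

    @property
    def horizontal(self) -> np.ndarray:
        return self.spv[:, 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "spv_h": self.spv[:, 0],
             "spv_v": self.spv[:, 1], "spv_t": self.spv[:, 2]}
        )


def default_params() -> ModelParams:
    """Model parameters with the standard time constants and documented gains."""
    return ModelParams()


def _rhs_factory(p: ModelParams):
    """Return an unrolled scalar RHS closure (fast enough for fixed-step RK4)."""
    Tc = p.t_canal
    Tvs = p.t_vs
    Ta1, Ta2, Ta3 = p.t_adapt
    w1, w2, w3 = p.adapt_weights
    gd, gs, ksom, krf = p.g_direct, p.g_store, p.k_somato, p.k_rf
    gx, gy, gz = p.g_unit

    def deriv(y, ax, ay, az):
        (cx, cy, cz, a1x, a1y, a1z, a2x, a2y, a2z,
         a3x, a3y, a3z, Vx, Vy, Vz, ghx, ghy, ghz) = y
        u1x = cx - a1x; u1y = cy - a1y; u1z = cz - a1z
        u2x = u1x - a2x; u2y = u1y - a2y; u2z = u1z - a2z
        vx = u2x - a3x; vy = u2y - a3y; vz = u2z - a3z
        Ox = gd * vx + Vx; Oy = gd * vy + Vy; Oz = gd * vz + Vz
        # gravity-conflict feedback: g_unit x g_hat opposes stored velocity
        crx = gy * ghz - gz * ghy
        cry = gz * ghx - gx * ghz
        crz = gx * ghy - gy * ghx
        Orx = Ox * _DEG; Ory = Oy * _DEG; Orz = Oz * _DEG
        return (
            ax - cx / Tc, ay - cy / Tc, az - cz / Tc,
            (w1 * cx - a1x) / Ta1, (w1 * cy - a1y) / Ta1, (w1 * cz - a1z) / Ta1,
            (w2 * u1x - a2x) / Ta2, (w2 * u1y - a2y) / Ta2, (w2 * u1z - a2z) / Ta2,
            (w3 * u2x - a3x) / Ta3, (w3 * u2y - a3y) / Ta3, (w3 * u2z - a3z) / Ta3,
            (gs * vx - Vx) / Tvs + krf * crx,
            (gs * vy - Vy) / Tvs + krf * cry,
            (gs * vz - Vz) / Tvs + krf * crz,
            -(Ory * ghz - Orz * ghy) + ksom * (gx - ghx),
            -(Orz * ghx - Orx * ghz) + ksom * (gy - ghy),
            -(Orx * ghy - Ory * ghx) + ksom * (gz - ghz),
        )

    return deriv


def _integrate(params: ModelParams, alpha: np.ndarray, dt: float, y0: np.ndarray):
    """Fixed-step RK4 over the stimulus grid.  Returns (omega, y_final).

    ``omega`` is the estimated head velocity (n, 3) in rotation-axis
    coordinates; SPV is its negative.
    """
    deriv = _rhs_factory(params)
    gd = params.g_direct
    n = alpha.shape[0]
    ax = alpha[:, 0]; ay = alpha[:, 1]; az = alpha[:, 2]
    omega = np.zeros((n, 3))
    y = tuple(float(v) for v in y0)
    vx0 = y[0] - y[3] - y[6] - y[9]
    vy0 = y[1] - y[4] - y[7] - y[10]
    vz0 = y[2] - y[5] - y[8] - y[11]
    omega[0] = (gd * vx0 + y[12], gd * vy0 + y[13], gd * vz0 + y[14])
    h = dt; h2 = 0.5 * dt; h6 = dt / 6.0
    rng18 = range(18)
    for i in range(n - 1):
        a0x = ax[i]; a0y = ay[i]; a0z = az[i]
        a1x_ = ax[i + 1]; a1y_ = ay[i + 1]; a1z_ = az[i + 1]
        amx = 0.5 * (a0x + a1x_); amy = 0.5 * (a0y + a1y_); amz = 0.5 * (a0z + a1z_)
        k1 = deriv(y, a0x, a0y, a0z)
        y2 = tuple(y[j] + h2 * k1[j] for j in rng18)
        k2 = deriv(y2, amx, amy, amz)
        y3 = tuple(y[j] + h2 * k2[j] for j in rng18)
        k3 = deriv(y3, amx, amy, amz)
        y4 = tuple(y[j] + h * k3[j] for j in rng18)
        k4 = deriv(y4, a1x_, a1y_, a1z_)
        y = tuple(y[j] + h6 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j]) for j in rng18)
        vx = y[0] - y[3] - y[6] - y[9]
        vy = y[1] - y[4] - y[7] - y[10]
        vz = y[2] - y[5] - y[8] - y[11]
        omega[i + 1, 0] = gd * vx + y[12]
        omega[i + 1, 1] = gd * vy + y[13]
        omega[i + 1, 2] = gd * vz + y[14]
    return omega, np.array(y)


def simulate(
    params: ModelParams,
    stim: StimulusTrace,
    initial: Optional[ModelState] = None,
    dt: Optional[float] = None,
) -> SimResult:
    """Integrate the model over a stimulus trace.

    Deterministic given inputs.  Raises :class:`IntegrationError` naming the
    first bad time if the state diverges.
    """
    steps = np.diff(stim.time)
    if steps.size == 0:
        raise InvalidParameterError("stimulus must contain at least two samples")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise InvalidParameterError("stimulus must be on a uniform time grid")
    step = float(steps[0])
    if dt is not None and not np.isclose(dt, step, rtol=1e-6):
        raise InvalidParameterError(f"dt={dt} does not match the stimulus grid ({step})")
    y0 = (initial or ModelState.zero(params)).as_vector()
    omega, y_final = _integrate(params, np.asarray(stim.alpha, dtype=float), step, y0)
    if not np.all(np.isfinite(omega)):
        bad = int(np.argmax(~np.all(np.isfinite(omega), axis=1)))
        raise IntegrationError(
            f"integration diverged: non-finite state at t={stim.time[bad]:.3f} s"
        )
    # rotation axes (x=roll, y=pitch, z=yaw) -> eye components (h, v, t)
    spv = -omega[:, [2, 1, 0]]
    return SimResult(
        time=stim.time.copy(),
        spv=spv,
        events=dict(stim.events),
        dt=step,
        final_state=ModelState.from_vector(y_final),
    )


def settle_state(params: ModelParams, b_field: float, axis_unit=None) -> ModelState:
    """Equilibrium state under a constant field (e.g. the fringe at table home).

    Solves ``rhs(y) = 0`` so that a paradigm can start from a subject already
    adapted to the baseline fringe field rather than from a cold start.
    """
    axis = DEFAULT_AXIS if axis_unit is None else np.asarray(axis_unit, float)
    alpha = params.kappa * b_field * axis
    deriv = _rhs_factory(params)

    def f(y):
        return np.array(deriv(tuple(y), alpha[0], alpha[1], alpha[2]))

    y0 = ModelState.zero(params).as_vector()
    sol, info, ier, _ = fsolve(f, y0, full_output=True)
    if ier != 1 or not np.all(np.isfinite(sol)):
        raise IntegrationError("could not find a baseline equilibrium state")
    return ModelState.from_vector(sol)


def run_paradigm(
    params: ModelParams,
    fieldmap: Optional[FieldMap] = None,
    entry_s: float = 20.0,
    dwell_s: float = 300.0,
    exit_s: float = 20.0,
    b0: float = 7.0,
    pre_s: float = 120.0,
    post_s: float = 240.0,
    dt: float = 0.05,
    mode: str = "constant_rate",
    axis_unit=None,
) -> SimResult:
    """Simulate one complete entry/dwell/exit paradigm.

    With ``fieldmap=None`` (the model-study default) the field at the head
    ramps linearly from zero, the pre segment is field free and the state
    starts at rest.  With a field map, the motion profile is built through
    the map (``mode`` selects constant-Tesla-rate or constant-velocity
    motion), the pre/post segments sit in the table-home fringe field, and
    the state starts at the fringe-field equilibrium, as in the experiment.
    ``entry_s`` or ``exit_s`` equal to 0 model an instantaneous ("null
    position") onset or offset.
    """
    if b0 <= 0:
        raise InvalidParameterError("b0 must be positive")
    if entry_s < 0 or exit_s < 0:
        raise InvalidParameterError("entry_s and exit_s must be >= 0")
    if fieldmap is None:
        stim = ramp_stimulus(
            b0, entry_s, dwell_s, exit_s, pre_s, post_s,
            kappa=params.kappa, axis_unit=axis_unit, dt=dt, pre_field=0.0,
        )
        initial = ModelState.zero(params)
    else:
        if not np.isclose(fieldmap.b0, b0):
            raise InvalidParameterError(
                f"b0={b0} does not match the field map (B0={fieldmap.b0})"
            )
        if entry_s == 0 or exit_s == 0:
            # instantaneous transition: fall back to a stepped field at the head
            from .field import HOME_POSITION_CM

            b_home = float(fieldmap.field_at(HOME_POSITION_CM))
            stim = ramp_stimulus(
                b0, entry_s, dwell_s, exit_s, pre_s, post_s,
                kappa=params.kappa, axis_unit=axis_unit, dt=dt, pre_field=b_home,
            )
        else:
            profile = assemble_paradigm(
                fieldmap, entry_s, dwell_s, exit_s, pre_s, post_s, mode=mode, dt=dt
            )
            stim = stimulus_from_profile(profile, fieldmap, params.kappa, axis_unit)
        initial = settle_state(params, float(stim.b_head[0]), axis_unit)
    return simulate(params, stim, initial=initial)


def _entry_peak(result: SimResult, search_window: float = 60.0) -> float:
    """Signed per-entry extremum of horizontal SPV (stimulated direction)."""
    ev = result.events
    i0 = int(round(ev["entry_start"] / result.dt))
    i1 = min(int(round((ev["entry_end"] + search_window) / result.dt)),
             result.time.size - 1)
    seg = result.horizontal[i0:i1 + 1]
    return float(seg[np.argmax(np.abs(seg))])


def calibrate_kappa(
    params: ModelParams,
    target_peak: float,
    entry_s: float = 20.0,
    dwell_s: float = 300.0,
    exit_s: float = 20.0,
    b0: float = 7.0,
    tol: float = 0.05,
    kappa_bracket: tuple = (1e-3, 10.0),
    dt: float = 0.05,
) -> float:
    """Find the lumped Lorentz gain that reproduces a target per-entry peak.

    Peak magnitude is monotone in ``kappa`` for this model, so a bracketing
    root search suffices.  Raises :class:`CalibrationError` when the target
    is zero or cannot be bracketed.
    """
    if target_peak == 0:
        raise CalibrationError("target peak of 0 deg/s cannot be bracketed")
    target_mag = abs(target_peak)

    def peak_mag(kappa: float) -> float:
        p = replace(params, kappa=kappa)
        res = run_paradigm(p, entry_s=entry_s, dwell_s=dwell_s, exit_s=exit_s,
                           b0=b0, dt=dt)
        return abs(_entry_peak(res))

    lo, hi = kappa_bracket
    f_lo = peak_mag(lo) - target_mag
    f_hi = peak_mag(hi) - target_mag
    if f_lo > 0 or f_hi < 0:
        raise CalibrationError(
            f"target peak {target_peak} deg/s is not bracketed by kappa in {kappa_bracket}"
        )
    kappa = brentq(lambda k: peak_mag(k) - target_mag, lo, hi, xtol=1e-5, rtol=1e-6)
    if abs(peak_mag(kappa) - target_mag) > tol:
        raise CalibrationError("calibration did not converge to within tolerance")
    return float(kappa)


def duration_response_table(
    params: ModelParams,
    durations: Sequence[float],
    b0: float = 7.0,
    dwell_s: float = 300.0,
    vary: str = "both",
    fixed_entry_s: float = 20.0,
    fixed_exit_s: float = 20.0,
    dt: float = 0.05,
    fieldmap: Optional[FieldMap] = None,
) -> pd.DataFrame:
    """Per-peak / post-peak / per-steady summary across entry-exit durations.

    ``vary`` selects which motion duration the sweep changes: ``"entry"``
    (exit fixed at ``fixed_exit_s``), ``"exit"`` (entry fixed), or ``"both"``
    (entry and exit equal, the paradigm actually run in the scanner).
    """
    from .spv import SPVTrace, period_summaries

    if len(durations) == 0:
        raise InvalidParameterError("durations must be non-empty")
    if vary not in ("entry", "exit", "both"):
        raise InvalidParameterError(f"unknown vary mode {vary!r}")
    rows = []
    for d in durations:
        entry = d if vary in ("entry", "both") else fixed_entry_s
        exit_ = d if vary in ("exit", "both") else fixed_exit_s
        res = run_paradigm(params, fieldmap=fieldmap, entry_s=entry, dwell_s=dwell_s,
                           exit_s=exit_, b0=b0, dt=dt)
        trace = SPVTrace(time=res.time, spv=res.horizontal,
                         mask=np.ones(res.time.size, bool), fs=1.0 / res.dt)
        summ = period_summaries(trace, res.events)
        rows.append({
            "duration_s": d,
            "per_peak": summ.per_peak,
            "post_peak": summ.post_peak,
            "per_steady": summ.per_steady_mean,
            "baseline": summ.baseline_mean,
        })
    return pd.DataFrame(rows)
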