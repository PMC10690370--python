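"""VOR model dynamics: fixed points, linear limits, calibration, sweeps."""

import dataclasses

import numpy as np
import pytest
from scipy.linalg import expm

from mvslab import (
    ModelParams,
    calibrate_kappa,
    default_params,
    duration_response_table,
    ramp_stimulus,
    run_paradigm,
    simulate,
)
from mvslab.errors import CalibrationError, IntegrationError, InvalidParameterError
from mvslab.model import _entry_peak


class TestDefaults:
    def test_stated_time_constants(self, params):
        assert params.t_vs == 16.0
        assert params.t_adapt == (80.0, 300.0, 3000.0)
        assert params.t_canal == 6.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            ModelParams(t_vs=-1.0)
        with pytest.raises(InvalidParameterError):
            ModelParams(t_adapt=(300.0, 80.0, 3000.0))
        with pytest.raises(InvalidParameterError):
            ModelParams(adapt_weights=(1.5, 0.2, 0.3))


class TestSimulate:
    def test_zero_input_zero_state_fixed_point(self, params):
        stim = ramp_stimulus(7.0, 20.0, 60.0, 20.0, kappa=0.0, pre_s=30.0, post_s=30.0)
        res = simulate(params, stim)
        assert np.allclose(res.spv, 0.0)

    def test_determinism_bit_identical(self, params):
        stim = ramp_stimulus(7.0, 20.0, 120.0, 20.0, kappa=params.kappa)
        a = simulate(params, stim)
        b = simulate(params, stim)
        assert np.array_equal(a.spv, b.spv)

    def test_step_response_morphology(self, params):
        """Constant-field exposure: rise to a peak, monotone decay, reversal."""
        res = run_paradigm(params, entry_s=20.0, dwell_s=300.0, exit_s=20.0)
        dt = res.dt
        h = res.horizontal
        i_entry = int(120.0 / dt)
        i_peak = i_entry + int(np.argmin(h[i_entry:int(200.0 / dt)]))
        # peak within 60 s of entry onset
        assert (i_peak - i_entry) * dt < 60.0
        # decay after the peak is monotone (sampled every 10 s to skip ripple)
        dwell_end = int((120.0 + 20.0 + 300.0) / dt)
        decay = h[i_peak:dwell_end:int(10.0 / dt)]
        assert np.all(np.diff(decay) > 0)  # negative SPV shrinking toward 0
        assert abs(h[dwell_end]) < abs(h[i_peak])
        # aftereffect reverses sign after exit
        assert h[dwell_end:].max() > 0.5

    def test_nonfinite_stimulus_raises_with_time(self, params):
        stim = ramp_stimulus(7.0, 20.0, 60.0, 20.0, kappa=params.kappa,
                             pre_s=30.0, post_s=30.0)
        stim.alpha[1000, 2] = np.inf
        with pytest.raises(IntegrationError, match="t="):
            simulate(params, stim)


class TestLinearLimits:
    def test_matrix_exponential_oracle(self):
        """With adaptation and feedback off, the canal+storage system is a
        two-state linear ODE; RK4 must match its matrix-exponential solution."""
        p = ModelParams(adapt_weights=(0.0, 0.0, 0.0), k_somato=0.0, k_rf=0.0,
                        kappa=0.3)
        stim = ramp_stimulus(7.0, 0.0, 200.0, 0.0, pre_s=0.0, post_s=0.0,
                             kappa=p.kappa)
        res = simulate(p, stim)
        # exact solution for dx/dt = A x + u, x(0)=0, constant u
        alpha = p.kappa * 7.0
        A = np.array([[-1.0 / p.t_canal, 0.0],
                      [p.g_store / p.t_vs, -1.0 / p.t_vs]])
        u = np.array([alpha, 0.0])
        M = np.zeros((3, 3))
        M[:2, :2] = A
        M[:2, 2] = u
        expected = np.empty(res.time.size)
        for i, t in enumerate(res.time):
            x = expm(M * t) @ np.array([0.0, 0.0, 1.0])
            expected[i] = -(p.g_direct * x[0] + x[1])
        # final sample reverts to zero field by the trace's edge convention
        assert np.max(np.abs(res.horizontal[:-1] - expected[:-1])) < 1e-6

    def test_exact_scaling_without_feedback(self):
        p = ModelParams(k_somato=0.0, k_rf=0.0, kappa=0.3)
        s1 = ramp_stimulus(7.0, 20.0, 120.0, 20.0, kappa=p.kappa)
        s2 = ramp_stimulus(7.0, 20.0, 120.0, 20.0, kappa=3.0 * p.kappa)
        r1 = simulate(p, s1)
        r2 = simulate(dataclasses.replace(p, kappa=3.0 * p.kappa), s2)
        assert np.allclose(r2.spv, 3.0 * r1.spv, rtol=1e-9, atol=1e-9)

    def test_near_proportional_scaling_with_feedback(self, params):
        peaks = {}
        for b in (1.5, 3.0, 7.0, 9.4, 11.7):
            res = run_paradigm(params, entry_s=20.0, dwell_s=300.0, exit_s=20.0, b0=b)
            peaks[b] = _entry_peak(res)
        base = peaks[7.0] / 7.0
        for b, pk in peaks.items():
            assert pk / b == pytest.approx(base, rel=0.15)


class TestCalibration:
    def test_round_trip(self, params):
        kappa = calibrate_kappa(params, target_peak=-15.5)
        p = dataclasses.replace(params, kappa=kappa)
        res = run_paradigm(p, entry_s=20.0, dwell_s=300.0, exit_s=20.0)
        assert _entry_peak(res) == pytest.approx(-15.5, abs=0.05)

    def test_zero_target_rejected(self, params):
        with pytest.raises(CalibrationError):
            calibrate_kappa(params, target_peak=0.0)

    def test_unbracketable_target_rejected(self, params):
        with pytest.raises(CalibrationError):
            calibrate_kappa(params, target_peak=-1e5)

    def test_quasi_linear_in_target(self, params):
        k1 = calibrate_kappa(params, target_peak=-8.0)
        k2 = calibrate_kappa(params, target_peak=-16.0)
        assert k2 / k1 == pytest.approx(2.0, rel=0.10)


class TestDurationTable:
    def test_per_peak_strictly_decreasing(self, both_sweep):
        mags = both_sweep["per_peak"].abs().to_numpy()
        assert np.all(np.diff(mags) < 0)

    def test_per_peak_exceeds_post_peak(self, both_sweep):
        assert np.all(both_sweep["per_peak"].abs() > both_sweep["post_peak"].abs())

    def test_aftereffect_sign_reversal(self, both_sweep):
        assert np.all(both_sweep["per_peak"] < 0)
        assert np.all(both_sweep["post_peak"] > 0)

    def test_adaptation_during_dwell(self, both_sweep):
        assert np.all(both_sweep["per_steady"].abs() < both_sweep["per_peak"].abs())

    def test_long_dwell_continues_adaptation(self, params, both_sweep):
        tbl30 = duration_response_table(params, [20.0], dwell_s=1800.0)
        ps5 = both_sweep.loc[both_sweep["duration_s"] == 20, "per_steady"].iloc[0]
        assert abs(tbl30["per_steady"].iloc[0]) < abs(ps5)

    def test_empty_durations_rejected(self, params):
        with pytest.raises(InvalidParameterError):
            duration_response_table(params, [])


class TestMapPath:
    def test_fringe_baseline_biases_direction(self, params, fmap):
        """Starting in the ~0.5-T fringe equilibrium yields a small negative
        baseline SPV, as the fringe field biases nystagmus direction."""
        res = run_paradigm(params, fieldmap=fmap, entry_s=20.0, dwell_s=120.0,
                           exit_s=20.0)
        baseline = res.horizontal[: int(100.0 / res.dt)]
        assert -1.5 < baseline.mean() < -0.05
        assert np.std(baseline[int(30 / res.dt):]) < 0.05  # settled, not transient
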