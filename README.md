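# mvslab

Strong static magnetic fields stimulate the inner ear. The ionic current that
flows through the utricular endolymph experiences a Lorentz force
(**F** = L **j** × **B**) inside an MRI magnet, pushing on the semicircular-canal
cupulae exactly as a sustained angular acceleration would. A person lying in a
7-T scanner therefore develops nystagmus — alternating slow compensatory eye
drifts and quick resets — and often vertigo, especially while the table moves
through the steep fringe-field gradient. Because the vestibular system adapts
to sustained stimulation on time scales of tens of seconds to minutes, *slower*
entry into the bore gives adaptation time to absorb the stimulus: peak
slow-phase eye velocity (SPV) and vertigo both shrink as entry duration grows.

`mvslab` is a Python library for studying this magnetic vestibular stimulation
(MVS) paradigm end to end:

* **Model** (`mvslab.model`) — a 3D control-systems model of the
  vestibulo-ocular reflex: first-order canal dynamics, three serial set-point
  adaptation operators (time constants 80 / 300 / 3000 s, each removing a
  fraction of its input), a 16-s velocity-storage integrator, and gravity
  cross-product loops (tilt estimation, rotational feedback). Integrated with
  fixed-step RK4; output is the SPV time series.
* **Field & stimulus** (`mvslab.field`, `mvslab.stimulus`) — an axial
  fringe-field map `B(z) = B0 / (1 + (z/z_half)^n)`, constant-velocity and
  constant-Tesla-rate table-motion profiles, and their conversion into the
  equivalent angular-acceleration input `alpha(t) = kappa * B_head(t)`.
* **SPV extraction** (`mvslab.spv`) — quick-phase detection and excision,
  smoothing, magnetometer-based entry/exit event detection, and the four
  period statistics per trial: baseline and per-steady 30-s means, per-peak
  (signed extremum after entry) and post-peak (reversed extremum after exit).
* **Synthetic cohorts** (`mvslab.synth`) — recordings with the experiment's
  structure (8 subjects × entry/exit durations {20, 120, 300} s, 2-min
  baseline, 5-min dwell, 4-min post, randomized order), built from the model
  with per-subject gains, fringe-field baseline bias, resetting quick phases,
  sensor noise, and ordinal vertigo ratings — with hidden ground truth for
  recovery testing.
* **Statistics** (`mvslab.stats`) — `SPV ~ condition + subject` OLS with
  estimated marginal means and Tukey-adjusted pairwise contrasts, a
  random-intercept cumulative-link (proportional-odds) model for vertigo
  intensity, and the duration–response regression.
* **Pipeline & CLI** (`mvslab.pipeline`, `mvs`) — orchestrated runs
  (`simulate`, `synthesize`, `reanalyze`) with validated YAML configs and
  deterministic, reproducible reports. The reanalysis path reads recordings
  from disk (a column-mapping config adapts foreign layouts), and produces
  byte-identical reports to the synthetic path on the same files.

## Worked example

Sweep the entry duration at 7 T with a 5-min dwell and a fixed 20-s exit:

```python
from mvslab import default_params, duration_response_table, duration_regression

params = default_params()
table = duration_response_table(params, [0, 20, 60, 120, 180, 300],
                                vary="entry", fixed_exit_s=20.0)
print(table.round(2))
reg = duration_regression(table["duration_s"], table["per_peak"])
print(f"adjusted R^2 = {reg.adj_r2:.3f}")
```

prints

```
 duration_s  per_peak  post_peak  per_steady  baseline
          0    -15.64       8.46       -6.63       0.0
         20    -15.50       8.50       -6.55       0.0
         60    -14.65       8.56       -6.43       0.0
        120    -13.04       8.64       -6.29       0.0
        180    -11.65       8.70       -6.19       0.0
        300     -9.81       8.79       -6.05       0.0
adjusted R^2 = 0.985
```

Per-peak SPV is negative (right-beating nystagmus) and its magnitude falls
near-linearly with entry duration — the signature of set-point adaptation
absorbing a slow stimulus ramp — while the post-exit aftereffect (positive,
left-beating) is untouched by entry duration: it depends only on how fast the
field is removed. The `examples/` directory has one short script per
capability (field map and table motion, duration sweep, field scaling,
synthetic cohort analysis, vertigo ratings).

A full synthetic study from the shell:

```bash
mvs synthesize --seed 1 --subjects 8 --out runs/study
mvs reanalyze --data runs/study/traces --out runs/reanalysis
```

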