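"""Entry/exit-duration sweep of the VOR model.

Simulates the six entry/exit durations at 7 T with a 5-min dwell and prints
the per-peak, per-steady and post-peak slow-phase velocity (deg/s), plus the
linear regression of peak amplitude on duration.  Longer entries blunt the
per-entry nystagmus peak near-linearly; the post-exit aftereffect depends on
the exit duration alone.
"""

from mvslab import default_params, duration_response_table, duration_regression

params = default_params()
durations = [0, 20, 60, 120, 180, 300]

entry = duration_response_table(params, durations, vary="entry", fixed_exit_s=20.0)
exit_ = duration_response_table(params, durations, vary="exit", fixed_entry_s=20.0)

print("entry sweep (exit fixed at 20 s):")
print(entry.round(2).to_string(index=False))

reg = duration_regression(entry["duration_s"], entry["per_peak"])
print(f"\nper-peak amplitude vs entry duration: adjusted R^2 = {reg.adj_r2:.3f} "
      f"(slope {reg.slope:.4f} deg/s per s)")
reg2 = duration_regression(exit_["duration_s"], exit_["post_peak"])
print(f"post-peak amplitude vs exit duration: R^2 = {reg2.r2:.3f}")
print("\nBoth peaks shrink near-linearly with motion duration: vestibular")
print("set-point adaptation absorbs slow stimulus ramps.")
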