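"""Nystagmus peak versus magnet strength.

The Lorentz-force stimulus scales linearly with the static field, so the
per-entry SPV peak grows near-proportionally from 1.5 T to 11.7 T (small
deviations come from the gravity-feedback loops).
"""

from mvslab import default_params, run_paradigm
from mvslab.model import _entry_peak

params = default_params()
print("20-s entry/exit, 5-min dwell:")
base = None
for b in (1.5, 3.0, 7.0, 9.4, 11.7):
    res = run_paradigm(params, entry_s=20.0, dwell_s=300.0, exit_s=20.0, b0=b)
    pk = _entry_peak(res)
    if b == 7.0:
        base = pk / 7.0
    print(f"  {b:5.1f} T -> per-peak {pk:7.2f} deg/s")
res = run_paradigm(params, entry_s=20.0, dwell_s=300.0, exit_s=20.0, b0=3.0)
print(f"\n3 T / 7 T peak ratio: {_entry_peak(res) / (base * 7.0):.3f} "
      f"(proportional scaling would give {3 / 7:.3f})")
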