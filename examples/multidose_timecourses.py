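"""Classical multi-dose time courses: IV bolus, loading dose, infusion.

Builds the worked one-compartment example (slow-elimination drug,
k_e = 0.0692 1/h, 500 mg every 12 h) and prints the levels a clinician
would look at: the post-dose peak and pre-dose trough as the regimen
approaches its periodic steady state, the effect of an 800 mg loading
dose, and the matched continuous-infusion plateau.
"""

import numpy as np

from transitpk import Regimen, classical, datasets

setting = datasets.catalog_settings("iv_bolus_demo")
params = setting["params"]
regimen = setting["regimen"]

sol = classical.solve(params, regimen)
print("IV equi-bolus, 500 mg every 12 h (k_e = 0.0692 1/h):")
for m in (1, 3, 10):
    peak = sol.interval(m, np.array([0.0]))[0]
    trough = sol.interval(m, np.array([12.0]))[0]
    print(f"  interval {m:2d}: peak {peak:7.1f} mg, trough {trough:6.1f} mg")

ss = sol.steady()
print(f"  steady state: peak {ss.initial_values['central']:.1f} mg, "
      f"trough {ss(np.array([11.999]))['central'][0]:.1f} mg")

loaded = classical.solve(params, setting["loading"])
print(f"with 800 mg loading dose, first-interval trough: "
      f"{loaded.central(np.array([11.999]))[0]:.1f} mg "
      "(already near the steady-state trough)")

plateau = params.F * setting["k_in"] / params.k_e
print(f"matched continuous infusion (D0/T = {setting['k_in']:.2f} mg/h) "
      f"plateaus at {plateau:.1f} mg,")
print("  the dosing-interval average of the bolus regimen at steady state.")
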