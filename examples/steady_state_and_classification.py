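"""Periodic steady state of a repeated-dose transit model, and checking
a regimen against a therapeutic range.

For 500 mg every 8 h through an n = 10 cascade (3 h mean transit time)
the closed-form periodic profile gives the steady trough and peak
without simulating hundreds of doses; the mass eliminated per period
must equal the effective dose.  The regimen is then classified against
a hypothetical 300-1000 mg therapeutic range.
"""

import numpy as np
from scipy.integrate import quad

from transitpk import Regimen, datasets, edrr, tcm

setting = datasets.catalog_settings("transit_multidose_demo")
params, regimen = setting["params"], setting["regimen"]
T, D0 = regimen.T, regimen.D0

prof = tcm.ss_profile(params, T, D0)
t_inf = np.linspace(0.0, T, 2000, endpoint=False)
ac = prof(t_inf)["central"]
print(f"steady state for {D0:.0f} mg every {T:.0f} h, n = {params.n}, "
      f"MTT = {params.mtt:.1f} h:")
print(f"  interval-start level {prof.initial_values['central']:.1f} mg, "
      f"trough {ac.min():.1f} mg, peak {ac.max():.1f} mg")

eliminated, _ = quad(
    lambda x: params.k_e * prof(np.array([x]))["central"][0], 0.0, T, limit=200
)
print(f"  eliminated per period: {eliminated:.2f} mg "
      f"(= effective dose F*D0 = {params.F * D0:.0f} mg)")

window = datasets.catalog_settings("oral_therapeutic_window")["range"]
verdict = edrr.classify_regimen(params, regimen, window)
print(f"against the {window.D_me:.0f}-{window.D_MS:.0f} mg window: "
      f"{verdict.verdict.value} "
      f"(steady band {verdict.steady_min:.0f}-{verdict.steady_max:.0f} mg)")
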