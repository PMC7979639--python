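"""Equi-dosing regimen regions: which (dose, interval) pairs keep the
steady-state drug level inside a therapeutic range.

For the 300-1000 mg window the acceptable (T, D0) region is a petal
bounded by f_lo(T) (trough stays effective) and f_hi(T) (peak stays
safe).  The petal closes at the crossover (T*, D0*); transit-compartment
models, which fluctuate less at steady state, always enlarge the petal
relative to plain oral dosing.
"""

import numpy as np

from transitpk import PKParams, datasets, edrr

iv = datasets.catalog_settings("iv_therapeutic_window")
oral = datasets.catalog_settings("oral_therapeutic_window")
window = iv["range"]

reg_iv = edrr.edrr_iv_bolus(iv["params"], window)
print(f"IV bolus petal: closes at T* = {reg_iv.crossover[0]:.1f} h, "
      f"D0* = {reg_iv.crossover[1]:.0f} mg")

reg_oral = edrr.edrr_oral_bolus(oral["params"], window)
print(f"oral petal:     closes at T* = {reg_oral.crossover[0]:.1f} h, "
      f"D0* = {reg_oral.crossover[1]:.0f} mg")

grid = np.linspace(4.0, 20.0, 9)
oral_petal = edrr.edrr_oral_bolus(oral["params"], window, T_grid=grid)
print("\ntransit cascades widen the acceptable region (T = 12 h column):")
i = int(np.argmin(np.abs(grid - 12.0)))
print(f"  oral (no transit): D0 in ({oral_petal.f_lo[i]:.0f}, {oral_petal.f_hi[i]:.0f}) mg")
for n in (3, 10):
    p = PKParams(model="Mt", k_e=0.0692, k_a=0.7, k=n / 4.4, n=n, F=1.0)
    reg = edrr.edrr_numerical(p, window, T_grid=grid, samples=800)
    print(f"  n = {n:2d}, MTT = 4.4 h:  D0 in ({reg.f_lo[i]:.0f}, {reg.f_hi[i]:.0f}) mg")

infusion = datasets.catalog_settings("infusion_therapeutic_window")
region = edrr.edrr_infusion(infusion["params"], infusion["range"], t_f_values=[1.0, 2.5, 4.0])
print("\nperiodic-infusion slices (rate window at the crossover):")
for tf, s in zip(region.slice_values, region.slices):
    print(f"  t_f = {tf:.1f} h: T in ({s.T.min():.1f}, {s.T.max():.1f}) h, "
          f"crossover k_in* = {s.crossover[1]:.0f} mg/h")
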