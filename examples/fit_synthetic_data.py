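"""Fitting the transit model to synthetic single-dose observations.

Generates a noisy glibenclamide-like dataset (3.5 mg dose, n = 10
cascade), sweeps the cascade length, and compares the best transit fit
with the pure time-lag alternative.  Also demonstrates the n = 1
flip-flop: with a single transit compartment, swapping k and k_a leaves
the central curve unchanged, so those rates cannot be identified.
"""

import numpy as np

from transitpk import datasets, fitting

ds = datasets.make_glibenclamide_like(seed=7, noise_cv=0.02)
print(f"synthetic dataset: {ds.t.size} samples over 0-8 h, "
      f"{100 * ds.noise_cv:.0f}% multiplicative noise")

sweep = fitting.fit_tcm(ds.t, ds.observations, dose=3.5,
                        n_range=range(6, 15), seed=0, n_starts=3)
print("\nn-sweep (sum of squared errors per cascade length):")
for f in sweep.fits:
    marker = "  <-- selected" if f.n == sweep.best_n else ""
    print(f"  n = {f.n:2d}: SSE = {f.sse:.3e}{marker}")
best = sweep.best
print(f"best fit: k = {best.params['k']:.2f}, k_a = {best.params['k_a']:.2f}, "
      f"k_e = {best.params['k_e']:.2f} 1/h, F = {best.params['F']:.2f} "
      f"(truth: 12.76, 9.11, 0.96, 0.69)")

lag = fitting.fit_lag(ds.t, ds.observations, dose=3.5, seed=0, n_starts=6)
print(f"\npure time-lag model: SSE = {lag.best.sse:.3e} "
      f"(t_lag = {lag.best.params['t_lag']:.2f} h)")
print("the smooth transit delay fits the data better than the switch-like lag.")

t = np.linspace(0.0, 10.0, 200)
pair = fitting.flip_flop_pair(2.0, 5.0, k_e=0.3, t=t, D0=10.0, n=1)
gap1 = np.max(np.abs(pair["central_12"] - pair["central_21"]))
pair2 = fitting.flip_flop_pair(2.0, 5.0, k_e=0.3, t=t, D0=10.0, n=2)
gap2 = np.max(np.abs(pair2["central_12"] - pair2["central_21"]))
print(f"\nflip-flop: swapping k and k_a changes the n = 1 curve by {gap1:.2e} mg")
print(f"(indistinguishable) but the n = 2 curve by {gap2:.2e} mg (identifiable).")
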