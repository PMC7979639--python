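# Methods

## Models and conventions

All solvers work on drug **amounts** (mg); a fixed central volume turns
amounts into concentrations and is deliberately left to the caller.
Times are hours, rates 1/h.  Bioavailability `F ∈ (0, 1]` multiplies
each administered dose on entry to the first modelled compartment, so
every solution is linear in the dose with effective input `F·D0`.

Three nested linear topologies are supported: one-compartment IV
(`M1`), two-compartment oral (`M2`, absorption rate `k_a`), and the
transit-compartment model (`Mt`): `n` identical transit stages at rate
`k` feeding the absorption compartment.  The cascade delays the
absorption input by the mean transit time `MTT = n/k` with variance
`MTT²/n`: large `n` at fixed MTT approaches a pure time lag, small `n`
a heavily smoothed delay.

Dosing regimens: single bolus (`B1`), equi-bolus (`Beq`: `D0` every
`T` h, `M` doses or `M = "infinite"`), equi-bolus with loading dose
(`BeqL`, first dose `D_L ≥ D0`), constant infusion, and periodic
infusion (`Ieq`: rate `k_in`, on for `t_f`, off for `T − t_f`).

Conventions that matter:

* Heaviside `H(0) = 1`: a sample taken exactly at a dose time is the
  post-dose level, so the single-dose IV solution is `F·D0` at `t = 0`.
  Time grids may repeat an abscissa just before/at a dose time to
  record both one-sided values.
* `M = "infinite"` routes to the periodic steady-state evaluators and
  is rejected by finite-sum transient solvers.
* All rate pairs entering a denominator (`k_a−k_e`, `k−k_a`, `k−k_e`)
  must be distinct: coincidences within a relative tolerance
  (default 1e-6) raise rather than silently substituting a limit form,
  because every closed form used here genuinely divides by these
  differences.  The tolerance is configurable in `validate_params`.
* `k_a < k_e` (absorption slower than elimination) is accepted with a
  warning: the formulas are sign-symmetric, but the regime is unusual
  and on single-compartment-cascade data it is indistinguishable from
  the swapped parameterisation (see identifiability below).

## Transient solutions

M1/M2 solutions use the algebraically collapsed per-interval forms
(geometric dose sums) as the default evaluator — O(1) per sample and
stable for arbitrarily many doses — with the explicit superposition
sums retained (`levels_sum`) and cross-checked in tests.  `expm1` is
used for every `1 − e^{-x}`.

The transit-model per-dose kernels are built from the scaled gamma
combination

    P(m, c, t) = γ(m, c·t) / (c^m (m−1)!) = ∫₀ᵗ u^{m−1} e^{−cu} du / (m−1)!,

which is strictly positive for `t > 0` whatever the sign of
`c = k − k_a` or `k − k_e`.  Its logarithm is evaluated directly:

* `c > 0`: `log(gammainc(m, ct)) − m·log c` (regularised incomplete
  gamma); when `gammainc` underflows (`ct ≪ m`) a positive series for
  `log γ(m, x)` takes over.
* `c < 0`: the everywhere-positive series
  `Σ_q (bt)^q/(q!(m+q))`-form in log space (`b = −c`), switching to an
  exact integration-by-parts form once `bt > 2m + 40` (there the
  alternating coefficients decay, so no cancellation).

Kernels then combine as `exp(m·log k + log P − k_x t)`, so the
individually astronomical factors `k^m`, `1/(m−1)!`, `γ(m, ·)` never
meet in double precision; cascades of hundreds of compartments and
either rate ordering evaluate safely.  A public
`lower_incomplete_gamma(n, t)` (any real `t`, exact closed form for
integer shape) and the exponentiated-log-gamma CDF route are provided
and cross-tested; their magnitudes are limited by `(n−1)!`, which is
why the solvers use the scaled form instead.

Near-coincident rates just above the rejection tolerance lose accuracy
through cancellation of the two kernel terms (roughly one digit per
decade below `|k_a−k_e|/k_a ≈ 1e-2`); tighten the tolerance rather than
trusting results in that band.

## Periodic steady state

Steady-state interval-initial values for the transit cascade are
computed by the recurrence in `φ = kT`, `β = e^{−φ}/(1−e^{−φ})`,
implemented in log space (the values span many orders of magnitude for
large `φ`).  The equivalent closed form with Stirling numbers of the
second kind is retained as `method="stirling"` for cross-validation
only: it mixes combinatorially large exact integers with powers of
`β` and is float-fragile for `n ≳ 20`.  Stirling numbers themselves are
computed exactly in integer arithmetic.  As `φ → 0` (interval much
shorter than a transit stage) the initial values grow like `1/φ`;
the log-space recurrence remains finite but regimens that extreme are
better treated as continuous infusion.

The steady evaluator returns *all* compartments, which enables the
mass-balance test (eliminated mass `∫ k_e a_c^∞ dt` over one period
equals `F·D0`) and the periodicity test (propagating the interval-end
state through one dose event reproduces the interval-start state).

## Stirling-approximation baseline

The historical single-dose treatment closes the cascade by feeding the
final-transit pulse into the absorption ODE with `(n−1)!` replaced by
Stirling's approximation; the absorption compartment drains at `k_a`
as usual (the efflux term is part of the model even where older
write-ups elide it — without it the predicted central level exceeds
the administered dose).  The baseline is solved numerically (LSODA,
`rtol = atol = 1e-10`, three orders tighter than the approximation
error being measured) since no closed form is claimed for it.  `n = 1`
raises a degenerate-approximation error: Stirling's formula gives 0
for `0!`.

Because the system is linear and the approximation only rescales the
forcing, the approximate solution is exactly
`(n−1)!/Stirling((n−1)!)` times the exact one; the peak relative error
therefore equals the Stirling factorial error (8.44% at `n = 2`,
2.81% at `n = 4`).  The comparison still measures it operationally —
dense grid (`Δt = MTT/2000`) plus parabolic refinement applied
identically to both curves — so the reported numbers do not presuppose
the scaling identity, and the identity itself is a test oracle.

## Regimen regions

A regimen is acceptable when the periodic steady-state central level
stays strictly inside `(D_me, D_MS)`.  For M1/M2 the trough/peak
inversions give analytical boundary curves; the oral petal's closing
point is found by bracketed root-finding from the widest point of the
petal (the gap vanishes at both ends, so a fixed left bracket fails for
extreme `k_a`).  Loading-dose and periodic-infusion regions are stacks
of per-slice chopped petals; the loading region enforces the
"therapeutic immediately and always" criterion (steady constraint plus
first-interval constraint; intermediate intervals are covered because
the per-interval extrema evolve monotonically — asserted in tests, not
assumed).  For the infusion steady state the trough sits at the start
of the on-phase (`t_∞ = 0`) and the peak at switch-off (`t_∞ = t_f`).

For the transit model the boundaries are numerical.  Since every
steady solution is linear in `D0`, the default route computes the
unit-dose steady extrema per `T` (2000-point sampling of one period
plus bounded golden-section refinement within one grid step; the
trough search is global because it may sit at the interval start or in
the interior) and divides the range bounds by them — exact to
evaluator precision.  The literal grid-scan algorithm (discretise
`D0`, pick the closest-extremum grid dose) is retained as
`method="scan"` and agrees within one grid step; it exists for
validation, the linearity route is the production path.  Default `T`
grid: 400 points over twice the IV petal's closing interval,
configurable.

At fixed MTT the petals *shrink* with growing `n` (variance `MTT²/n`:
sharper delay → wider steady band), nesting down onto the no-transit
oral petal, which every transit petal contains.

## Fitting and identifiability

`fit_tcm` sweeps the discrete cascade length `n`, fitting
`(k, k_a, k_e, F)` per `n` by least squares and selecting the minimal
SSE.  Rates are optimised in log space, `F` in logit space (constraints
by construction, no penalties), within a plausibility box of
`e^{±9} ≈ 1e-4..8e3` 1/h.  Each fit is multi-start — default 8 seeded
Nelder-Mead starts (iteration cap 1000, both cap and tolerances
exposed) scattered around a data-driven initial guess (terminal slope
for `k_e`, peak time for MTT) — followed by a Levenberg-Marquardt
polish, accepted only if it improves the SSE.  Multi-start is used
because 4-parameter SSE surfaces for these models are start-sensitive;
the polish turns a near-optimum into a machine-precision one (noise-free
recovery to ~1e-29 SSE).

With `n = 1` the central inflow is symmetric under swapping `k` and
`k_a` (the flip-flop of two-compartment kinetics), so those rates are
structurally unidentifiable from central data; `n = 1` fits warn, the
default sweep starts at `n = 2`, and `flip_flop_pair` demonstrates both
the `n = 1` degeneracy and its disappearance at `n = 2`.  SSE is
computed on amounts; concentration data should be converted with the
caller's volume of distribution beforehand.

## Synthetic data

Real single-dose glibenclamide observations exist only as a digitised
figure, so `datasets.make_glibenclamide_like` generates a synthetic
stand-in: the exact `n = 10` transit curve at the published best-fit
parameters (`k = 12.76`, `k_a = 9.11`, `k_e = 0.96` 1/h, `F = 0.69`,
3.5 mg dose), sampled at 12 points over 0–8 h (dense through the
absorption peak, sparse in the tail — a fixture convention, since the
original sampling times are unknowable), with mean-corrected
multiplicative lognormal noise (default CV 5%; amounts are positive,
and the half-`σ²` correction keeps the expected observation on the
true curve).  Identical seeds reproduce datasets bit-identically.

What passing tests on these data do and do not show: they validate the
estimation machinery (recovery, model selection, the
transit-beats-lag ordering) under the stated noise model; they say
nothing about assay error structure, sampling irregularity, or
between-subject variability in real data, and the published SSE values
for the real fits are not reproducible from synthetic data.

## Problem sizes used in the checks

The acceptance-style checks run at desk scale by choice: 30 random
parameter draws (`n ≤ 25`) against adaptive ODE integration;
steady-state convergence compared at 300 doses; regimen-region grids
of order 10–400 intervals with 600–2000 samples per period; the
n-sweep over `n = 6..14` with 3–4 starts.  All complete in seconds to
a few minutes on one core.

## Known limitations

* No peripheral/distribution compartment, nonlinear (Michaelis-Menten)
  elimination, or time-varying parameters; the linear cascade is the
  scope.
* Equal rates are rejected, not handled by confluent limit forms.
* The EDRR for the transit model applies the steady-state criterion
  only (no first-interval constraint), matching how such regions are
  defined for plain oral dosing.
* Infusion regimens are implemented for the one-compartment model.
* Amount/concentration conversion and unit systems other than
  mg/h/mg·h⁻¹ are out of scope.
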