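"""Exact multi-dose solutions for the n-transit-compartment model.

The model is a linear cascade: bolus doses F*D0 enter transit
compartment 1; drug moves through the n transit compartments (rate k
each), into an absorption compartment (emptied at rate k_a), then into
the central compartment (eliminated at rate k_e).  Per dose, the transit
levels are gamma-density-shaped pulses; the absorption and central
levels involve lower incomplete gamma functions gamma(m, (k - k_x) t)
whose argument may have either sign depending on the ordering of k
versus k_a, k_e.

All gamma terms are evaluated through the strictly positive scaled
combination P(m, c, t) = gamma(m, c t)/(c^m (m-1)!) in log space (see
:mod:`transitpk.special`), so large n and either rate ordering are safe.

The periodic steady state is built from interval-initial values
a_i^inf(0): a recurrence in the dimensionless quantities phi = k T and
beta = e^-phi/(1 - e^-phi) (the default path), or an equivalent closed
form involving Stirling numbers of the second kind (retained for
cross-validation; it mixes combinatorially large integers with powers
of beta and is float-fragile for n over about 20).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import (
    Model,
    PKParams,
    Regimen,
    RegimenKind,
    SteadyStateProfile,
    TimeCourse,
    heaviside,
    validate_params,
)
from .special import log_gamma_scaled, stirling2

__all__ = [
    "TCMState",
    "SSCoefficients",
    "transit_levels",
    "absorption_level",
    "central_level",
    "timecourse",
    "ss_initial_values",
    "ss_profile",
]


@dataclass(frozen=True)
class TCMState:
    """Drug amounts in every compartment at one instant (mg)."""

    transit: tuple[float, ...]
    absorption: float
    central: float

    @property
    def total(self) -> float:
        return sum(self.transit) + self.absorption + self.central


@dataclass(frozen=True)
class SSCoefficients:
    """Steady-state interval-initial values and the dimensionless
    quantities they are built from."""

    phi: float  # k T
    beta: float  # e^-phi / (1 - e^-phi)
    beta_a: float  # e^-ka T / (1 - e^-ka T)
    beta_c: float  # ka / ((ka - ke)(1 - e^-ke T))
    transit0: np.ndarray  # a_i^inf(0), i = 1..n
    absorption0: float  # a_b^inf(0)
    central0: float  # a_c^inf(0)


def _check_tcm(params, regimen=None, kinds=(RegimenKind.B1, RegimenKind.Beq, RegimenKind.BeqL)):
    if regimen is None:
        regimen = Regimen(kind=RegimenKind.B1, D0=1.0)
    params, regimen = validate_params(params, regimen)
    if params.model is not Model.Mt:
        raise ValueError("transit-compartment solvers require the Mt model")
    if regimen.kind not in kinds:
        raise ValueError(f"unsupported regimen kind {regimen.kind} for Mt")
    return params, regimen


def _dose_schedule(regimen: Regimen, t_max: float) -> list[tuple[float, float]]:
    """(time, dose amount) pairs; a loading regimen is the equi-bolus
    train plus an extra (D_L - D0) dose at t=0 by superposition."""
    times = regimen.dose_times(t_max)
    doses = [(float(tj), regimen.D0) for tj in times if tj <= t_max]
    if regimen.kind is RegimenKind.BeqL:
        doses.append((0.0, regimen.D_L - regimen.D0))
    return doses


def _transit_single(params: PKParams, i: int, dose: float, t: np.ndarray) -> np.ndarray:
    """a_i for one bolus: dose * (k t)^{i-1} e^{-k t} k^0 / (i-1)! shape,
    computed in log space to dodge factorial overflow."""
    k, F = params.k, params.F
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    with np.errstate(divide="ignore"):
        log_pulse = (i - 1) * np.log(k * tp) - gammaln(i) - k * tp
    out[pos] = F * dose * np.exp(log_pulse)
    if i == 1:
        out[t == 0.0] = F * dose
    return out


def _ab_single(params: PKParams, dose: float, t: np.ndarray) -> np.ndarray:
    """Absorption level for one bolus: F*dose * k^n * P(n, k-ka, t) * e^{-ka t}."""
    k, ka, n, F = params.k, params.k_a, params.n, params.F
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    logP = log_gamma_scaled(n, k - ka, tp)
    out[pos] = F * dose * np.exp(n * math.log(k) + logP - ka * tp)
    return out


def _ac_single(params: PKParams, dose: float, t: np.ndarray) -> np.ndarray:
    """Central level for one bolus: the two-gamma-term difference."""
    k, ka, ke, n, F = params.k, params.k_a, params.k_e, params.n, params.F
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    term_a = np.exp(n * math.log(k) + log_gamma_scaled(n, k - ka, tp) - ka * tp)
    term_e = np.exp(n * math.log(k) + log_gamma_scaled(n, k - ke, tp) - ke * tp)
    out[pos] = F * dose * ka / (ke - ka) * (term_a - term_e)
    return out


def _superpose(single, params, regimen, t):
    t = np.asarray(t, dtype=float)
    total = np.zeros_like(t)
    for tj, dose in _dose_schedule(regimen, float(t.max(initial=0.0))):
        total += single(params, dose, t - tj)
    return total


def transit_levels(params, regimen, t) -> TimeCourse:
    """Drug levels a_1..a_n in the transit cascade under bolus dosing.

    Each dose contributes a gamma-density pulse to compartment i, peaking
    at (i-1)/k after the dose; a_1 alone is discontinuous at dose times.
    """
    params, regimen = _check_tcm(params, regimen)
    t = np.asarray(t, dtype=float)
    levels = {}
    for i in range(1, params.n + 1):
        levels[f"transit_{i}"] = _superpose(
            lambda p, d, ts, i=i: _transit_single(p, i, d, ts), params, regimen, t
        )
    return TimeCourse(t=t, levels=levels, meta={"params": params, "regimen": regimen})


def absorption_level(params, regimen, t) -> np.ndarray:
    """Absorption-compartment drug level a_b(t) under bolus dosing."""
    params, regimen = _check_tcm(params, regimen)
    return _superpose(_ab_single, params, regimen, np.asarray(t, dtype=float))


def central_level(params, regimen, t) -> np.ndarray:
    """Central-compartment drug level a_c(t) under bolus dosing -- the
    primary model output."""
    params, regimen = _check_tcm(params, regimen)
    return _superpose(_ac_single, params, regimen, np.asarray(t, dtype=float))


def timecourse(params, regimen, t, transit: bool = True) -> TimeCourse:
    """Full solution: transit_1..n (optional), absorption and central."""
    params, regimen = _check_tcm(params, regimen)
    t = np.asarray(t, dtype=float)
    levels = {}
    if transit:
        levels.update(transit_levels(params, regimen, t).levels)
    levels["absorption"] = absorption_level(params, regimen, t)
    levels["central"] = central_level(params, regimen, t)
    return TimeCourse(t=t, levels=levels, meta={"params": params, "regimen": regimen})


# ---------------------------------------------------------------------------
# periodic steady state


def _transit0_recurrence(params: PKParams, T: float, D0: float) -> np.ndarray:
    """Interval-initial transit values by the log-space recurrence."""
    n, k, F = params.n, params.k, params.F
    phi = k * T
    log_phi = math.log(phi)
    # log beta = -phi - log(1 - e^-phi)
    log_beta = -phi - math.log(-math.expm1(-phi))
    log_a = np.empty(n)
    log_a[0] = math.log(F * D0) - math.log(-math.expm1(-phi))
    lgam = gammaln(np.arange(n + 1) + 1.0)  # lgamma(p+1) = log p!
    for i in range(2, n + 1):
        p = np.arange(1, i)
        terms = log_a[i - 1 - p] + p * log_phi - lgam[p]
        log_a[i - 1] = log_beta + logsumexp(terms)
    return np.exp(log_a)


def _transit0_stirling(params: PKParams, T: float, D0: float) -> np.ndarray:
    """Closed-form interval-initial transit values via Stirling numbers
    of the second kind (cross-validation path; float-fragile for large n)."""
    n, k, F = params.n, params.k, params.F
    phi = k * T
    beta = math.exp(-phi) / -math.expm1(-phi)
    lead = F * D0 / -math.expm1(-phi)
    out = np.empty(n)
    for i in range(1, n + 1):
        s = math.fsum(
            math.factorial(p) * stirling2(i - 1, p) * beta**p
            for p in range(0, i)
        )
        out[i - 1] = lead * phi ** (i - 1) / math.factorial(i - 1) * s
    return out


def ss_initial_values(
    params, T: float, D0: float, method: str = "recurrence"
) -> SSCoefficients:
    """Steady-state interval-initial values for every compartment.

    ``method`` selects the transit-coefficient path: ``"recurrence"``
    (default, numerically robust in log space) or ``"stirling"`` (the
    equivalent closed form, kept for cross-checks).
    """
    params, _ = _check_tcm(params, Regimen(kind=RegimenKind.Beq, D0=D0, T=T, M=math.inf))
    n, k, ka, ke, F = params.n, params.k, params.k_a, params.k_e, params.F
    phi = k * T
    beta = math.exp(-phi) / -math.expm1(-phi)
    if method == "recurrence":
        transit0 = _transit0_recurrence(params, T, D0)
    elif method == "stirling":
        transit0 = _transit0_stirling(params, T, D0)
    else:
        raise ValueError("method must be 'recurrence' or 'stirling'")

    log_a = np.log(transit0)
    p = np.arange(1, n + 1)
    m = n - p + 1  # gamma shape per term
    log_k_pow = m * math.log(k)

    # a_b^inf(0) = beta_a * sum_p a_p k^m P(m, k-ka, T)
    beta_a = math.exp(-ka * T) / -math.expm1(-ka * T)
    logP_a_T = np.array(
        [log_gamma_scaled(int(mi), k - ka, T) for mi in m]
    )
    ab0 = beta_a * np.exp(logsumexp(log_a + log_k_pow + logP_a_T))

    # a_c^inf(0) = beta_c * { ab0 (e^-keT - e^-kaT) + sum_p a_p k^m
    #              [e^-keT P(m, k-ke, T) - e^-kaT P(m, k-ka, T)] }
    beta_c = ka / ((ka - ke) * -math.expm1(-ke * T))
    logP_e_T = np.array(
        [log_gamma_scaled(int(mi), k - ke, T) for mi in m]
    )
    term_e = np.exp(log_a + log_k_pow + logP_e_T - ke * T)
    term_a = np.exp(log_a + log_k_pow + logP_a_T - ka * T)
    ac0 = beta_c * (
        ab0 * (math.exp(-ke * T) - math.exp(-ka * T))
        + math.fsum(term_e - term_a)
    )
    return SSCoefficients(
        phi=phi,
        beta=beta,
        beta_a=beta_a,
        beta_c=beta_c,
        transit0=transit0,
        absorption0=float(ab0),
        central0=float(ac0),
    )


def ss_profile(params, T: float, D0: float, coeffs: SSCoefficients | None = None) -> SteadyStateProfile:
    """Periodic steady-state profile over one dosing interval [0, T).

    The evaluator returns all compartments; propagating the values at
    T^- through one dose event (add F*D0 to transit_1) reproduces the
    interval-initial values.
    """
    params, _ = _check_tcm(params, Regimen(kind=RegimenKind.Beq, D0=D0, T=T, M=math.inf))
    n, k, ka, ke = params.n, params.k, params.k_a, params.k_e
    if coeffs is None:
        coeffs = ss_initial_values(params, T, D0)
    a0 = coeffs.transit0
    ab0, ac0 = coeffs.absorption0, coeffs.central0
    log_a = np.log(a0)
    p = np.arange(1, n + 1)
    m = n - p + 1
    log_k_pow = m * math.log(k)

    def ev(t_inf):
        t_inf = np.atleast_1d(np.asarray(t_inf, dtype=float))
        out: dict[str, np.ndarray] = {}
        # transit: a_i(t) = e^{-k t} sum_{q=0}^{i-1} a_{i-q}(0) (k t)^q / q!
        kt = k * t_inf
        decay = np.exp(-kt)
        pows = np.ones_like(t_inf)
        # build the i-indexed partial sums iteratively in q
        series = np.zeros((n, t_inf.size))
        for q in range(n):
            if q > 0:
                pows = pows * kt / q
            # contributes a_{i-q}(0) * pows to every i > q
            series[q:, :] += a0[: n - q, None] * pows[None, :]
        for i in range(1, n + 1):
            out[f"transit_{i}"] = series[i - 1] * decay

        # absorption and central
        logP_a = np.stack(
            [log_gamma_scaled(int(mi), k - ka, t_inf) for mi in m]
        )
        logP_e = np.stack(
            [log_gamma_scaled(int(mi), k - ke, t_inf) for mi in m]
        )
        sum_a = np.exp(log_a[:, None] + log_k_pow[:, None] + logP_a).sum(axis=0)
        out["absorption"] = (ab0 + sum_a) * np.exp(-ka * t_inf)
        term_e = np.exp(
            log_a[:, None] + log_k_pow[:, None] + logP_e - ke * t_inf[None, :]
        ).sum(axis=0)
        term_a = np.exp(
            log_a[:, None] + log_k_pow[:, None] + logP_a - ka * t_inf[None, :]
        ).sum(axis=0)
        out["central"] = (
            ac0 * np.exp(-ke * t_inf)
            + ka
            / (ka - ke)
            * (
                ab0 * (np.exp(-ke * t_inf) - np.exp(-ka * t_inf))
                + term_e
                - term_a
            )
        )
        return out

    initial = {f"transit_{i}": float(a0[i - 1]) for i in range(1, n + 1)}
    initial["absorption"] = ab0
    initial["central"] = ac0
    return SteadyStateProfile(
        T=T,
        initial_values=initial,
        evaluator=ev,
        meta={"params": params, "D0": D0, "coeffs": coeffs},
    )
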