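"""Exact one- and two-compartment solutions under equi-dosing regimens.

Each solver exposes three views of the same solution:

* a transient evaluator over absolute time t (the algebraically
  collapsed per-interval form, O(1) per sample),
* a per-interval evaluator ``interval(M, t_M)`` giving the level at time
  ``t_M`` into the M-th dosing interval,
* a periodic steady-state profile (the M -> infinity limit).

The explicit superposition sums over doses are retained as
``levels_sum`` and cross-checked against the collapsed forms in the
test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

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

__all__ = [
    "ClassicalSolution",
    "solve",
    "m1_beq",
    "m1_beql",
    "m1_ieq",
    "m2_beq",
    "m2_beql",
    "continuous_infusion",
    "lag_time_solution",
    "m2_steady_extrema",
]


def _geom(rate: float, T: float, m) -> np.ndarray:
    """(1 - e^{-m rate T}) / (1 - e^{-rate T}): the collapsed sum of m
    geometrically decaying dose contributions.  m may be inf."""
    m = np.asarray(m, dtype=float)
    with np.errstate(over="ignore"):
        num = np.where(np.isinf(m), -1.0, np.expm1(-m * rate * T))
    return num / math.expm1(-rate * T)


@dataclass
class ClassicalSolution:
    """Bundle of transient / per-interval / steady evaluators for one
    (model, regimen) pair."""

    params: PKParams
    regimen: Regimen
    levels: Callable[[np.ndarray], dict[str, np.ndarray]]
    interval: Callable[[int, np.ndarray], np.ndarray]
    steady: Callable[[], SteadyStateProfile]
    levels_sum: Callable[[np.ndarray], dict[str, np.ndarray]] | None = None

    def timecourse(self, t) -> TimeCourse:
        t = np.asarray(t, dtype=float)
        return TimeCourse(
            t=t,
            levels=self.levels(t),
            meta={"params": self.params, "regimen": self.regimen},
        )

    def central(self, t) -> np.ndarray:
        return self.levels(np.asarray(t, dtype=float))["central"]


def _interval_index(t: np.ndarray, T: float, M) -> np.ndarray:
    """1-based index of the dosing interval containing each t, capped at
    M (after the last dose the M-th interval formula keeps decaying)."""
    m = np.floor(t / T) + 1.0
    m = np.maximum(m, 1.0)
    if not math.isinf(M):
        m = np.minimum(m, float(M))
    return m


def _single_dose(regimen: Regimen) -> bool:
    return regimen.kind is RegimenKind.B1


# ---------------------------------------------------------------------------
# M1 (one compartment, IV)


def _m1_beq_solution(params: PKParams, regimen: Regimen) -> ClassicalSolution:
    ke, F = params.k_e, params.F
    D0 = regimen.D0
    single = _single_dose(regimen)
    T = math.inf if single else regimen.T
    M = 1 if single else regimen.M

    def interval(m, t_m):
        t_m = np.asarray(t_m, dtype=float)
        g = 1.0 if single else _geom(ke, T, m)
        return F * D0 * g * np.exp(-ke * t_m)

    def levels(t):
        t = np.asarray(t, dtype=float)
        if single:
            return {"central": F * D0 * heaviside(t) * np.exp(-ke * t)}
        m = _interval_index(t, T, M)
        t_m = t - (m - 1) * T
        return {"central": interval(m, t_m) * heaviside(t)}

    def levels_sum(t):
        t = np.asarray(t, dtype=float)
        m_eff = 1 if single else (
            int(M) if not math.isinf(M) else int(np.floor(t.max() / T)) + 1
        )
        tj = t[None, :] - np.arange(m_eff)[:, None] * (0.0 if single else T)
        tjc = np.where(tj > 0, tj, 0.0)
        ac = F * D0 * (heaviside(tj) * np.exp(-ke * tjc)).sum(axis=0)
        return {"central": ac}

    def steady():
        if single:
            raise ValueError("single-dose regimen has no periodic steady state")
        a0 = F * D0 / -math.expm1(-ke * T)

        def ev(t_inf):
            return {"central": a0 * np.exp(-ke * np.asarray(t_inf, float))}

        return SteadyStateProfile(T=T, initial_values={"central": a0}, evaluator=ev)

    return ClassicalSolution(params, regimen, levels, interval, steady, levels_sum)


def _m1_beql_solution(params: PKParams, regimen: Regimen) -> ClassicalSolution:
    base = _m1_beq_solution(params, regimen)
    ke, F = params.k_e, params.F
    extra = regimen.D_L - regimen.D0

    def levels(t):
        t = np.asarray(t, dtype=float)
        out = base.levels(t)
        out["central"] = out["central"] + F * extra * heaviside(t) * np.exp(-ke * t)
        return out

    def interval(m, t_m):
        t_m = np.asarray(t_m, dtype=float)
        t = t_m + (np.asarray(m, dtype=float) - 1.0) * regimen.T
        return base.interval(m, t_m) + F * extra * np.exp(-ke * t)

    return ClassicalSolution(params, regimen, levels, interval, base.steady)


def _m1_ieq_solution(params: PKParams, regimen: Regimen) -> ClassicalSolution:
    ke, F = params.k_e, params.F
    kin, tf, T, M = regimen.k_in, regimen.t_f, regimen.T, regimen.M
    amp = F * kin / ke

    def _one(ts):
        # one infusion pulse: on at 0, off at tf
        ts = np.asarray(ts, dtype=float)
        up = -np.expm1(-ke * np.maximum(ts, 0.0)) * heaviside(ts)
        down = -np.expm1(-ke * np.maximum(ts - tf, 0.0)) * heaviside(ts - tf)
        return amp * (up - down)

    def interval(m, t_m):
        t_m = np.asarray(t_m, dtype=float)
        m = np.asarray(m, dtype=float)
        # (e^{-m ke T} - e^{-ke T}) / (e^{-ke T} - 1)
        with np.errstate(over="ignore"):
            em = np.where(np.isinf(m), 0.0, np.exp(-m * ke * T))
        geo = (em - math.exp(-ke * T)) / math.expm1(-ke * T)
        return amp * (
            -np.expm1(-ke * t_m)
            + math.expm1(ke * tf) * geo * np.exp(-ke * t_m)
            - heaviside(t_m - tf) * -np.expm1(-ke * np.maximum(t_m - tf, 0.0))
        )

    def levels(t):
        t = np.asarray(t, dtype=float)
        m = _interval_index(t, T, M)
        t_m = t - (m - 1) * T
        return {"central": interval(m, t_m) * heaviside(t)}

    def levels_sum(t):
        t = np.asarray(t, dtype=float)
        m_eff = int(M) if not math.isinf(M) else int(np.floor(t.max() / T)) + 1
        ac = np.zeros_like(t)
        for j in range(m_eff):
            ac += _one(t - j * T)
        return {"central": ac}

    def steady():
        coeff = (math.exp(ke * tf) - math.exp(ke * T)) / (1.0 - math.exp(ke * T))

        def ev(t_inf):
            t_inf = np.asarray(t_inf, dtype=float)
            ac = amp * (
                1.0
                - coeff * np.exp(-ke * t_inf)
                - heaviside(t_inf - tf)
                * -np.expm1(-ke * np.maximum(t_inf - tf, 0.0))
            )
            return {"central": ac}

        a0 = amp * (1.0 - coeff)
        return SteadyStateProfile(T=T, initial_values={"central": a0}, evaluator=ev)

    return ClassicalSolution(params, regimen, levels, interval, steady, levels_sum)


# ---------------------------------------------------------------------------
# M2 (absorption + central, oral)


def _m2_beq_solution(params: PKParams, regimen: Regimen) -> ClassicalSolution:
    ka, ke, F = params.k_a, params.k_e, params.F
    D0 = regimen.D0
    single = _single_dose(regimen)
    T = math.inf if single else regimen.T
    M = 1 if single else regimen.M
    pref = ka / (ke - ka) * F * D0

    def _ab_interval(m, t_m):
        ga = 1.0 if single else _geom(ka, T, m)
        return F * D0 * ga * np.exp(-ka * np.asarray(t_m, dtype=float))

    def interval(m, t_m):
        t_m = np.asarray(t_m, dtype=float)
        if single:
            ga = ge = 1.0
        else:
            ga = _geom(ka, T, m)
            ge = _geom(ke, T, m)
        return pref * (ga * np.exp(-ka * t_m) - ge * np.exp(-ke * t_m))

    def levels(t):
        t = np.asarray(t, dtype=float)
        if single:
            m = np.ones_like(t)
            t_m = t
        else:
            m = _interval_index(t, T, M)
            t_m = t - (m - 1) * T
        h = heaviside(t)
        return {
            "absorption": _ab_interval(m, t_m) * h,
            "central": interval(m, t_m) * h,
        }

    def levels_sum(t):
        t = np.asarray(t, dtype=float)
        m_eff = 1 if single else (
            int(M) if not math.isinf(M) else int(np.floor(t.max() / T)) + 1
        )
        tj = t[None, :] - np.arange(m_eff)[:, None] * (0.0 if single else T)
        h = heaviside(tj)
        tjc = np.where(tj > 0, tj, 0.0)
        ab = F * D0 * (h * np.exp(-ka * tjc)).sum(axis=0)
        ac = pref * (h * (np.exp(-ka * tjc) - np.exp(-ke * tjc))).sum(axis=0)
        return {"absorption": ab, "central": ac}

    def steady():
        if single:
            raise ValueError("single-dose regimen has no periodic steady state")
        fa = 1.0 / -math.expm1(-ka * T)
        fe = 1.0 / -math.expm1(-ke * T)

        def ev(t_inf):
            t_inf = np.asarray(t_inf, dtype=float)
            return {
                "absorption": F * D0 * fa * np.exp(-ka * t_inf),
                "central": pref
                * (fa * np.exp(-ka * t_inf) - fe * np.exp(-ke * t_inf)),
            }

        return SteadyStateProfile(
            T=T,
            initial_values={
                "absorption": F * D0 * fa,
                "central": pref * (fa - fe),
            },
            evaluator=ev,
        )

    return ClassicalSolution(params, regimen, levels, interval, steady, levels_sum)


def _m2_beql_solution(params: PKParams, regimen: Regimen) -> ClassicalSolution:
    base = _m2_beq_solution(params, regimen)
    ka, ke, F = params.k_a, params.k_e, params.F
    extra = regimen.D_L - regimen.D0
    pref = ka / (ke - ka) * F * extra

    def levels(t):
        t = np.asarray(t, dtype=float)
        out = base.levels(t)
        h = heaviside(t)
        out["absorption"] = out["absorption"] + F * extra * h * np.exp(-ka * t)
        out["central"] = out["central"] + pref * h * (
            np.exp(-ka * t) - np.exp(-ke * t)
        )
        return out

    def interval(m, t_m):
        t = np.asarray(t_m, dtype=float) + (np.asarray(m, float) - 1.0) * regimen.T
        return base.interval(m, t_m) + pref * (np.exp(-ka * t) - np.exp(-ke * t))

    return ClassicalSolution(params, regimen, levels, interval, base.steady)


_SOLVERS = {
    (Model.M1, RegimenKind.B1): _m1_beq_solution,
    (Model.M1, RegimenKind.Beq): _m1_beq_solution,
    (Model.M1, RegimenKind.BeqL): _m1_beql_solution,
    (Model.M1, RegimenKind.Ieq): _m1_ieq_solution,
    (Model.M2, RegimenKind.B1): _m2_beq_solution,
    (Model.M2, RegimenKind.Beq): _m2_beq_solution,
    (Model.M2, RegimenKind.BeqL): _m2_beql_solution,
}


def solve(params: PKParams, regimen: Regimen) -> ClassicalSolution:
    """Exact solution bundle for an (M1/M2, regimen) pair."""
    params, regimen = validate_params(params, regimen)
    key = (params.model, regimen.kind)
    if key not in _SOLVERS:
        raise ValueError(f"no classical solver for {key}")
    return _SOLVERS[key](params, regimen)


def _timecourse_op(params, regimen, t, model, kind) -> TimeCourse:
    params, regimen = validate_params(params, regimen)
    if params.model is not model or regimen.kind is not kind:
        raise ValueError(f"expected ({model.value}, {kind.value}) inputs")
    return solve(params, regimen).timecourse(t)


def m1_beq(params, regimen, t) -> TimeCourse:
    """IV equi-bolus dosing, one compartment: geometric superposition of
    decaying exponentials."""
    return _timecourse_op(params, regimen, t, Model.M1, RegimenKind.Beq)


def m1_beql(params, regimen, t) -> TimeCourse:
    """IV equi-bolus with loading dose: Beq plus an (D_L - D0) e^{-ke t}
    correction; same steady state."""
    return _timecourse_op(params, regimen, t, Model.M1, RegimenKind.BeqL)


def m1_ieq(params, regimen, t) -> TimeCourse:
    """IV equi-infusion dosing (on for t_f, off for T - t_f); continuous
    with derivative kinks at the switch times."""
    return _timecourse_op(params, regimen, t, Model.M1, RegimenKind.Ieq)


def m2_beq(params, regimen, t) -> TimeCourse:
    """Oral equi-bolus dosing, two compartments; returns both absorption
    and central levels."""
    return _timecourse_op(params, regimen, t, Model.M2, RegimenKind.Beq)


def m2_beql(params, regimen, t) -> TimeCourse:
    """Oral equi-bolus with loading dose."""
    return _timecourse_op(params, regimen, t, Model.M2, RegimenKind.BeqL)


def continuous_infusion(params: PKParams, k_in: float, t) -> TimeCourse:
    """Single continuous IV infusion: monotone rise to the plateau
    F k_in / k_e."""
    if not isinstance(params, PKParams):
        params = PKParams(**params)
    if params.model is not Model.M1:
        raise ValueError("continuous infusion is a one-compartment result")
    if not k_in > 0:
        raise ValueError("k_in must be positive")
    t = np.asarray(t, dtype=float)
    ac = params.F * k_in / params.k_e * -np.expm1(-params.k_e * np.maximum(t, 0.0))
    return TimeCourse(t=t, levels={"central": ac}, meta={"k_in": k_in})


def lag_time_solution(
    params: PKParams,
    D0: float,
    t_lag: float,
    t,
    T: float | None = None,
    M: float = 1,
) -> TimeCourse:
    """Pure time-lag two-compartment profile: zero until ``t_lag``, then
    the single-dose oral solution shifted by ``t_lag``.  With ``T`` set,
    a multi-dose profile is built by superposing shifted copies."""
    if not isinstance(params, PKParams):
        params = PKParams(**params)
    if params.k_a is None:
        raise ValueError("lag-time model needs two-compartment parameters")
    if t_lag < 0:
        raise ValueError("t_lag must be >= 0")
    ka, ke, F = params.k_a, params.k_e, params.F
    t = np.asarray(t, dtype=float)

    def single(ts):
        s = np.maximum(ts - t_lag, 0.0)
        h = heaviside(ts - t_lag)
        ab = F * D0 * h * np.exp(-ka * s)
        ac = ka / (ke - ka) * F * D0 * h * (np.exp(-ka * s) - np.exp(-ke * s))
        return ab, ac

    if T is None:
        ab, ac = single(t)
    else:
        m_eff = int(M) if not math.isinf(M) else int(np.floor(t.max() / T)) + 1
        ab = np.zeros_like(t)
        ac = np.zeros_like(t)
        for j in range(m_eff):
            a, c = single(t - j * T)
            ab += a
            ac += c
    return TimeCourse(
        t=t,
        levels={"absorption": ab, "central": ac},
        meta={"t_lag": t_lag, "D0": D0},
    )


def m2_steady_extrema(
    params: PKParams, T: float, D0: float
) -> tuple[float, float, float]:
    """Steady-state trough, peak time and peak level for oral
    equi-dosing.

    Returns ``(a_min, t_star, a_max)``: the trough is the interval-start
    value, and the peak time ``t_star`` in (0, T) is the closed-form
    stationary point of the periodic profile.
    """
    if not isinstance(params, PKParams):
        params = PKParams(**params)
    ka, ke, F = params.k_a, params.k_e, params.F
    ea = -math.expm1(-ka * T)  # 1 - e^{-ka T}
    ee = -math.expm1(-ke * T)  # 1 - e^{-ke T}
    a_min = ka / (ke - ka) * F * D0 * (1.0 / ea - 1.0 / ee)
    t_star = 1.0 / (ka - ke) * math.log((ka / ke) * (ee / ea))
    a_max = F * D0 * ((ke / ka) ** ke * ea**ke / ee**ka) ** (1.0 / (ka - ke))
    return a_min, t_star, a_max
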