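"""Independent reference computations for the test-suite.

These deliberately avoid the closed forms under test: linear-ODE
propagation uses the matrix exponential or adaptive Runge-Kutta with
impulse restarts, Stirling numbers come from brute-force set-partition
enumeration, and incomplete-gamma values from adaptive quadrature.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.linalg import expm

from transitpk.core import Model, PKParams, Regimen, RegimenKind


def system_matrix(params: PKParams) -> np.ndarray:
    """Compartment transfer matrix; state ordering matches labels()."""
    if params.model is Model.M1:
        return np.array([[-params.k_e]])
    if params.model is Model.M2:
        return np.array(
            [[-params.k_a, 0.0], [params.k_a, -params.k_e]]
        )
    n = params.n
    B = np.zeros((n + 2, n + 2))
    for i in range(n):
        B[i, i] = -params.k
        if i > 0:
            B[i, i - 1] = params.k
    B[n, n - 1] = params.k
    B[n, n] = -params.k_a
    B[n + 1, n] = params.k_a
    B[n + 1, n + 1] = -params.k_e
    return B


def labels(params: PKParams) -> list[str]:
    if params.model is Model.M1:
        return ["central"]
    if params.model is Model.M2:
        return ["absorption", "central"]
    return [f"transit_{i}" for i in range(1, params.n + 1)] + [
        "absorption",
        "central",
    ]


def _dose_schedule(params: PKParams, regimen: Regimen) -> list[tuple[float, float]]:
    F = params.F
    if regimen.kind is RegimenKind.B1:
        return [(0.0, F * regimen.D0)]
    doses = [
        (j * regimen.T, F * regimen.D0) for j in range(int(regimen.M))
    ]
    if regimen.kind is RegimenKind.BeqL:
        doses[0] = (0.0, F * regimen.D_L)
    return doses


def bolus_oracle(params: PKParams, regimen: Regimen, t) -> dict[str, np.ndarray]:
    """Exact propagation of the impulsively dosed linear system with the
    matrix exponential (impulses add the effective dose to the first
    compartment)."""
    t = np.asarray(t, dtype=float)
    B = system_matrix(params)
    dim = B.shape[0]
    doses = dict()
    for tj, amt in _dose_schedule(params, regimen):
        doses[tj] = doses.get(tj, 0.0) + amt
    events = np.unique(np.concatenate([t, np.array(sorted(doses))]))
    x = np.zeros(dim)
    tprev = 0.0
    states = {}
    for te in events:
        if te < 0:
            states[te] = x.copy()
            continue
        x = expm(B * (te - tprev)) @ x
        tprev = te
        if te in doses:
            x[0] += doses[te]
        states[te] = x.copy()
    out = np.stack([states[ti] for ti in t], axis=1)
    return {name: out[i] for i, name in enumerate(labels(params))}


def rk_bolus_oracle(
    params: PKParams, regimen: Regimen, t, rtol=1e-10, atol=1e-12
) -> dict[str, np.ndarray]:
    """Adaptive Runge-Kutta integration between doses with impulse
    restarts at each dose time."""
    t = np.asarray(t, dtype=float)
    B = system_matrix(params)
    dim = B.shape[0]
    doses = {}
    for tj, amt in _dose_schedule(params, regimen):
        doses[tj] = doses.get(tj, 0.0) + amt
    dose_times = sorted(doses)
    segments = dose_times + [float(max(t.max(), dose_times[-1])) + 1e-9]
    x = np.zeros(dim)
    out = np.zeros((dim, t.size))
    done = t < 0
    for lo, hi in zip(segments[:-1], segments[1:]):
        x = x.copy()
        x[0] += doses[lo]
        sel = ~done & (t >= lo) & (t < hi)
        t_eval = np.unique(t[sel])
        sol = solve_ivp(
            lambda ti, y: B @ y,
            (lo, hi),
            x,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if t_eval.size:
            vals = sol.sol(t_eval)
            for i, te in enumerate(t_eval):
                out[:, np.isclose(t, te)] = vals[:, i : i + 1]
        done |= sel
        x = sol.y[:, -1]
    return {name: out[i] for i, name in enumerate(labels(params))}


def infusion_oracle(
    params: PKParams, regimen: Regimen, t, rtol=1e-11
) -> np.ndarray:
    """One-compartment periodic-infusion solution by adaptive
    integration of the piecewise-constant forcing."""
    t = np.asarray(t, dtype=float)
    ke, F = params.k_e, params.F
    kin, tf, T, M = regimen.k_in, regimen.t_f, regimen.T, int(regimen.M)

    def forcing(ti):
        if ti < 0 or ti >= M * T:
            return 0.0
        return F * kin if (ti % T) < tf else 0.0

    switches = sorted(
        {j * T for j in range(M + 1)} | {j * T + tf for j in range(M)}
    )
    t_end = float(max(t.max(), switches[-1]))
    segments = [s for s in switches if s < t_end] + [t_end]
    x = 0.0
    out = np.zeros(t.size)
    for lo, hi in zip(segments[:-1], segments[1:]):
        f = forcing(lo)
        sol = solve_ivp(
            lambda ti, y: [f - ke * y[0]],
            (lo, hi),
            [x],
            rtol=rtol,
            atol=1e-13,
            dense_output=True,
        )
        sel = (t >= lo) & (t <= hi)
        if np.any(sel):
            out[sel] = sol.sol(t[sel])[0]
        x = float(sol.y[0, -1])
    out[t < 0] = 0.0
    return out


def count_set_partitions(n: int, q: int) -> int:
    """Number of partitions of {0..n-1} into exactly q nonempty blocks,
    by exhaustive enumeration of block assignments."""
    if n == 0:
        return 1 if q == 0 else 0
    count = 0
    for assignment in itertools.product(range(q), repeat=n):
        if len(set(assignment)) != q:
            continue
        # canonical labelling: first occurrences in increasing order
        first = {}
        for a in assignment:
            if a not in first:
                first[a] = len(first)
        if all(first[a] == a for a in range(q) if a in first):
            canonical = tuple(first[a] for a in assignment)
            if canonical == assignment:
                count += 1
    return count


def gamma_quadrature(n: int, t: float) -> float:
    """Lower incomplete gamma by adaptive quadrature (any real t)."""
    val, err = quad(lambda x: x ** (n - 1) * math.exp(-x), 0.0, t,
                    epsabs=1e-13, epsrel=1e-13)
    assert abs(err) < 1e-9
    return val
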