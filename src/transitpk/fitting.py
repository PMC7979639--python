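"""Least-squares parameter estimation for transit-compartment and
lag-time models, with an n-sweep and flip-flop identifiability checks.

The number of transit compartments n is a discrete parameter: the sweep
fits the continuous parameters (k, k_a, k_e, F) separately for each
candidate n and selects the n with minimal sum of squared errors (SSE).
Rates are optimised in log space and F in logit space so positivity and
F <= 1 hold by construction.  Each fit is multi-start (derivative-free
Nelder-Mead from seeded random perturbations of a data-driven initial
guess, followed by a least-squares polish), since 4-parameter SSE
surfaces for these models are start-sensitive.

For n = 1 the transit and absorption rates are structurally
unidentifiable: swapping (k, k_a) leaves the central-compartment inflow
-- and hence the fitted output -- unchanged (the flip-flop phenomenon of
two-compartment kinetics).  :func:`flip_flop_pair` demonstrates this;
the sweep therefore starts at n = 2 by default and n = 1 requests emit
a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .core import Model, PKParams, Regimen, RegimenKind
from . import classical, tcm

__all__ = [
    "FitResult",
    "NFit",
    "fit_tcm",
    "fit_lag",
    "flip_flop_pair",
    "IdentifiabilityWarning",
]


class IdentifiabilityWarning(UserWarning):
    """Fitting a structurally unidentifiable parameterisation."""


@dataclass
class NFit:
    """Best fit for one fixed number of transit compartments."""

    n: int
    params: dict[str, float]
    sse: float
    converged: bool
    nfev: int


@dataclass
class FitResult:
    """n-sweep fit summary; ``best`` is the arg-min-SSE entry."""

    fits: list[NFit]
    model: str  # "tcm" or "lag"

    @property
    def best(self) -> NFit:
        return min(self.fits, key=lambda f: f.sse)

    @property
    def best_n(self) -> int:
        return self.best.n

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            row = {"n": f.n, "sse": f.sse, "converged": f.converged}
            row.update(f.params)
            rows.append(row)
        return pd.DataFrame(rows)


def _check_observations(t, y):
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or t.size < 4:
        raise ValueError("observations must be matching 1-D arrays, >= 4 points")
    if np.all(y == 0):
        raise ValueError("degenerate fit: all observations are zero")
    if np.any(y < 0):
        raise ValueError("drug amounts cannot be negative")
    return t, y


def _logit(x):
    return math.log(x / (1.0 - x))


def _expit(z):
    return 1.0 / (1.0 + math.exp(-z))


def _heuristic_start(t, y, n):
    """Data-driven initial guess: terminal slope for k_e, peak time for
    the mean transit time, absorption a few times faster than elimination."""
    i_peak = int(np.argmax(y))
    tail = slice(max(i_peak + 1, t.size - 4), t.size)
    tt, yy = t[tail], y[tail]
    ke = 0.5
    if tt.size >= 2 and np.all(yy > 0):
        slope = np.polyfit(tt, np.log(yy), 1)[0]
        if slope < 0:
            ke = -slope
    t_peak = max(t[i_peak], t[1])
    mtt = max(0.5 * t_peak, 1e-2)
    return {"k": n / mtt, "k_a": 3.0 * ke, "k_e": ke, "F": 0.7}


def _fit_fixed(
    predict, theta0, n_starts, rng, maxiter, scatter=0.6
):
    """Multi-start Nelder-Mead + least-squares polish in transformed
    coordinates.  ``predict(theta) -> residuals``."""

    def sse(theta):
        r = predict(theta)
        return float(r @ r)

    best = None
    starts = [np.asarray(theta0, dtype=float)]
    for _ in range(n_starts - 1):
        starts.append(starts[0] + rng.normal(scale=scatter, size=len(theta0)))
    for s in starts:
        res = minimize(
            sse,
            s,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-10, "fatol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    # derivative-free result polished to full precision
    polish = least_squares(predict, best.x, method="lm", xtol=1e-15, ftol=1e-15, max_nfev=4000)
    if float(polish.cost * 2) < best.fun:
        return polish.x, float(2 * polish.cost), True, best.nfev + polish.nfev
    return best.x, float(best.fun), bool(best.success), best.nfev


def fit_tcm(
    t,
    y,
    dose: float,
    n_range=range(2, 16),
    regimen: Regimen | None = None,
    seed: int = 0,
    n_starts: int = 8,
    maxiter: int = 1000,
) -> FitResult:
    """Sweep-fit the transit-compartment model to central-level
    observations.

    Parameters
    ----------
    t, y:
        Observation times (h) and central drug amounts (mg).
    dose:
        Administered dose D0 (mg); a single bolus unless ``regimen``
        overrides it.
    n_range:
        Candidate transit-compartment counts; n = 1 triggers an
        identifiability warning (k and k_a swap freely there).
    seed, n_starts:
        Multi-start randomisation; the default 8 starts per n.
    maxiter:
        Nelder-Mead iteration cap per start.
    """
    t, y = _check_observations(t, y)
    rng = np.random.default_rng(seed)
    if regimen is None:
        regimen = Regimen(kind=RegimenKind.B1, D0=dose)
    fits = []
    for n in n_range:
        n = int(n)
        if n < 1:
            raise ValueError("n must be >= 1")
        if n == 1:
            warnings.warn(
                "n = 1: k and k_a are not uniquely identifiable (flip-flop)",
                IdentifiabilityWarning,
                stacklevel=2,
            )

        def predict(theta, n=n):
            # keep the search inside a physically plausible rate box
            if np.any(np.abs(theta[:3]) > 9.0) or abs(theta[3]) > 30.0:
                return np.full(t.shape, 1e6)
            k, ka, ke = np.exp(theta[:3])
            F = _expit(theta[3])
            # keep clear of the rate-coincidence singular set
            rates = sorted([k, ka, ke])
            if rates[1] - rates[0] < 1e-9 * rates[2] or rates[2] - rates[1] < 1e-9 * rates[2]:
                return np.full(t.shape, 1e6)
            try:
                p = PKParams(model=Model.Mt, k_e=ke, k_a=ka, k=k, n=n, F=F)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pred = tcm.central_level(p, regimen, t)
            except (ValueError, OverflowError):
                return np.full(t.shape, 1e6)
            return pred - y

        h = _heuristic_start(t, y, n)
        theta0 = [math.log(h["k"]), math.log(h["k_a"]), math.log(h["k_e"]), _logit(h["F"])]
        x, sse, ok, nfev = _fit_fixed(predict, theta0, n_starts, rng, maxiter)
        fits.append(
            NFit(
                n=n,
                params={
                    "k": math.exp(x[0]),
                    "k_a": math.exp(x[1]),
                    "k_e": math.exp(x[2]),
                    "F": _expit(x[3]),
                },
                sse=sse,
                converged=ok,
                nfev=nfev,
            )
        )
    return FitResult(fits=fits, model="tcm")


def fit_lag(
    t,
    y,
    dose: float,
    seed: int = 0,
    n_starts: int = 8,
    maxiter: int = 1000,
) -> FitResult:
    """Fit the pure time-lag two-compartment model (parameters k_a, k_e,
    t_lag, F) to single-dose central-level observations."""
    t, y = _check_observations(t, y)
    rng = np.random.default_rng(seed)

    def predict(theta):
        ka, ke = np.exp(theta[:2])
        t_lag = theta[2] ** 2  # >= 0 by construction
        F = _expit(theta[3])
        if abs(ka - ke) < 1e-9 * max(ka, ke):
            return np.full(t.shape, 1e6)
        p = PKParams(model=Model.M2, k_e=ke, k_a=ka, F=F)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = classical.lag_time_solution(p, dose, t_lag, t).central
        return pred - y

    h = _heuristic_start(t, y, 1)
    t_peak = max(float(t[np.argmax(y)]), 1e-2)
    theta0 = [
        math.log(h["k_a"]),
        math.log(h["k_e"]),
        math.sqrt(0.3 * t_peak),
        _logit(h["F"]),
    ]
    x, sse, ok, nfev = _fit_fixed(predict, theta0, n_starts, rng, maxiter)
    fit = NFit(
        n=0,
        params={
            "k_a": math.exp(x[0]),
            "k_e": math.exp(x[1]),
            "t_lag": x[2] ** 2,
            "F": _expit(x[3]),
        },
        sse=sse,
        converged=ok,
        nfev=nfev,
    )
    return FitResult(fits=[fit], model="lag")


def flip_flop_pair(
    k1: float,
    k2: float,
    k_e: float,
    t,
    D0: float = 1.0,
    F: float = 1.0,
    n: int = 1,
) -> dict[str, np.ndarray]:
    """Central-compartment inflow and level for the two swapped
    parameterisations (k=k1, k_a=k2) and (k=k2, k_a=k1).

    For n = 1 the two inflows (and hence the central levels) are
    identical -- k and k_a cannot be told apart from central data.  For
    n >= 2 the symmetry is broken and the curves differ.
    """
    if k1 == k2:
        raise ValueError("k1 and k2 must differ")
    t = np.asarray(t, dtype=float)
    regimen = Regimen(kind=RegimenKind.B1, D0=D0)
    out = {}
    for tag, (k, ka) in {"12": (k1, k2), "21": (k2, k1)}.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = PKParams(model=Model.Mt, k_e=k_e, k_a=ka, k=k, n=n, F=F)
            out[f"inflow_{tag}"] = ka * tcm.absorption_level(p, regimen, t)
            out[f"central_{tag}"] = tcm.central_level(p, regimen, t)
    return out
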