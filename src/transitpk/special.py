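"""Lower incomplete gamma function and Stirling numbers of the second kind.

The transit-compartment closed forms are built from integer-shape lower
incomplete gamma functions gamma(n, (k - k_x) t) whose argument is
*negative* whenever the transit rate k is smaller than the downstream
rate k_x, a regime standard library routines reject.  This module
provides:

* :func:`lower_incomplete_gamma` -- gamma(n, t) for any real t,
* :func:`log_gamma_scaled` -- the log of the always-positive combination
  gamma(n, c t) / (c^n (n-1)!) that the solvers actually need, evaluated
  in log space so that astronomically large/small factors never meet in
  double precision,
* :func:`stirling2` -- exact integer Stirling numbers of the second kind
  for the closed-form steady-state interval-initial values.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammainc, gammaln, logsumexp

__all__ = [
    "lower_incomplete_gamma",
    "lower_incomplete_gamma_cdf",
    "log_gamma_scaled",
    "gamma_scaled",
    "stirling2",
]


def _gamma_neg_scalar(n: int, t: float) -> float:
    # gamma(n, -s) = (-1)^n int_0^s u^{n-1} e^u du for s = -t > 0.
    # The textbook closed form (n-1)!(1 - e^{-t} sum_{p<n} t^p/p!)
    # cancels catastrophically for |t| << n, so the integral is summed
    # as the everywhere-positive series sum_m s^{n+m}/(m!(n+m)).
    s = -t
    terms = []
    coef = s**n / n if n * math.log(s) < 700 else math.inf
    m = 0
    peak = coef
    while True:
        terms.append(coef)
        peak = max(peak, coef)
        if (coef < 1e-18 * peak and m > s) or m > 100_000 or not math.isfinite(coef):
            break
        coef *= s * (n + m) / ((m + 1) * (n + m + 1))
        m += 1
    integral = math.fsum(terms)
    return (-1.0) ** n * integral


def lower_incomplete_gamma(n: int, t):
    """gamma(n, t) = int_0^t x^{n-1} e^{-x} dx for integer n >= 1, any real t.

    For t >= 0 this routes through the regularised incomplete gamma
    (equivalently the unit-scale gamma-distribution CDF); for t < 0 it
    uses the truncated-exponential closed form, which is exact for
    integer shape.  Continuous at t = 0 with gamma(n, 0) = 0.

    Magnitudes are limited by ``(n-1)!`` in double precision (n <= 170);
    the solvers use :func:`log_gamma_scaled` instead, which has no such
    limit.
    """
    if int(n) != n or n < 1:
        raise ValueError("shape n must be a positive integer")
    n = int(n)
    t_arr = np.asarray(t, dtype=float)
    out = np.empty_like(t_arr)
    pos = t_arr >= 0
    if np.any(pos):
        out[pos] = math.gamma(n) * gammainc(n, t_arr[pos])
    if np.any(~pos):
        neg_vals = [_gamma_neg_scalar(n, ti) for ti in np.atleast_1d(t_arr[~pos])]
        out[~pos] = neg_vals
    return out if np.ndim(t) else float(out)


def lower_incomplete_gamma_cdf(n: int, t):
    """Fallback route gamma(n,t) = exp(lnGamma(n)) * F_Gamma(t; n, 1),
    using the exponentiated log-gamma and the gamma-distribution CDF.

    Defined for t >= 0 (the CDF route has no negative-argument
    extension); cross-checked against :func:`lower_incomplete_gamma`.
    """
    if int(n) != n or n < 1:
        raise ValueError("shape n must be a positive integer")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("CDF route requires t >= 0")
    out = np.exp(gammaln(n)) * gammainc(n, t_arr)
    return out if np.ndim(t) else float(out)


def _log_asymptotic_positive(n: int, b: float, t: np.ndarray) -> np.ndarray:
    # exact finite form for b t >> n (integration by parts from the top):
    # int_0^t u^{n-1} e^{bu} du = e^{bt} t^{n-1}/b * sum_{j<n} (-1)^j c_j
    #                             + (-1)^n (n-1)!/b^n,
    # c_j = (n-1)!/((n-1-j)! (bt)^j); terms decrease when bt > n so the
    # alternating sum is stable; the last term is exponentially negligible
    bt = b * t
    j = np.arange(n)
    log_c = gammaln(n) - gammaln(n - j)  # log (n-1)!/(n-1-j)!
    s = np.exp(log_c[None, :] - j[None, :] * np.log(bt)[:, None])
    alt = (s * (-1.0) ** j[None, :]).sum(axis=1)
    return bt + (n - 1) * np.log(t) - math.log(b) + np.log(alt) - gammaln(n)


def _log_series_positive(n: int, b: float, t: np.ndarray) -> np.ndarray:
    # log of int_0^t u^{n-1} e^{bu} du / (n-1)!  for b > 0, t > 0
    #   = log sum_{m>=0} b^m t^{n+m} / (m! (n+m) (n-1)!)   (all terms > 0)
    out = np.empty_like(t)
    big = b * t > 2.0 * n + 40.0
    if np.any(big):
        out[big] = _log_asymptotic_positive(n, b, t[big])
    small = ~big
    if np.any(small):
        ts = t[small]
        bt_max = b * float(ts.max())
        m_max = int(bt_max + 40.0 * math.sqrt(bt_max + 40.0) + 60.0)
        m = np.arange(m_max + 1)
        # terms[i, m] = n log t_i + m log(b t_i) - lgamma(m+1) - log(n+m)
        terms = (
            n * np.log(ts)[:, None]
            + m[None, :] * (math.log(b) + np.log(ts))[:, None]
            - gammaln(m + 1)[None, :]
            - np.log(n + m)[None, :]
        )
        out[small] = logsumexp(terms, axis=1) - gammaln(n)
    return out


def _log_gamma_small_x(n: int, x: np.ndarray) -> np.ndarray:
    # log gamma(n, x) via gamma(n,x) = x^n e^{-x} sum_{m>=0} x^m / (n...(n+m))
    # accurate and underflow-free for x small relative to n (x > 0)
    m_max = 80
    m = np.arange(m_max + 1)
    # log coefficient: -log(n (n+1) ... (n+m)) = lgamma(n) - lgamma(n+m+1)
    terms = (
        m[None, :] * np.log(x)[:, None]
        + gammaln(n)
        - gammaln(n + m + 1)[None, :]
    )
    return n * np.log(x) - x + logsumexp(terms, axis=1)


def log_gamma_scaled(n: int, c: float, t):
    """log of P(n, c, t) = gamma(n, c t) / (c^n (n-1)!).

    Substituting x = c u shows P(n, c, t) = int_0^t u^{n-1} e^{-c u} du
    / (n-1)!, which is strictly positive for t > 0 *regardless of the
    sign of c* -- this is the combination appearing in every absorption/
    central closed form, with c = k - k_a or c = k - k_e.  Evaluating its
    logarithm directly avoids overflow of gamma(n, c t) and underflow of
    c^{-n} for large n.

    Returns -inf at t = 0.  Requires t >= 0 and c != 0.
    """
    if int(n) != n or n < 1:
        raise ValueError("shape n must be a positive integer")
    if c == 0:
        raise ValueError("c must be nonzero (rate coincidence)")
    n = int(n)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = np.full(t_arr.shape, -np.inf)
    pos = t_arr > 0
    tp = t_arr[pos]
    if tp.size:
        if c > 0:
            x = c * tp
            with np.errstate(divide="ignore"):
                reg = np.log(gammainc(n, x)) - n * math.log(c)
            # gammainc underflows to 0 when x << n; switch to the series
            bad = ~np.isfinite(reg)
            if np.any(bad):
                reg[bad] = _log_gamma_small_x(n, x[bad]) - gammaln(n) - n * math.log(c)
            out[pos] = reg
        else:
            out[pos] = _log_series_positive(n, -c, tp)
    return out if np.ndim(t) else float(out[0])


def gamma_scaled(n: int, c: float, t):
    """P(n, c, t) = gamma(n, c t) / (c^n (n-1)!), see :func:`log_gamma_scaled`."""
    return np.exp(log_gamma_scaled(n, c, t))


def stirling2(n: int, q: int) -> int:
    """Stirling number of the second kind S(n, q): the number of ways to
    partition an n-element set into q nonempty blocks.

    Evaluated by the alternating binomial sum in exact integer
    arithmetic (S grows combinatorially and would lose precision in
    floats), with S(0, 0) = 1.
    """
    if n < 0 or q < 0 or int(n) != n or int(q) != q:
        raise ValueError("n and q must be nonnegative integers")
    if q > n:
        raise ValueError(f"require q <= n, got S({n}, {q})")
    n, q = int(n), int(q)
    if n == 0 and q == 0:
        return 1
    if q == 0:
        return 0
    total = sum(
        (-1) ** p * math.comb(q, p) * (q - p) ** n for p in range(q + 1)
    )
    return total // math.factorial(q)
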