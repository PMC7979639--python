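"""Equi-dosing regimen regions (EDRRs).

An EDRR is the set of regimen parameters -- (T, D0) for repeated bolus
dosing, plus a loading dose D_L or infusion on-time t_f for the
three-parameter regimens -- whose *periodic steady-state* central drug
level stays strictly inside a therapeutic range (D_me, D_MS).  For the
one- and two-compartment models the region boundaries are analytical
curves f_lo(T) < D0 < f_hi(T) (petal-shaped regions); for the transit
model the boundaries are constructed numerically from the steady-state
evaluator.

Because every steady-state solution is linear in the dose, the
numerical construction defaults to the linearity route: compute the
steady min/max for a unit dose once per T and divide the range bounds
by them.  The grid-scan algorithm (discretise D0, pick the grid dose
whose steady extremum is closest to the range bound) is retained as
``method="scan"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from . import classical, tcm
from .core import (
    Model,
    PKParams,
    Regimen,
    RegimenKind,
    TherapeuticRange,
    validate_params,
)

__all__ = [
    "EDRR2D",
    "EDRR3D",
    "Verdict",
    "RegimenVerdict",
    "steady_extrema",
    "edrr_iv_bolus",
    "edrr_oral_bolus",
    "edrr_loading",
    "edrr_infusion",
    "edrr_numerical",
    "classify_regimen",
]


@dataclass
class EDRR2D:
    """Two-parameter acceptable-regimen region bounded by two curves.

    For bolus regimens the axes are (T, D0); for fixed-t_f infusion
    slices they are (T, k_in).  Outside the T-domain of the petal both
    curves are NaN.  The region is ``{(T, y): f_lo(T) < y < f_hi(T)}``.
    """

    T: np.ndarray
    f_lo: np.ndarray
    f_hi: np.ndarray
    crossover: tuple[float, float] | None = None  # (T*, y*)
    y_label: str = "D0"
    meta: dict = field(default_factory=dict)

    @property
    def nonempty(self) -> bool:
        ok = np.isfinite(self.f_lo) & np.isfinite(self.f_hi)
        return bool(np.any(self.f_lo[ok] < self.f_hi[ok]))

    def contains(self, T: float, y: float) -> bool:
        lo = np.interp(T, self.T, self.f_lo, left=np.nan, right=np.nan)
        hi = np.interp(T, self.T, self.f_hi, left=np.nan, right=np.nan)
        if not (np.isfinite(lo) and np.isfinite(hi)):
            return False
        return bool(lo < y < hi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"T": self.T, "f_lo": self.f_lo, "f_hi": self.f_hi})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EDRR3D:
    """Three-parameter region stored as a stack of 2-D slices over a
    third regimen parameter (D_L or t_f)."""

    slice_param: str
    slice_values: np.ndarray
    slices: list[EDRR2D]
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for v, s in zip(self.slice_values, self.slices):
            f = s.to_frame()
            f.insert(0, self.slice_param, v)
            parts.append(f)
        return pd.concat(parts, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class Verdict(str, Enum):
    ACCEPTABLE = "acceptable"  # entirely within the therapeutic range
    UNSAFE = "unsafe"  # steady peak overshoots D_MS
    INEFFECTIVE = "ineffective"  # steady trough undershoots D_me
    BOTH = "both"  # overshoots and undershoots


@dataclass(frozen=True)
class RegimenVerdict:
    verdict: Verdict
    steady_min: float
    steady_max: float


# ---------------------------------------------------------------------------
# steady-state extrema


def tcm_steady_extrema(
    params: PKParams, T: float, D0: float, samples: int = 2000
) -> tuple[float, float]:
    """Steady-state (trough, peak) of the transit-model central level by
    dense sampling of one period plus bounded golden-section refinement.

    The periodic profile is continuous (only transit_1 jumps at dose
    times), so a dense grid brackets both extrema; each is then refined
    within one grid step.  The trough may sit at the interval start or
    in the interior depending on the delay, so the search is global.
    """
    prof = tcm.ss_profile(params, T, D0)
    t = np.linspace(0.0, T, samples, endpoint=False)
    ac = prof(t)["central"]

    def value(ti: float) -> float:
        return float(prof(np.array([ti % T]))["central"][0])

    def refine(idx: int, sign: float) -> float:
        lo = t[max(idx - 1, 0)]
        hi = t[min(idx + 1, samples - 1)]
        if hi <= lo:
            return sign * value(t[idx])
        res = minimize_scalar(
            lambda x: sign * value(x), bounds=(lo, hi), method="bounded",
            options={"xatol": T * 1e-10},
        )
        return min(res.fun, sign * value(t[idx]))

    a_max = -refine(int(np.argmax(ac)), -1.0)
    a_min = refine(int(np.argmin(ac)), 1.0)
    # the interval start is a candidate trough (the grid includes it at t[0])
    return float(a_min), float(a_max)


def steady_extrema(params: PKParams, regimen: Regimen) -> tuple[float, float]:
    """(trough, peak) of the periodic steady-state central level for any
    supported (model, regimen) pair."""
    params, regimen = validate_params(params, regimen)
    T = regimen.T
    if params.model is Model.M1 and regimen.kind in (
        RegimenKind.Beq,
        RegimenKind.BeqL,
    ):
        a0 = params.F * regimen.D0 / -math.expm1(-params.k_e * T)
        return a0 * math.exp(-params.k_e * T), a0
    if params.model is Model.M1 and regimen.kind is RegimenKind.Ieq:
        ke, F = params.k_e, params.F
        amp = F * regimen.k_in / ke
        tf = regimen.t_f
        a_max = amp * math.expm1(-ke * tf) / math.expm1(-ke * T)
        a_min = amp * math.expm1(ke * tf) / math.expm1(ke * T)
        return a_min, a_max
    if params.model is Model.M2 and regimen.kind in (
        RegimenKind.Beq,
        RegimenKind.BeqL,
    ):
        a_min, _, a_max = classical.m2_steady_extrema(params, T, regimen.D0)
        return a_min, a_max
    if params.model is Model.Mt:
        return tcm_steady_extrema(params, T, regimen.D0)
    raise ValueError(f"no steady state for ({params.model}, {regimen.kind})")


# ---------------------------------------------------------------------------
# analytical regions


def _default_T_grid(params: PKParams, rng: TherapeuticRange, points: int = 400):
    t_star = math.log(rng.D_MS / rng.D_me) / params.k_e
    return np.linspace(0.0, 2.0 * t_star, points + 1)[1:]


def edrr_iv_bolus(
    params: PKParams, rng: TherapeuticRange, T_grid=None
) -> EDRR2D:
    """Analytical petal for one-compartment IV equi-bolus dosing.

    f_lo(T) = (D_me/F)(e^{ke T} - 1) keeps the steady trough above
    D_me; f_hi(T) = (D_MS/F)(1 - e^{-ke T}) keeps the steady peak below
    D_MS.  The petal closes at T* = ln(D_MS/D_me)/ke, where the
    acceptable dose is D0* = (D_MS - D_me)/F.
    """
    if not isinstance(params, PKParams):
        params = PKParams(**params)
    if params.model is not Model.M1:
        raise ValueError("IV bolus region requires M1 parameters")
    ke, F = params.k_e, params.F
    if T_grid is None:
        T_grid = _default_T_grid(params, rng)
    T = np.asarray(T_grid, dtype=float)
    f_lo = rng.D_me / F * np.expm1(ke * T)
    f_hi = rng.D_MS / F * -np.expm1(-ke * T)
    t_star = math.log(rng.D_MS / rng.D_me) / ke
    d_star = (rng.D_MS - rng.D_me) / F
    return EDRR2D(
        T=T,
        f_lo=f_lo,
        f_hi=f_hi,
        crossover=(t_star, d_star),
        meta={"model": "M1", "range": rng, "params": params},
    )


def _oral_bounds(params: PKParams, rng: TherapeuticRange, T: np.ndarray):
    ka, ke, F = params.k_a, params.k_e, params.F
    ea = -np.expm1(-ka * T)  # 1 - e^{-ka T}
    ee = -np.expm1(-ke * T)  # 1 - e^{-ke T}
    f_lo = (
        rng.D_me / F * (ka - ke) / ka * ea * ee / (np.exp(-ke * T) - np.exp(-ka * T))
    )
    f_hi = rng.D_MS / F * ((ke / ka) ** ke * ea**ke / ee**ka) ** (
        1.0 / (ke - ka)
    )
    return f_lo, f_hi


def edrr_oral_bolus(
    params: PKParams, rng: TherapeuticRange, T_grid=None
) -> EDRR2D:
    """Analytical petal for two-compartment oral equi-bolus dosing.

    The bounds invert the closed-form steady trough/peak; the crossover
    (petal tip) has no closed form and is located numerically.
    """
    if not isinstance(params, PKParams):
        params = PKParams(**params)
    if params.model is not Model.M2:
        raise ValueError("oral bolus region requires M2 parameters")
    if T_grid is None:
        T_grid = _default_T_grid(params, rng)
    T = np.asarray(T_grid, dtype=float)
    f_lo, f_hi = _oral_bounds(params, rng, T)

    def gap(Ti):
        lo, hi = _oral_bounds(params, rng, np.array([Ti]))
        return float(hi[0] - lo[0])

    t_hi = float(T.max())
    while gap(t_hi) > 0:
        t_hi *= 2.0
    # bracket from the widest point of the petal (the gap vanishes at
    # both ends, so a fixed left endpoint is unreliable)
    scan = np.geomspace(1e-4 / params.k_e, t_hi, 256)
    gaps = np.array([gap(s) for s in scan])
    i_max = int(np.argmax(gaps))
    if gaps[i_max] <= 0:
        t_star, d_star = float("nan"), float("nan")
    else:
        t_star = brentq(gap, scan[i_max], t_hi, xtol=1e-12)
        d_star = float(_oral_bounds(params, rng, np.array([t_star]))[0][0])
    return EDRR2D(
        T=T,
        f_lo=f_lo,
        f_hi=f_hi,
        crossover=(t_star, d_star),
        meta={"model": "M2", "range": rng, "params": params},
    )


def edrr_loading(
    params: PKParams,
    rng: TherapeuticRange,
    D_L_values,
    T_grid=None,
) -> EDRR3D:
    """Three-parameter region for IV equi-bolus dosing with a loading
    dose, as a stack of per-D_L "chopped petals".

    A regimen is acceptable when the level is therapeutic *immediately
    and always*: the steady-state petal constraint plus a first-interval
    constraint D_me e^{ke T} < F D_L < D_MS, which chops the petal at
    T < ln(F D_L / D_me)/ke (intermediate intervals are covered because
    the per-interval peaks and troughs evolve monotonically).
    """
    if not isinstance(params, PKParams):
        params = PKParams(**params)
    ke, F = params.k_e, params.F
    base = edrr_iv_bolus(params, rng, T_grid)
    slices = []
    values = np.asarray(D_L_values, dtype=float)
    for dl in values:
        f_lo = base.f_lo.copy()
        f_hi = base.f_hi.copy()
        if F * dl >= rng.D_MS or F * dl <= rng.D_me:
            # first interval already unsafe (or never effective)
            f_lo[:] = np.nan
            f_hi[:] = np.nan
        else:
            t_chop = math.log(F * dl / rng.D_me) / ke
            cut = base.T >= t_chop
            f_lo[cut] = np.nan
            f_hi[cut] = np.nan
        slices.append(
            EDRR2D(
                T=base.T,
                f_lo=f_lo,
                f_hi=f_hi,
                crossover=base.crossover,
                meta={"D_L": float(dl)},
            )
        )
    return EDRR3D(
        slice_param="D_L",
        slice_values=values,
        slices=slices,
        meta={"model": "M1", "range": rng, "params": params,
              "boundary_surface": "D_L = (D_me/F) e^{ke T}"},
    )


def infusion_crossover(params: PKParams, rng: TherapeuticRange, t_f: float) -> float:
    """Crossover infusion rate k_in* where the two steady-state bounds of
    the fixed-t_f infusion petal meet."""
    ke, F = params.k_e, params.F
    return (
        ke
        / F
        * (rng.D_MS - rng.D_me * math.exp(-ke * t_f))
        / -math.expm1(-ke * t_f)
    )


def edrr_infusion(
    params: PKParams,
    rng: TherapeuticRange,
    t_f_values,
    T_points: int = 400,
) -> EDRR3D:
    """Three-parameter region for periodic IV infusion, as a stack of
    per-t_f chopped petals in (T, k_in) space.

    Each slice lives on t_f < T < t_f + ln(D_MS/D_me)/ke; the lower
    bound keeps the steady trough (at the start of the "on" phase)
    above D_me, the upper keeps the steady peak (at switch-off, t_f into
    the interval) below D_MS.
    """
    if not isinstance(params, PKParams):
        params = PKParams(**params)
    if params.model is not Model.M1:
        raise ValueError("infusion region requires M1 parameters")
    ke, F = params.k_e, params.F
    span = math.log(rng.D_MS / rng.D_me) / ke
    slices = []
    values = np.asarray(t_f_values, dtype=float)
    for tf in values:
        T = tf + np.linspace(0.0, span, T_points + 1)[1:]
        f_lo = ke * rng.D_me / F * np.expm1(ke * T) / math.expm1(ke * tf)
        f_hi = ke * rng.D_MS / F * -np.expm1(-ke * T) / -math.expm1(-ke * tf)
        slices.append(
            EDRR2D(
                T=T,
                f_lo=f_lo,
                f_hi=f_hi,
                crossover=(tf + span, infusion_crossover(params, rng, tf)),
                y_label="k_in",
                meta={"t_f": float(tf)},
            )
        )
    return EDRR3D(
        slice_param="t_f",
        slice_values=values,
        slices=slices,
        meta={"model": "M1", "range": rng, "params": params},
    )


# ---------------------------------------------------------------------------
# numerical region (transit model and cross-checks)


def _unit_extrema(params: PKParams, T: float, samples: int) -> tuple[float, float]:
    regimen = Regimen(kind=RegimenKind.Beq, D0=1.0, T=T, M=math.inf)
    if params.model is Model.Mt:
        return tcm_steady_extrema(params, T, 1.0, samples=samples)
    return steady_extrema(params, regimen)


def edrr_numerical(
    params: PKParams,
    rng: TherapeuticRange,
    T_grid=None,
    method: str = "linearity",
    D0_grid=None,
    samples: int = 2000,
) -> EDRR2D:
    """Numerically constructed (T, D0) region for any model with a
    steady-state evaluator (the transit model being the primary use).

    method="linearity" (default): the steady solution is proportional to
    D0, so f_lo(T) = D_me / min-of-unit-dose-profile and f_hi(T) =
    D_MS / max-of-unit-dose-profile, exact to evaluator precision.

    method="scan": discretise D0 as well and pick, per T, the grid dose
    whose steady trough (peak) lands closest to D_me (D_MS); one D0 grid
    step of quantisation error, retained mainly for validation.
    """
    if not isinstance(params, PKParams):
        params = PKParams(**params)
    if T_grid is None:
        T_grid = _default_T_grid(params, rng, points=100)
    T = np.asarray(T_grid, dtype=float)
    f_lo = np.full(T.shape, np.nan)
    f_hi = np.full(T.shape, np.nan)
    if method == "linearity":
        for i, Ti in enumerate(T):
            a_min, a_max = _unit_extrema(params, float(Ti), samples)
            f_lo[i] = rng.D_me / a_min if a_min > 0 else np.inf
            f_hi[i] = rng.D_MS / a_max
    elif method == "scan":
        if D0_grid is None:
            raise ValueError("scan method needs an explicit D0 grid")
        D0s = np.asarray(D0_grid, dtype=float)
        for i, Ti in enumerate(T):
            mins = np.empty(D0s.shape)
            maxs = np.empty(D0s.shape)
            for j, d0 in enumerate(D0s):
                regimen = Regimen(kind=RegimenKind.Beq, D0=float(d0), T=float(Ti), M=math.inf)
                if params.model is Model.Mt:
                    mins[j], maxs[j] = tcm_steady_extrema(
                        params, float(Ti), float(d0), samples=samples
                    )
                else:
                    mins[j], maxs[j] = steady_extrema(params, regimen)
            f_lo[i] = D0s[np.argmin(np.abs(mins - rng.D_me))]
            f_hi[i] = D0s[np.argmin(np.abs(maxs - rng.D_MS))]
    else:
        raise ValueError("method must be 'linearity' or 'scan'")
    empty = ~(f_lo < f_hi)
    region = EDRR2D(
        T=T, f_lo=f_lo, f_hi=f_hi,
        meta={"model": params.model.value, "range": rng, "params": params,
              "method": method, "empty_mask": empty},
    )
    return region


def classify_regimen(
    params: PKParams, regimen: Regimen, rng: TherapeuticRange
) -> RegimenVerdict:
    """Compare the steady-state trough/peak of a regimen against the
    therapeutic range and return one of the four verdicts."""
    a_min, a_max = steady_extrema(params, regimen)
    over = a_max > rng.D_MS
    under = a_min < rng.D_me
    if over and under:
        v = Verdict.BOTH
    elif over:
        v = Verdict.UNSAFE
    elif under:
        v = Verdict.INEFFECTIVE
    else:
        v = Verdict.ACCEPTABLE
    return RegimenVerdict(verdict=v, steady_min=a_min, steady_max=a_max)
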