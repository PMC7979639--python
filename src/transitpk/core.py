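"""Domain types, validation and shared conventions.

Conventions used throughout the package:

* amounts in mg, times in hours, rates in 1/h; the bioavailability
  fraction ``F`` scales the dose entering the first modelled compartment
  (effective dose ``F * D0``);
* the Heaviside step is right-continuous, ``H(0) = 1``: a bolus given at
  ``t = jT`` is included at that instant, so the sampled value at a dose
  time is the post-dose level;
* an infinite number of doses is expressed as ``M = math.inf`` (or the
  string ``"infinite"`` in JSON configs) and is only meaningful to
  steady-state evaluators, never to finite-sum transient solvers.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Model",
    "RegimenKind",
    "PKParams",
    "Regimen",
    "TherapeuticRange",
    "TimeCourse",
    "SteadyStateProfile",
    "RateCoincidenceError",
    "RegimenShapeError",
    "RateOrderingWarning",
    "validate_params",
    "time_since_dose",
    "heaviside",
    "load_config",
]

#: default relative tolerance below which two first-order rate constants
#: are considered coincident (the closed forms divide by their difference)
RATE_COINCIDENCE_RTOL = 1e-6

#: numerical slack allowed on the non-negativity of drug levels
LEVEL_TOL = -1e-9


class Model(str, Enum):
    """Compartmental topology."""

    M1 = "M1"  #: one compartment, IV input straight to central
    M2 = "M2"  #: absorption -> central (oral dosing)
    Mt = "Mt"  #: n transit compartments -> absorption -> central


class RegimenKind(str, Enum):
    """Dosing regimen shape."""

    B1 = "B1"  #: single bolus at t=0
    Beq = "Beq"  #: equi-bolus: dose D0 every T hours
    BeqL = "BeqL"  #: equi-bolus with loading dose D_L at t=0
    Iinf = "Iinf"  #: single continuous infusion at rate k_in
    Ieq = "Ieq"  #: periodic infusion: on for t_f, off for T - t_f


class RateCoincidenceError(ValueError):
    """Two rate constants are equal (or nearly so) where the model
    requires them distinct."""


class RegimenShapeError(ValueError):
    """Regimen fields missing or inconsistent for the requested kind."""


class RateOrderingWarning(UserWarning):
    """Emitted when k_a < k_e (accepted, but outside the usual
    absorption-faster-than-elimination regime)."""


@dataclass(frozen=True)
class PKParams:
    """Rate constants and bioavailability for a chosen model topology.

    Parameters
    ----------
    model:
        Compartmental topology (:class:`Model` or its string value).
    k_e:
        First-order elimination rate constant from the central
        compartment (1/h).
    k_a:
        Absorption -> central transfer rate (1/h); required for M2/Mt.
    k:
        Transit rate constant, identical for every compartment of the
        transit cascade (1/h); required for Mt.
    n:
        Number of transit compartments (Mt only); the mean transit time
        of the cascade is ``MTT = n / k``.
    F:
        Bioavailability fraction in (0, 1].
    """

    model: Model
    k_e: float
    k_a: float | None = None
    k: float | None = None
    n: int | None = None
    F: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", Model(self.model))
        if not (self.k_e > 0):
            raise ValueError(f"k_e must be positive, got {self.k_e}")
        if not (0 < self.F <= 1):
            raise ValueError(f"F must be in (0, 1], got {self.F}")
        if self.model in (Model.M2, Model.Mt):
            if self.k_a is None or not (self.k_a > 0):
                raise ValueError("k_a must be positive for M2/Mt")
        if self.model is Model.Mt:
            if self.k is None or not (self.k > 0):
                raise ValueError("k must be positive for Mt")
            if self.n is None or int(self.n) != self.n or self.n < 1:
                raise ValueError("n must be a positive integer for Mt")
            object.__setattr__(self, "n", int(self.n))

    @property
    def mtt(self) -> float:
        """Mean transit time n/k of the transit cascade (Mt only)."""
        if self.model is not Model.Mt:
            raise AttributeError("MTT is defined only for the transit model")
        return self.n / self.k


@dataclass(frozen=True)
class Regimen:
    """Dosing regimen description.

    ``M`` may be ``math.inf`` to denote indefinitely repeated dosing,
    which is only accepted by steady-state evaluators.
    """

    kind: RegimenKind
    D0: float | None = None
    T: float | None = None
    M: float | None = None
    D_L: float | None = None
    k_in: float | None = None
    t_f: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", RegimenKind(self.kind))
        if self.M == "infinite":
            object.__setattr__(self, "M", math.inf)

    @property
    def is_infinite(self) -> bool:
        return self.M is not None and math.isinf(self.M)

    def dose_times(self, t_max: float | None = None) -> np.ndarray:
        """Bolus administration times, truncated to ``t_max`` if the
        regimen repeats indefinitely."""
        if self.kind is RegimenKind.B1:
            return np.array([0.0])
        if self.kind in (RegimenKind.Beq, RegimenKind.BeqL):
            if self.is_infinite:
                if t_max is None:
                    raise ValueError("t_max required for infinite regimens")
                m = int(math.floor(t_max / self.T)) + 1
            else:
                m = int(self.M)
            return np.arange(m) * self.T
        raise RegimenShapeError(f"{self.kind} has no bolus dose times")


@dataclass(frozen=True)
class TherapeuticRange:
    """Therapeutic window: minimum effective and maximum safe central
    drug levels (mg)."""

    D_me: float
    D_MS: float

    def __post_init__(self) -> None:
        if not (0 < self.D_me < self.D_MS):
            raise ValueError(
                f"require 0 < D_me < D_MS, got ({self.D_me}, {self.D_MS})"
            )


@dataclass
class TimeCourse:
    """Sampled drug-level trajectories for one or more compartments.

    ``levels`` maps compartment label (``"central"``, ``"absorption"``,
    ``"transit_1"`` ...) to an amount series aligned with ``t``.
    """

    t: np.ndarray
    levels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) < 0):
            raise ValueError("time samples must be non-decreasing")
        for name, series in self.levels.items():
            series = np.asarray(series, dtype=float)
            if series.shape != self.t.shape:
                raise ValueError(f"series {name!r} length mismatch")
            if np.any(series < LEVEL_TOL):
                raise ValueError(f"negative drug level in series {name!r}")
            self.levels[name] = series

    def __getitem__(self, label: str) -> np.ndarray:
        return self.levels[label]

    @property
    def central(self) -> np.ndarray:
        return self.levels["central"]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame with columns (t, compartment, amount)."""
        parts = [
            pd.DataFrame({"t": self.t, "compartment": name, "amount": series})
            for name, series in self.levels.items()
        ]
        return pd.concat(parts, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SteadyStateProfile:
    """One-period (T-periodic) steady-state solution.

    ``evaluator`` maps an array of within-interval times
    ``t_inf in [0, T)`` to a dict of per-compartment amounts;
    ``initial_values`` are the interval-start amounts, which the
    evaluator reproduces at ``t_inf = 0``.
    """

    T: float
    initial_values: dict[str, float]
    evaluator: Callable[[np.ndarray], dict[str, np.ndarray]]
    meta: dict = field(default_factory=dict)

    def __call__(self, t_inf) -> dict[str, np.ndarray]:
        t_inf = np.asarray(t_inf, dtype=float)
        if np.any(t_inf < 0) or np.any(t_inf >= self.T):
            raise ValueError("steady-state evaluator expects t_inf in [0, T)")
        return self.evaluator(t_inf)

    def central(self, t_inf) -> np.ndarray:
        return self(t_inf)["central"]

    def sample(self, num: int = 1000) -> TimeCourse:
        t = np.linspace(0.0, self.T, num, endpoint=False)
        return TimeCourse(t=t, levels=dict(self(t)), meta=dict(self.meta))

    def to_csv(self, path: str | Path, num: int = 1000) -> None:
        self.sample(num).to_csv(path)


def heaviside(x) -> np.ndarray:
    """Heaviside step with the dosing convention H(0) = 1.

    A bolus administered at ``t = jT`` is counted at that instant, so the
    value sampled at a dose time equals the post-dose level (consistent
    with the single-dose solution taking the value ``F*D0`` at t=0).
    """
    return np.where(np.asarray(x, dtype=float) >= 0.0, 1.0, 0.0)


def time_since_dose(t, j: int, T: float):
    """Time elapsed since the j-th dose (j >= 1), ``t_j = t - (j-1)T``.

    Negative values correspond to doses not yet given and are masked by
    the Heaviside factor in every solution formula.
    """
    if j < 1:
        raise ValueError("dose index j starts at 1")
    return np.asarray(t, dtype=float) - (j - 1) * T


def _check_distinct(rates: Mapping[str, float], rtol: float) -> None:
    names = list(rates)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra, rb = rates[a], rates[b]
            if abs(ra - rb) < rtol * max(abs(ra), abs(rb)):
                raise RateCoincidenceError(
                    f"{a} = {ra} and {b} = {rb} are closer than the "
                    f"relative tolerance {rtol}; the closed-form solutions "
                    "divide by their difference. Perturb one rate or use a "
                    "different model topology."
                )


def validate_params(
    params: PKParams,
    regimen: Regimen,
    rate_rtol: float = RATE_COINCIDENCE_RTOL,
) -> tuple[PKParams, Regimen]:
    """Validate a (parameters, regimen) pair and return it normalised.

    Raises
    ------
    RateCoincidenceError
        if any two of (k, k_a, k_e) needed by the model are closer than
        ``rate_rtol`` in relative terms.
    RegimenShapeError
        if regimen fields are missing or inconsistent for its kind.
    ValueError
        on nonpositive doses, intervals or rates.
    """
    if not isinstance(params, PKParams):
        params = PKParams(**params)
    if not isinstance(regimen, Regimen):
        regimen = Regimen(**regimen)

    if params.model is Model.M2:
        _check_distinct({"k_a": params.k_a, "k_e": params.k_e}, rate_rtol)
    elif params.model is Model.Mt:
        _check_distinct(
            {"k": params.k, "k_a": params.k_a, "k_e": params.k_e}, rate_rtol
        )
    if params.k_a is not None and params.k_a < params.k_e:
        warnings.warn(
            "k_a < k_e: absorption slower than elimination; solutions are "
            "valid but outside the usual ordering",
            RateOrderingWarning,
            stacklevel=2,
        )

    kind = regimen.kind
    if kind in (RegimenKind.B1, RegimenKind.Beq, RegimenKind.BeqL):
        if regimen.D0 is None or not (regimen.D0 > 0):
            raise RegimenShapeError(f"{kind} requires D0 > 0")
    if kind in (RegimenKind.Beq, RegimenKind.BeqL, RegimenKind.Ieq):
        if regimen.T is None or not (regimen.T > 0):
            raise RegimenShapeError(f"{kind} requires T > 0")
        if regimen.M is None:
            raise RegimenShapeError(f"{kind} requires M (or 'infinite')")
        if not regimen.is_infinite and (
            int(regimen.M) != regimen.M or regimen.M < 1
        ):
            raise RegimenShapeError("M must be a positive integer or infinite")
    if kind is RegimenKind.B1 and regimen.M not in (None, 1):
        raise RegimenShapeError("B1 is a single dose; M must be 1 or omitted")
    if kind is RegimenKind.BeqL:
        if regimen.D_L is None or regimen.D_L < regimen.D0:
            raise RegimenShapeError("BeqL requires a loading dose D_L >= D0")
    if kind in (RegimenKind.Iinf, RegimenKind.Ieq):
        if regimen.k_in is None or not (regimen.k_in > 0):
            raise RegimenShapeError(f"{kind} requires k_in > 0")
        if params.model is not Model.M1:
            raise RegimenShapeError("infusion regimens are defined for M1")
    if kind is RegimenKind.Ieq:
        if regimen.t_f is None or not (0 < regimen.t_f < regimen.T):
            raise RegimenShapeError("Ieq requires 0 < t_f < T")

    return params, regimen


# ---------------------------------------------------------------------------
# JSON configuration

_PARAM_KEYS = {"model", "k_e", "k_a", "k", "n", "F"}
_REGIMEN_KEYS = {"kind", "D0", "T", "M", "D_L", "k_in", "t_f"}
_RANGE_KEYS = {"D_me", "D_MS"}


def _strict(section: Mapping, allowed: set[str], name: str) -> dict:
    unknown = set(section) - allowed
    if unknown:
        raise KeyError(f"unknown key(s) {sorted(unknown)} in {name!r} section")
    return dict(section)


def load_config(
    source: str | Path | Mapping,
) -> tuple[PKParams, Regimen, TherapeuticRange | None]:
    """Load a validated (params, regimen[, therapeutic range]) triple from
    a JSON file, JSON string or mapping. Unknown keys are rejected."""
    if isinstance(source, Mapping):
        cfg = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        cfg = json.loads(text)
    unknown = set(cfg) - {"params", "regimen", "therapeutic_range"}
    if unknown:
        raise KeyError(f"unknown top-level key(s) {sorted(unknown)}")
    params = PKParams(**_strict(cfg["params"], _PARAM_KEYS, "params"))
    regimen = Regimen(**_strict(cfg["regimen"], _REGIMEN_KEYS, "regimen"))
    rng = None
    if "therapeutic_range" in cfg:
        rng = TherapeuticRange(
            **_strict(cfg["therapeutic_range"], _RANGE_KEYS, "therapeutic_range")
        )
    params, regimen = validate_params(params, regimen)
    return params, regimen, rng
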