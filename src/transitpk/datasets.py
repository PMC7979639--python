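"""Synthetic observation generators and catalogued worked-example
settings.

The single-dose glibenclamide time course used for model fitting in the
literature exists only as a digitised figure, so this module generates a
synthetic stand-in: the exact transit-model curve at the published
best-fit parameters (k = 12.76, k_a = 9.11, k_e = 0.96 1/h, F = 0.69,
n = 10, 3.5 mg dose), sampled densely early and sparsely late over
0-8 h, with mean-corrected multiplicative lognormal noise (drug amounts
are positive, so lognormal is the natural noise family; the correction
keeps the expected observation on the true curve).

``catalog_settings`` collects the named parameter/regimen/range sets
used by the examples and the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Model,
    PKParams,
    Regimen,
    RegimenKind,
    TherapeuticRange,
    validate_params,
)
from . import tcm

__all__ = [
    "SyntheticDataset",
    "make_glibenclamide_like",
    "catalog_settings",
    "GLIBENCLAMIDE_PARAMS",
]

#: published best-fit transit-model parameters for a 3.5 mg
#: glibenclamide dose (n = 10 cascade)
GLIBENCLAMIDE_PARAMS = PKParams(
    model=Model.Mt, k_e=0.96, k_a=9.11, k=12.76, n=10, F=0.69
)

#: sampling layout: dense through absorption/peak, sparse in the tail
_SAMPLE_TIMES = np.array(
    [0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, 8.0]
)


@dataclass
class SyntheticDataset:
    """Synthetic noisy observations with their generating truth."""

    params: PKParams
    regimen: Regimen
    t: np.ndarray
    observations: np.ndarray
    truth: np.ndarray
    noise_cv: float
    seed: int
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "value": self.observations})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def read_observations(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
        df = pd.read_csv(path)
        return df["t"].to_numpy(), df["value"].to_numpy()


def make_glibenclamide_like(
    seed: int, noise_cv: float = 0.05, sample_times=None
) -> SyntheticDataset:
    """Synthetic single-dose dataset emulating a glibenclamide
    concentration-time course (converted to amounts).

    Observations are the exact n = 10 transit-model central level for a
    single 3.5 mg oral dose, multiplied by mean-corrected lognormal
    noise with coefficient of variation ``noise_cv`` (0 gives the exact
    curve).  The same seed reproduces the dataset bit-identically.
    """
    params = GLIBENCLAMIDE_PARAMS
    regimen = Regimen(kind=RegimenKind.B1, D0=3.5)
    t = np.asarray(_SAMPLE_TIMES if sample_times is None else sample_times, float)
    truth = tcm.central_level(params, regimen, t)
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = math.sqrt(math.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=t.shape)
    else:
        noise = np.ones_like(t)
    return SyntheticDataset(
        params=params,
        regimen=regimen,
        t=t,
        observations=truth * noise,
        truth=truth,
        noise_cv=noise_cv,
        seed=seed,
        meta={"dose_mg": 3.5},
    )


def _settings() -> dict[str, dict]:
    hypo_iv = dict(model=Model.M1, k_e=0.0692, F=1.0)
    hypo_oral = dict(model=Model.M2, k_e=0.0692, k_a=0.7, F=1.0)
    return {
        # hypothetical-drug IV bolus course: 500 mg every 12 h,
        # optionally with an 800 mg loading dose
        "iv_bolus_demo": {
            "params": PKParams(**hypo_iv),
            "regimen": Regimen(kind=RegimenKind.Beq, D0=500.0, T=12.0, M=10),
            "loading": Regimen(
                kind=RegimenKind.BeqL, D0=500.0, T=12.0, M=10, D_L=800.0
            ),
            "k_in": 500.0 / 12.0,
        },
        # matched periodic infusion: 41.67 mg/h on for 3 h of every 6 h
        "iv_infusion_demo": {
            "params": PKParams(**hypo_iv),
            "regimen": Regimen(
                kind=RegimenKind.Ieq, k_in=41.67, t_f=3.0, T=6.0, M=20
            ),
        },
        # rapid IV bolus train approximating a continuous infusion
        "iv_bolus_rapid": {
            "params": PKParams(**hypo_iv),
            "regimen": Regimen(kind=RegimenKind.Beq, D0=20.83, T=0.5, M=200),
            "k_in": 41.67,
        },
        # oral two-compartment course with the same schedule
        "oral_bolus_demo": {
            "params": PKParams(**hypo_oral),
            "regimen": Regimen(kind=RegimenKind.Beq, D0=500.0, T=12.0, M=10),
            "loading": Regimen(
                kind=RegimenKind.BeqL, D0=500.0, T=12.0, M=10, D_L=800.0
            ),
        },
        # long transit cascade: single 500 mg dose, 3 h mean transit time
        "transit_single_dose_demo": {
            "params": PKParams(
                model=Model.Mt, k_e=0.0692, k_a=0.7, k=100 / 3.0, n=100, F=1.0
            ),
            "regimen": Regimen(kind=RegimenKind.B1, D0=500.0),
            "t_lag": 3.0,
        },
        # glibenclamide-like single dose (fitting target)
        "glibenclamide_tcm": {
            "params": GLIBENCLAMIDE_PARAMS,
            "regimen": Regimen(kind=RegimenKind.B1, D0=3.5),
        },
        # the same drug under 3-hourly repeat dosing
        "glibenclamide_multidose": {
            "params": GLIBENCLAMIDE_PARAMS,
            "regimen": Regimen(kind=RegimenKind.Beq, D0=3.5, T=3.0, M=8),
        },
        # second-individual fit of the same study (simulation only)
        "glibenclamide_tcm_alt": {
            "params": PKParams(
                model=Model.Mt, k_e=0.48, k_a=0.87, k=17.59, n=10, F=0.37
            ),
            "regimen": Regimen(kind=RegimenKind.Beq, D0=3.5, T=3.0, M=8),
        },
        # exact-vs-Stirling comparison setting (fixed MTT = 0.78 h)
        "stirling_comparison": {
            "params": PKParams(
                model=Model.Mt, k_e=0.96, k_a=9.11, k=2 / 0.78, n=2, F=0.69
            ),
            "regimen": Regimen(kind=RegimenKind.B1, D0=3.5),
            "mtt": 0.78,
        },
        # multi-dose transit demo: n = 10, MTT = 3 h, 500 mg every 8 h
        "transit_multidose_demo": {
            "params": PKParams(
                model=Model.Mt, k_e=0.0692, k_a=0.7, k=10 / 3.0, n=10, F=1.0
            ),
            "regimen": Regimen(kind=RegimenKind.Beq, D0=500.0, T=8.0, M=6),
        },
        # IV therapeutic-window study (regimen-region petal)
        "iv_therapeutic_window": {
            "params": PKParams(**hypo_iv),
            "range": TherapeuticRange(D_me=300.0, D_MS=1000.0),
        },
        # oral therapeutic-window study
        "oral_therapeutic_window": {
            "params": PKParams(**hypo_oral),
            "range": TherapeuticRange(D_me=300.0, D_MS=1000.0),
        },
        # transit-model regimen regions at fixed MTT = 4.4 h / fixed k
        "transit_edrr_demo": {
            "params": PKParams(**hypo_oral),
            "range": TherapeuticRange(D_me=300.0, D_MS=1000.0),
            "mtt": 4.4,
            "k_fixed": 0.45,
        },
        # infusion therapeutic-window study
        "infusion_therapeutic_window": {
            "params": PKParams(model=Model.M1, k_e=0.2, F=1.0),
            "range": TherapeuticRange(D_me=200.0, D_MS=3000.0),
        },
    }


def catalog_settings(name: str | None = None):
    """Named worked-example parameter/regimen/range sets.

    With no argument, returns the full dict; with a name, returns that
    setting or raises ``KeyError`` listing the available names.
    """
    table = _settings()
    if name is None:
        return table
    try:
        return table[name]
    except KeyError:
        raise KeyError(
            f"unknown setting {name!r}; available: {sorted(table)}"
        ) from None
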