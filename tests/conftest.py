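import warnings

import numpy as np
import pytest

from transitpk import PKParams, Regimen, TherapeuticRange
from transitpk.core import RateOrderingWarning


@pytest.fixture(autouse=True)
def _quiet_rate_ordering():
    # several tests deliberately exercise the k_a < k_e regime
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RateOrderingWarning)
        yield


@pytest.fixture
def hypo_iv_params():
    """Hypothetical-drug one-compartment parameters used throughout the
    worked examples (slow elimination, half-life ~10 h)."""
    return PKParams(model="M1", k_e=0.0692, F=1.0)


@pytest.fixture
def hypo_oral_params():
    return PKParams(model="M2", k_e=0.0692, k_a=0.7, F=1.0)


@pytest.fixture
def tcm_multidose_params():
    """n = 10 cascade, 3 h mean transit time."""
    return PKParams(model="Mt", k_e=0.0692, k_a=0.7, k=10 / 3.0, n=10, F=1.0)


@pytest.fixture
def therapeutic_window():
    return TherapeuticRange(D_me=300.0, D_MS=1000.0)


@pytest.fixture
def beq_500_12(n_doses=10):
    return Regimen(kind="Beq", D0=500.0, T=12.0, M=10)
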