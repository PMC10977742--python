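import numpy as np
import pytest

from obediab.params import BASELINE_KEYS, HR_GROUPS, ParameterSet, reference_parameters
from obediab.segments import CovariateProfile

#: log-rate that underflows exp() to exactly 0.0 — switches a transition off
OFF = -800.0


@pytest.fixture(scope="session")
def ref_params() -> ParameterSet:
    return reference_parameters()


@pytest.fixture(scope="session")
def reference_profile() -> CovariateProfile:
    """The covariate reference cell: male, >= 50, before 1995, onset active."""
    return CovariateProfile(
        sex="M", age_class="ge50", period="pre1995",
        dm_active_nw=True, dm_active_owob=True, dm_age_lt50=False,
    )


def params_with(**rates: float) -> ParameterSet:
    """Parameter set with the given per-year baselines, all others off, HRs 1."""
    log_baseline = {k: OFF for k in BASELINE_KEYS}
    for k, v in rates.items():
        log_baseline[k] = float(np.log(v))
    return ParameterSet(
        log_baseline=log_baseline,
        log_hr={g: {c: 0.0 for c in covs} for g, covs in HR_GROUPS.items()},
    )


@pytest.fixture(scope="session")
def two_state_params() -> ParameterSet:
    """Only NW<->OW moves: a = 0.048 up, b = 0.027 down; everything else off."""
    return params_with(nw_ow=0.048, ow_nw=0.027)


@pytest.fixture(scope="session")
def silent_params() -> ParameterSet:
    """Every transition switched off: the chain never leaves NW non-diabetic."""
    return params_with()


def two_state_closed_form(a: float, b: float, t: float) -> float:
    """P(OW at t | NW at 0) for the two-state chain with constant rates a, b."""
    return a / (a + b) * (1.0 - np.exp(-(a + b) * t))
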