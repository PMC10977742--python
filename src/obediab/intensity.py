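"""Construction of the 10-state generator (transition-intensity) matrix.

For a fully resolved covariate profile every allowed off-diagonal entry is
``exp(log-baseline + sum of applicable log-hazard-ratios)``; the diagonal
makes rows sum to zero.  Diabetes-onset entries are exactly zero on segments
where onset is not yet activated (before age 40 in normal weight, before 25
otherwise).  BMI-transition entries are identical in the diabetic and
non-diabetic layers.

``up_mult`` / ``down_mult`` scale the move-up (NW->OW and the three
progressions) and move-down (all four regressions) intensities; they realize
public-health scenarios and default to 1.
"""

from __future__ import annotations

import numpy as np

from .params import ParameterSet
from .segments import CovariateProfile
from .states import N_BMI, N_LIVING

#: diabetes-onset baseline key per BMI-class index
_DM_KEYS = ("dm_nw", "dm_ow", "dm_ob1", "dm_ob23", "dm_ob23")


def _covariate_log_hr(params: ParameterSet, group: str, profile: CovariateProfile) -> float:
    """Sum of log-hazard-ratios applying to one BMI-transition group."""
    hr = params.log_hr[group]
    total = 0.0
    if profile.sex == "F":
        total += hr["female"]
    if profile.period == "p1995_2004":
        total += hr["p1995_2004"]
    elif profile.period == "p2005_2014":
        total += hr["p2005_2014"]
    if profile.age_class == "lt25":
        total += hr["age_lt25"]
    elif profile.age_class == "a25_49":
        total += hr["age_25_49"]
    return total


def _dm_log_hr(params: ParameterSet, profile: CovariateProfile) -> float:
    hr = params.log_hr["dm"]
    total = 0.0
    if profile.sex == "F":
        total += hr["female"]
    if profile.period == "p1995_2004":
        total += hr["p1995_2004"]
    elif profile.period == "p2005_2014":
        total += hr["p2005_2014"]
    if profile.dm_age_lt50:
        total += hr["age_lt50"]
    return total


def build_intensity_matrix(
    params: ParameterSet,
    profile: CovariateProfile,
    up_mult: float = 1.0,
    down_mult: float = 1.0,
) -> np.ndarray:
    """Return the 10x10 generator Q (per-year intensities) for one profile."""
    if up_mult < 0 or down_mult < 0:
        raise ValueError("scenario multipliers must be non-negative")
    Q = np.zeros((N_LIVING, N_LIVING))

    q_up = np.empty(N_BMI - 1)
    q_up[0] = np.exp(params.log_baseline["nw_ow"] + _covariate_log_hr(params, "nw_ow", profile))
    q_up[1:] = np.exp(params.log_baseline["prog"] + _covariate_log_hr(params, "prog", profile))
    q_up *= up_mult

    regr_hr = _covariate_log_hr(params, "regr", profile)
    q_down = np.empty(N_BMI - 1)  # q_down[b-1] is the b -> b-1 intensity
    q_down[0] = np.exp(params.log_baseline["ow_nw"] + regr_hr)
    q_down[1:] = np.exp(params.log_baseline["regr"] + regr_hr)
    q_down *= down_mult

    # BMI transitions, identical in both diabetes layers
    for layer in (0, N_BMI):
        for b in range(N_BMI - 1):
            Q[layer + b, layer + b + 1] = q_up[b]
            Q[layer + b + 1, layer + b] = q_down[b]

    # diabetes onset, gated by the activation ages
    dm_hr = _dm_log_hr(params, profile)
    for b in range(N_BMI):
        active = profile.dm_active_nw if b == 0 else profile.dm_active_owob
        if active:
            Q[b, b + N_BMI] = np.exp(params.log_baseline[_DM_KEYS[b]] + dm_hr)

    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q
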