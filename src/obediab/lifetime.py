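"""Lifetime cumulative risk of type 2 diabetes under competing mortality.

The chain is augmented to 12 states: the 10 living states plus death split
into "died never diabetic" and "died after diabetes onset".  Starting from
a living non-diabetic state at a given age and calendar year, the
distribution is stepped annually to the horizon (age 110); the lifetime
risk is the terminal mass of the diabetic living states plus
died-after-diabetes — the probability of *ever* developing the disease
before death.  Calendar-period effects are frozen at their last estimated
level for future years, and scenarios modify the BMI intensities exactly
as in the population projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .intensity import build_intensity_matrix
from .params import ParameterSet
from .projection import MortalityAdjustment, ScenarioSpec
from .segments import DEFAULT_CONFIG, CovariateProfile, ModelConfig
from .simulate import lifetable_lookup
from .states import N_BMI, N_LIVING, HealthState

DEAD_NONDM = N_LIVING      # died without ever developing diabetes
DEAD_DM = N_LIVING + 1     # died after diabetes onset
_N_AUG = N_LIVING + 2


@dataclass
class LifetimeRiskResult:
    """Lifetime diabetes risk for one starting profile."""

    sex: str
    start_age: int
    start_state: str
    scenario: ScenarioSpec
    risk: float
    cumulative_incidence: pd.Series  # by age, monotone non-decreasing

    def __post_init__(self) -> None:
        assert 0.0 <= self.risk <= 1.0 + 1e-12


def _augmented_step(
    params: ParameterSet,
    profile: CovariateProfile,
    qx: float,
    mort_adj: MortalityAdjustment,
    up_mult: float,
    down_mult: float,
    constrain_bmi: bool,
) -> np.ndarray:
    Q = np.zeros((_N_AUG, _N_AUG))
    core = build_intensity_matrix(params, profile, up_mult, down_mult)
    if constrain_bmi:
        # freeze the BMI dimension: keep only diabetes-onset intensities
        frozen = np.zeros_like(core)
        for b in range(N_BMI):
            frozen[b, b + N_BMI] = core[b, b + N_BMI]
        np.fill_diagonal(frozen, -frozen.sum(axis=1))
        core = frozen
    Q[:N_LIVING, :N_LIVING] = core
    mu = -np.log1p(-qx)
    for s in range(N_LIVING):
        dest = DEAD_DM if s >= N_BMI else DEAD_NONDM
        m = mu * mort_adj.hazard_ratios[s]
        Q[s, dest] += m
        Q[s, s] -= m
    return Q


def lifetime_risk(
    params: ParameterSet,
    life_table: pd.DataFrame,
    sex: str,
    start_state: str | HealthState = "NW",
    start_age: int = 25,
    start_year: int = 2022,
    scenario: ScenarioSpec | None = None,
    mort_adj: MortalityAdjustment | None = None,
    constrain_bmi: bool = False,
    config: ModelConfig = DEFAULT_CONFIG,
) -> LifetimeRiskResult:
    """Probability of developing type 2 diabetes before death.

    ``start_state`` must be a living non-diabetic state (the risk is
    conditional on being alive and disease-free at ``start_age``).
    ``constrain_bmi=True`` freezes the BMI category for life — the
    "remaining in normal weight" variant when starting from NW.
    """
    if isinstance(start_state, HealthState):
        state = start_state
    else:
        state = HealthState.from_label(str(start_state), False)
    if state.diabetic:
        raise ValueError("lifetime risk is defined for non-diabetic starting states")
    scenario = scenario or ScenarioSpec.status_quo(start_year)
    mort_adj = mort_adj or MortalityAdjustment()
    qx = lifetable_lookup(life_table)

    dist = np.zeros(_N_AUG)
    dist[state.index] = 1.0
    horizon = int(config.horizon_age)
    ages = []
    cuminc = []
    for age in range(int(start_age), horizon):
        year = start_year + (age - start_age)
        profile = CovariateProfile.at(sex, float(age), float(year), config)
        up, down = scenario.multipliers(year)
        Q = _augmented_step(
            params, profile, qx(age, year, sex), mort_adj, up, down, constrain_bmi
        )
        dist = dist @ scipy.linalg.expm(Q)
        ages.append(age + 1)
        cuminc.append(dist[N_BMI:N_LIVING].sum() + dist[DEAD_DM])

    curve = pd.Series(cuminc, index=pd.Index(ages, name="age"), name="cumulative_incidence")
    return LifetimeRiskResult(
        sex=sex,
        start_age=int(start_age),
        start_state=state.bmi_class,
        scenario=scenario,
        risk=float(curve.iloc[-1]),
        cumulative_incidence=curve,
    )


def population_lifetime_risk(
    params: ParameterSet,
    life_table: pd.DataFrame,
    sex: str,
    start_distribution: dict[str, float],
    start_age: int = 25,
    start_year: int = 2022,
    scenario: ScenarioSpec | None = None,
    mort_adj: MortalityAdjustment | None = None,
    config: ModelConfig = DEFAULT_CONFIG,
) -> float:
    """Lifetime risk of a cohort mixed over starting BMI categories.

    ``start_distribution`` maps BMI classes to weights summing to one
    (tolerance 1e-6); the result is the weighted mean of the per-state
    lifetime risks.
    """
    total = sum(start_distribution.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"start distribution sums to {total}, expected 1")
    risk = 0.0
    for bmi_class, w in start_distribution.items():
        if w == 0.0:
            continue
        r = lifetime_risk(
            params, life_table, sex, bmi_class, start_age, start_year,
            scenario, mort_adj, config=config,
        )
        risk += w * r.risk
    return float(risk)
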