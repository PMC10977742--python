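"""Birth-cohort projection with competing mortality, and intervention scenarios.

Every birth cohort (by default from 1895 onward) starts at age 3 entirely
normal-weight and non-diabetic and is pushed forward in annual steps through
an 11-state generator: the 10 living states plus an absorbing death state.
The death intensity from living state ``s`` at age ``a`` in year ``y`` is
``-ln(1 - qx(a, y, sex)) * HR(s)`` where ``qx`` comes from a life table and
``HR`` is a configurable state-specific all-cause-mortality hazard ratio
(1 everywhere by default).  Population prevalences are cohort-size-weighted
aggregates over the living, by default among adults (age >= 18).

Scenarios scale the BMI intensities from a start year: a "move-up" factor
``delta`` multiplies the four upward intensities by ``1 - delta`` and a
"move-down" factor ``gamma`` multiplies the four downward intensities by
``1 + gamma``.  Diabetes-onset and death intensities are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import scipy.linalg

from .intensity import build_intensity_matrix
from .params import ParameterSet
from .segments import DEFAULT_CONFIG, CovariateProfile, ModelConfig
from .simulate import lifetable_lookup
from .states import N_BMI, N_LIVING, STATE_LABELS

DEATH = N_LIVING  # index of the absorbing death state


@dataclass(frozen=True)
class MortalityAdjustment:
    """State-specific all-cause-mortality hazard ratios vs NW non-diabetic.

    The excess mortality of overweight, obesity and diabetes enters the
    projection as multiplicative hazard ratios on the life-table hazard.
    Defaults are 1 (no excess) and are meant to be overridden from
    configuration when external estimates are available.
    """

    hazard_ratios: tuple[float, ...] = (1.0,) * N_LIVING

    def __post_init__(self) -> None:
        if len(self.hazard_ratios) != N_LIVING:
            raise ValueError(f"need {N_LIVING} hazard ratios")
        if any(h <= 0 for h in self.hazard_ratios):
            raise ValueError("mortality hazard ratios must be positive")
        if self.hazard_ratios[0] != 1.0:
            raise ValueError("the NW non-diabetic reference hazard ratio must be 1")

    @classmethod
    def from_mapping(cls, hrs: dict[str, float]) -> "MortalityAdjustment":
        vals = [float(hrs.get(lab, 1.0)) for lab in STATE_LABELS]
        return cls(hazard_ratios=tuple(vals))


@dataclass(frozen=True)
class ScenarioSpec:
    """Multiplicative intervention on BMI transition intensities.

    ``up_factor`` (delta, in [0, 1]) is the fractional *decrease* of all
    move-up intensities; ``down_factor`` (gamma, >= 0) the fractional
    *increase* of all move-down intensities; both apply from ``start_year``.
    """

    up_factor: float = 0.0
    down_factor: float = 0.0
    start_year: int = 2022
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.up_factor <= 1.0:
            raise ValueError("up_factor must lie in [0, 1] (rates cannot turn negative)")
        if self.down_factor < 0.0:
            raise ValueError("down_factor must be non-negative")

    def multipliers(self, year: float) -> tuple[float, float]:
        """(up_mult, down_mult) applying in calendar year ``year``."""
        if year >= self.start_year:
            return 1.0 - self.up_factor, 1.0 + self.down_factor
        return 1.0, 1.0

    @classmethod
    def status_quo(cls, start_year: int = 2022) -> "ScenarioSpec":
        return cls(0.0, 0.0, start_year, "status quo")

    @classmethod
    def scenario1(cls, start_year: int = 2022) -> "ScenarioSpec":
        """22% decrease in the probability of moving up one BMI class."""
        return cls(0.22, 0.0, start_year, "scenario 1")

    @classmethod
    def scenario2(cls, start_year: int = 2022) -> "ScenarioSpec":
        """33% increase in the probability of moving down one BMI class."""
        return cls(0.0, 0.33, start_year, "scenario 2")

    @classmethod
    def scenario3(cls, start_year: int = 2022) -> "ScenarioSpec":
        """Scenarios 1 and 2 combined."""
        return cls(0.22, 0.33, start_year, "scenario 3")


def apply_scenario(Q: np.ndarray, spec: ScenarioSpec, year: float) -> np.ndarray:
    """Return ``Q`` with the scenario multipliers applied to its BMI entries.

    Up entries (b -> b+1 in both diabetes layers) are scaled by
    ``1 - delta``, down entries by ``1 + gamma``; diabetes-onset entries and
    anything else are untouched.  The diagonal is rebuilt.
    """
    up, down = spec.multipliers(year)
    out = Q.copy()
    np.fill_diagonal(out, 0.0)
    for layer in (0, N_BMI):
        for b in range(N_BMI - 1):
            out[layer + b, layer + b + 1] *= up
            out[layer + b + 1, layer + b] *= down
    np.fill_diagonal(out, -out.sum(axis=1))
    return out


def _augmented_generator(
    params: ParameterSet,
    profile: CovariateProfile,
    qx: float,
    mort_adj: MortalityAdjustment,
    up_mult: float,
    down_mult: float,
) -> np.ndarray:
    """11x11 generator: living states plus absorbing death."""
    if not 0.0 <= qx < 1.0:
        raise ValueError(f"annual death probability out of range: {qx}")
    Q = np.zeros((N_LIVING + 1, N_LIVING + 1))
    Q[:N_LIVING, :N_LIVING] = build_intensity_matrix(params, profile, up_mult, down_mult)
    mu = -np.log1p(-qx)
    for s in range(N_LIVING):
        m = mu * mort_adj.hazard_ratios[s]
        Q[s, DEATH] = m
        Q[s, s] -= m
    return Q


class CohortProjector:
    """Annual-step forward projection of one or many birth cohorts.

    Caches the one-year transition matrices, which depend only on
    (sex, covariate profile, qx, scenario multipliers) — a small set when
    the life table varies slowly.
    """

    def __init__(
        self,
        params: ParameterSet,
        life_table: pd.DataFrame,
        mort_adj: MortalityAdjustment | None = None,
        config: ModelConfig = DEFAULT_CONFIG,
    ):
        self.params = params
        self.qx = lifetable_lookup(life_table)
        self.mort_adj = mort_adj or MortalityAdjustment()
        self.config = config
        self._cache: dict[tuple, np.ndarray] = {}

    def step_matrix(self, sex: str, age: int, year: int, scenario: ScenarioSpec) -> np.ndarray:
        profile = CovariateProfile.at(sex, float(age), float(year), self.config)
        qx = self.qx(age, year, sex)
        up, down = scenario.multipliers(year)
        key = (sex, profile, round(qx, 12), up, down)
        P = self._cache.get(key)
        if P is None:
            Q = _augmented_generator(self.params, profile, qx, self.mort_adj, up, down)
            P = scipy.linalg.expm(Q)
            self._cache[key] = P
        return P

    def cohort_distribution(
        self,
        sex: str,
        birth_year: int,
        through_year: int,
        scenario: ScenarioSpec,
        callback: Callable[[int, int, np.ndarray], None] | None = None,
    ) -> np.ndarray:
        """11-vector of state shares at the end of ``through_year``.

        Starts the cohort at age 3 (all mass in NW non-diabetic) and steps
        one year at a time; ``callback(year, age, dist)`` is invoked after
        each step, with the distribution holding at the *end* of ``year``
        (age ``year - birth_year``).
        """
        dist = np.zeros(N_LIVING + 1)
        dist[0] = 1.0
        start_age = int(self.config.start_age)
        for age in range(start_age, through_year - birth_year):
            year = birth_year + age
            dist = dist @ self.step_matrix(sex, age, year, scenario)
            if callback is not None:
                callback(year + 1, age + 1, dist)
        return dist


def project_cohorts(
    params: ParameterSet,
    life_table: pd.DataFrame,
    cohort_sizes: pd.DataFrame,
    years: tuple[int, int],
    scenario: ScenarioSpec | None = None,
    mort_adj: MortalityAdjustment | None = None,
    first_cohort: int = 1895,
    min_age: int = 18,
    config: ModelConfig = DEFAULT_CONFIG,
    by_sex: bool = False,
) -> pd.DataFrame:
    """Population prevalence trajectories over ``years`` (inclusive).

    All cohorts born from ``first_cohort`` are projected with background
    mortality; prevalences are shares of the living population aged
    ``>= min_age``.  Output: one row per calendar year with the five BMI
    class shares, overall obesity (classes I-III) and diabetes.  BMI shares
    sum to 1 among the living.
    """
    scenario = scenario or ScenarioSpec.status_quo()
    projector = CohortProjector(params, life_table, mort_adj, config)
    sizes = {
        (r.sex, int(r.year)): float(r.size) for r in cohort_sizes.itertuples(index=False)
    }
    y0, y1 = years
    report_years = range(y0, y1 + 1)
    acc: dict[int, np.ndarray] = {y: np.zeros(N_LIVING) for y in report_years}

    last_cohort = y1 - min_age
    for sex in ("M", "F"):
        for by in range(first_cohort, last_cohort + 1):
            size = sizes.get((sex, by))
            if size is None:
                raise KeyError(f"no cohort size for sex={sex}, year={by}")

            def tally(year: int, age: int, dist: np.ndarray, _s=size) -> None:
                if y0 <= year <= y1 and age >= min_age:
                    acc[year] += _s * dist[:N_LIVING]

            projector.cohort_distribution(sex, by, y1, scenario, callback=tally)

    rows = []
    for y in report_years:
        living = acc[y]
        tot = living.sum()
        share = living / tot if tot > 0 else np.zeros(N_LIVING)
        bmi = share[:N_BMI] + share[N_BMI:]
        rows.append(
            {
                "year": y,
                "nw": bmi[0],
                "ow": bmi[1],
                "ob1": bmi[2],
                "ob2": bmi[3],
                "ob3": bmi[4],
                "obesity": bmi[2:].sum(),
                "diabetes": share[N_BMI:].sum(),
                "living": tot,
            }
        )
    out = pd.DataFrame(rows).set_index("year")
    if by_sex:
        raise NotImplementedError("per-sex output: project each sex separately")
    return out


# ---------------------------------------------------------------------------
# required-change search


@dataclass
class RequiredChangeResult:
    """Outcome of the search for the intervention magnitude meeting a target."""

    direction: str
    value: float
    attained: bool
    target_prevalence: float
    achieved_prevalence: float


def find_required_change(
    params: ParameterSet,
    life_table: pd.DataFrame,
    cohort_sizes: pd.DataFrame,
    objective: str | tuple[str, float] = "stabilize",
    direction: str = "up",
    start_year: int = 2022,
    end_year: int = 2027,
    mort_adj: MortalityAdjustment | None = None,
    first_cohort: int = 1895,
    min_age: int = 18,
    config: ModelConfig = DEFAULT_CONFIG,
    prevalence_tol: float = 1e-3,
    max_down: float = 4.0,
) -> RequiredChangeResult:
    """Smallest scenario factor meeting an obesity-prevalence objective.

    ``objective="stabilize"`` targets the ``start_year`` obesity prevalence
    at ``end_year``; ``("relative_reduction", r)`` targets ``(1 - r)`` times
    the *status quo* ``end_year`` prevalence.  ``direction`` picks the
    lever: "up" searches the move-up decrease delta in [0, 1], "down" the
    move-down increase gamma in [0, max_down].  The prevalence map is
    monotone in either factor, so bisection applies; an unattainable
    objective returns the boundary with ``attained=False``.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")

    def prevalence(delta: float, gamma: float) -> float:
        spec = ScenarioSpec(delta, gamma, start_year)
        series = project_cohorts(
            params, life_table, cohort_sizes, (start_year, end_year), spec,
            mort_adj, first_cohort, min_age, config,
        )
        return float(series.loc[end_year, "obesity"])

    status_quo = project_cohorts(
        params, life_table, cohort_sizes, (start_year, end_year),
        ScenarioSpec.status_quo(start_year), mort_adj, first_cohort, min_age, config,
    )
    if objective == "stabilize":
        target = float(status_quo.loc[start_year, "obesity"])
    else:
        kind, r = objective
        if kind != "relative_reduction":
            raise ValueError(f"unknown objective {objective!r}")
        target = (1.0 - r) * float(status_quo.loc[end_year, "obesity"])

    lo, hi = (0.0, 1.0) if direction == "up" else (0.0, max_down)

    def f(x: float) -> float:
        d, g = (x, 0.0) if direction == "up" else (0.0, x)
        return prevalence(d, g) - target

    f_lo = f(lo)
    if f_lo <= 0:
        return RequiredChangeResult(direction, lo, True, target, f_lo + target)
    f_hi = f(hi)
    if f_hi > 0:
        return RequiredChangeResult(direction, hi, False, target, f_hi + target)

    while True:
        mid = (lo + hi) / 2.0
        f_mid = f(mid)
        if abs(f_mid) < prevalence_tol or hi - lo < 1e-4:
            return RequiredChangeResult(direction, mid, True, target, f_mid + target)
        if f_mid > 0:
            lo = mid
        else:
            hi = mid


def scenario_grid(
    params: ParameterSet,
    life_table: pd.DataFrame,
    cohort_sizes: pd.DataFrame,
    deltas: np.ndarray,
    gammas: np.ndarray,
    start_year: int = 2022,
    end_year: int = 2027,
    mort_adj: MortalityAdjustment | None = None,
    first_cohort: int = 1895,
    min_age: int = 18,
    config: ModelConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """End-year obesity prevalence surface over (delta, gamma).

    One row per grid cell with the achieved prevalence and its relative
    reduction under both conventions: versus the status-quo ``end_year``
    prevalence and versus the ``start_year`` level.
    """
    rows = []
    ref = None
    for d in deltas:
        for g in gammas:
            series = project_cohorts(
                params, life_table, cohort_sizes, (start_year, end_year),
                ScenarioSpec(float(d), float(g), start_year),
                mort_adj, first_cohort, min_age, config,
            )
            prev = float(series.loc[end_year, "obesity"])
            base = float(series.loc[start_year, "obesity"])
            if d == deltas[0] and g == gammas[0] and d == 0 and g == 0:
                ref = prev
            rows.append(
                {"delta": float(d), "gamma": float(g), "obesity_end": prev, "obesity_start": base}
            )
    out = pd.DataFrame(rows)
    if ref is None:  # status quo not on the grid: compute it
        sq = project_cohorts(
            params, life_table, cohort_sizes, (start_year, end_year),
            ScenarioSpec.status_quo(start_year), mort_adj, first_cohort, min_age, config,
        )
        ref = float(sq.loc[end_year, "obesity"])
    out["reduction_vs_statusquo"] = 1.0 - out["obesity_end"] / ref
    out["reduction_vs_start"] = 1.0 - out["obesity_end"] / out["obesity_start"]
    return out
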