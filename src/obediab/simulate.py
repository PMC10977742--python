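"""Synthetic survey panels, life tables and cohort sizes.

The French survey microdata behind this model are access-restricted, so
every stage of the pipeline is exercised against synthetic stand-ins drawn
from the model itself: exact (Gillespie-style) simulation of the
continuous-time chain with piecewise-constant intensities, survey-like
sampling of one observation per individual across biennial waves, a
Gompertz life table and smooth birth-cohort sizes.

Defaults emulate the survey structure the model was built for: nine waves
1998-2014, respondents aged 15-90 with mean age ~44.7 (SD ~18.7), 51.5%
men, everyone normal-weight and non-diabetic at age 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intensity import build_intensity_matrix
from .params import ParameterSet, reference_parameters
from .segments import DEFAULT_CONFIG, ModelConfig, make_segments
from .states import N_BMI, N_LIVING, STATES

# ---------------------------------------------------------------------------
# exact trajectory simulation


def simulate_trajectory(
    params: ParameterSet,
    sex: str,
    birth_year: int,
    end_age: float,
    rng: np.random.Generator,
    config: ModelConfig = DEFAULT_CONFIG,
) -> list[tuple[float, int]]:
    """Exact simulation of one life course from age 3 to ``end_age``.

    Within each constant-covariate segment the chain leaves state ``i``
    after an Exp(-Q[i,i]) holding time and jumps to ``j`` with probability
    proportional to ``Q[i,j]`` — competing exponential clocks for the
    allowed moves (BMI one step up/down, diabetes onset).

    Returns the event list ``[(age, state_index), ...]`` starting with
    ``(3.0, 0)`` (normal weight, non-diabetic); diabetes never reverts.
    """
    events = [(config.start_age, 0)]
    state = 0
    for seg in make_segments(birth_year, sex, end_age=end_age, config=config):
        Q = build_intensity_matrix(params, seg.profile)
        t = seg.start_age
        while True:
            rate = -Q[state, state]
            if rate <= 0.0:
                break
            t = t + rng.exponential(1.0 / rate)
            if t >= seg.end_age:
                break
            probs = Q[state].clip(min=0.0)
            probs[state] = 0.0
            state = int(rng.choice(N_LIVING, p=probs / probs.sum()))
            events.append((t, state))
    return events


def state_at(events: list[tuple[float, int]], age: float) -> int:
    """State occupied at ``age`` given a trajectory event list."""
    state = events[0][1]
    for t, s in events:
        if t <= age:
            state = s
        else:
            break
    return state


def simulate_states_at_ages(
    params: ParameterSet,
    sex: str,
    birth_year: int,
    target_ages: np.ndarray,
    rng: np.random.Generator,
    config: ModelConfig = DEFAULT_CONFIG,
    up_mult: float = 1.0,
    down_mult: float = 1.0,
) -> np.ndarray:
    """Vectorized exact simulation of many individuals of one sex and cohort.

    Returns the state index of each individual at its own ``target_ages``
    entry.  Statistically identical to :func:`simulate_trajectory`, but
    simulates the whole batch in parallel with numpy, which makes
    survey-scale generation and Monte-Carlo oracle runs cheap.
    """
    target_ages = np.asarray(target_ages, dtype=float)
    n = target_ages.size
    state = np.zeros(n, dtype=np.int64)
    if n == 0:
        return state
    t = np.full(n, config.start_age)
    max_age = float(target_ages.max())
    for seg in make_segments(birth_year, sex, end_age=max_age, config=config):
        Q = build_intensity_matrix(params, seg.profile, up_mult, down_mult)
        rates = -np.diag(Q)  # exit rate per state
        # cumulative jump distribution per state
        J = Q.clip(min=0.0)
        np.fill_diagonal(J, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Jc = np.cumsum(J, axis=1) / J.sum(axis=1, keepdims=True)
        seg_end = np.minimum(seg.end_age, target_ages)
        active = t < seg_end
        while active.any():
            idx = np.flatnonzero(active)
            r = rates[state[idx]]
            dt = np.full(idx.size, np.inf)
            pos = r > 0
            dt[pos] = rng.exponential(1.0 / r[pos])
            t_new = t[idx] + dt
            jumped = t_new < seg_end[idx]
            t[idx] = np.where(jumped, t_new, seg_end[idx])
            ji = idx[jumped]
            if ji.size:
                u = rng.random(ji.size)
                state[ji] = (Jc[state[ji]] > u[:, None]).argmax(axis=1)
            active[idx] = jumped
    return state


# ---------------------------------------------------------------------------
# survey-panel generation


@dataclass
class SyntheticConfig:
    """Design of a synthetic survey panel.

    ``age_mean``/``age_sd`` parameterize a normal age-at-survey
    distribution truncated to ``age_range``; ages and birth years are
    integers, as in survey files.  ``misdeclared_diabetes_rate`` injects
    the survey artifact of under-40 normal-weight respondents declaring
    (type 1 / genetic) diabetes, which the cleaning step must undo.
    """

    n_individuals: int = 10_000
    survey_years: tuple[int, ...] = tuple(range(1998, 2015, 2))
    age_range: tuple[int, int] = (15, 90)
    age_mean: float = 44.7
    age_sd: float = 18.7
    male_fraction: float = 0.515
    params: ParameterSet = field(default_factory=reference_parameters)
    seed: int = 0
    mortality_thinning: bool = False
    life_table: pd.DataFrame | None = None
    misdeclared_diabetes_rate: float = 0.0
    model_config: ModelConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    def __post_init__(self) -> None:
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be a probability")
        if not 0 <= self.misdeclared_diabetes_rate <= 1:
            raise ValueError("misdeclared_diabetes_rate must be a probability")
        if self.age_range[0] < self.model_config.start_age:
            raise ValueError("survey ages must lie at or beyond the simulation origin")
        if self.mortality_thinning and self.life_table is None:
            raise ValueError("mortality_thinning requires a life_table")


def _draw_design(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_individuals
    sex = np.where(rng.random(n) < config.male_fraction, "M", "F")
    survey_year = rng.choice(config.survey_years, size=n)
    lo, hi = config.age_range
    age = np.empty(n)
    todo = np.arange(n)
    while todo.size:  # truncated-normal ages by rejection
        draw = rng.normal(config.age_mean, config.age_sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        age[todo[ok]] = draw[ok]
        todo = todo[~ok]
    age = np.floor(age).astype(int)
    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "sex": sex,
            "birth_year": survey_year - age,
            "survey_year": survey_year,
        }
    )


def generate_panel(
    config: SyntheticConfig,
    return_trajectories: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[int, list[tuple[float, int]]]]:
    """Generate a survey-like panel: one observed state per individual.

    Each individual gets a sex, a survey wave and an integer age at survey
    (hence a birth year), then an exact simulation of the chain from age 3
    determines the state recorded at the survey.  Identical configs produce
    byte-identical output.  With ``return_trajectories=True`` the full
    (hidden) event lists are returned alongside, keyed by ``person_id``.

    With ``mortality_thinning`` individuals who would have died before
    their survey age (background mortality from ``config.life_table``,
    no state dependence) are redrawn, mimicking survivor-only sampling.
    """
    rng = np.random.default_rng(config.seed)
    design = _draw_design(config, rng)

    if config.mortality_thinning:
        design = _thin_by_mortality(design, config, rng)

    states = np.zeros(len(design), dtype=np.int64)
    trajectories: dict[int, list[tuple[float, int]]] = {}
    if return_trajectories:
        for i, row in enumerate(design.itertuples(index=False)):
            ev = simulate_trajectory(
                config.params, row.sex, int(row.birth_year),
                float(row.survey_year - row.birth_year), rng, config.model_config,
            )
            trajectories[int(row.person_id)] = ev
            states[i] = state_at(ev, float(row.survey_year - row.birth_year))
    else:
        groups = design.groupby(["sex", "birth_year"], sort=True).indices
        for (sex, by), idx in groups.items():
            ages = (design["survey_year"].to_numpy()[idx] - by).astype(float)
            states[idx] = simulate_states_at_ages(
                config.params, sex, int(by), ages, rng, config.model_config
            )

    out = design.copy()
    out["bmi_class"] = [STATES[s].bmi_class for s in states]
    out["diabetes"] = (states >= N_BMI).astype(int)

    if config.misdeclared_diabetes_rate > 0:
        age = out["survey_year"] - out["birth_year"]
        eligible = (out["bmi_class"] == "NW") & (out["diabetes"] == 0) & (age < 40)
        flip = eligible & (rng.random(len(out)) < config.misdeclared_diabetes_rate)
        out.loc[flip, "diabetes"] = 1

    if return_trajectories:
        return out, trajectories
    return out


def _thin_by_mortality(
    design: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    lt = lifetable_lookup(config.life_table)
    design = design.copy()
    for i, row in enumerate(design.itertuples(index=False)):
        while True:
            ages = np.arange(0, int(row.survey_year - row.birth_year))
            years = int(row.birth_year) + ages
            qx = np.array([lt(a, y, row.sex) for a, y in zip(ages, years)])
            if rng.random() < np.prod(1.0 - qx):
                break
            repl = _draw_design(
                SyntheticConfig(
                    n_individuals=1,
                    survey_years=config.survey_years,
                    age_range=config.age_range,
                    age_mean=config.age_mean,
                    age_sd=config.age_sd,
                    male_fraction=config.male_fraction,
                    params=config.params,
                ),
                rng,
            ).iloc[0]
            row = row._replace(
                sex=repl["sex"],
                birth_year=int(repl["birth_year"]),
                survey_year=int(repl["survey_year"]),
            )
        design.iloc[i, design.columns.get_loc("sex")] = row.sex
        design.iloc[i, design.columns.get_loc("birth_year")] = row.birth_year
        design.iloc[i, design.columns.get_loc("survey_year")] = row.survey_year
    return design


# ---------------------------------------------------------------------------
# life tables and cohort sizes


def make_synthetic_lifetable(
    alpha: float = 2e-5,
    beta: float = 0.095,
    years: tuple[int, int] = (1895, 2030),
    max_age: int = 110,
    sex_multiplier: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Gompertz life table: ``qx = 1 - exp(-m_sex * alpha * e^(beta*age))``.

    A deliberately simple stand-in for national mortality tables: constant
    over calendar years, log-linear in age, with a small male excess.
    Columns: ``age, year, sex, qx``.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("Gompertz shape parameters must be non-negative")
    sex_multiplier = sex_multiplier or {"M": 1.2, "F": 0.85}
    ages = np.arange(0, max_age + 1)
    yrs = np.arange(years[0], years[1] + 1)
    frames = []
    for sex, m in sex_multiplier.items():
        qx = 1.0 - np.exp(-m * alpha * np.exp(beta * ages))
        grid = pd.MultiIndex.from_product([ages, yrs], names=["age", "year"]).to_frame(
            index=False
        )
        grid["sex"] = sex
        grid["qx"] = np.repeat(qx, yrs.size)
        frames.append(grid)
    return pd.concat(frames, ignore_index=True)[["age", "year", "sex", "qx"]]


def lifetable_lookup(life_table: pd.DataFrame):
    """Fast ``(age, year, sex) -> qx`` accessor with explicit coverage errors.

    Calendar years beyond the table reuse its last year; ages beyond the
    table reuse the last available hazard (open age interval).
    """
    tab = {}
    for r in life_table.itertuples(index=False):
        tab[(int(r.age), int(r.year), r.sex)] = float(r.qx)
    max_year = int(life_table["year"].max())
    min_year = int(life_table["year"].min())
    max_age = int(life_table["age"].max())

    def qx(age: int, year: int, sex: str) -> float:
        a = min(int(age), max_age)
        y = min(max(int(year), min_year), max_year)
        try:
            return tab[(a, y, sex)]
        except KeyError:
            raise KeyError(
                f"life table does not cover age={age}, year={year}, sex={sex}"
            ) from None

    return qx


def life_expectancy(life_table: pd.DataFrame, sex: str = "F", year: int | None = None) -> float:
    """Period life expectancy at birth implied by the table (trapezoid-free sum)."""
    sub = life_table[life_table["sex"] == sex]
    if year is None:
        year = int(sub["year"].min())
    sub = sub[sub["year"] == year].sort_values("age")
    surv = np.cumprod(1.0 - sub["qx"].to_numpy())
    return float(surv.sum() + 0.5)


def make_cohort_sizes(
    years: tuple[int, int] = (1895, 2030),
    base: float = 800_000.0,
    male_fraction: float = 0.512,
) -> pd.DataFrame:
    """Smooth synthetic annual birth-cohort sizes by sex.

    Births rise from ~75% of ``base`` in the first year to ``base`` by 1950
    and stay flat after — a stand-in for national natality tables.
    Columns: ``year, sex, size``.
    """
    yrs = np.arange(years[0], years[1] + 1)
    ramp = np.clip((yrs - years[0]) / max(1950 - years[0], 1), 0.0, 1.0)
    total = base * (0.75 + 0.25 * ramp)
    rows = []
    for y, tot in zip(yrs, total):
        rows.append({"year": int(y), "sex": "M", "size": tot * male_fraction})
        rows.append({"year": int(y), "sex": "F", "size": tot * (1 - male_fraction)})
    return pd.DataFrame(rows)
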