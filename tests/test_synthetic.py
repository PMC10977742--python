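"""Synthetic-data generator: trajectories, panels, life tables, cohorts."""

import numpy as np
import pandas as pd
import pytest

from obediab.model import transition_probability
from obediab.simulate import (
    SyntheticConfig,
    generate_panel,
    life_expectancy,
    make_cohort_sizes,
    make_synthetic_lifetable,
    simulate_states_at_ages,
    simulate_trajectory,
    state_at,
)

from conftest import two_state_closed_form, params_with


class TestTrajectories:
    def test_silent_chain_never_moves(self, silent_params):
        rng = np.random.default_rng(0)
        ev = simulate_trajectory(silent_params, "F", 1950, 100, rng)
        assert ev == [(3.0, 0)]

    def test_two_state_empirical_frequency(self, two_state_params):
        rng = np.random.default_rng(12)
        n, t = 20_000, 10.0
        hits = 0
        for _ in range(n):
            ev = simulate_trajectory(two_state_params, "M", 2000, 3 + t, rng)
            hits += state_at(ev, 3 + t) == 1
        p = two_state_closed_form(0.048, 0.027, t)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_diabetes_never_reverts_and_moves_are_adjacent(self, ref_params):
        rng = np.random.default_rng(5)
        for _ in range(200):
            ev = simulate_trajectory(ref_params, "F", 1950, 80, rng)
            states = [s for _, s in ev]
            for a, b in zip(states[:-1], states[1:]):
                assert (a >= 5) <= (b >= 5)  # onset is one-way
                assert abs(b % 5 - a % 5) <= 1  # BMI moves one class at a time
            ages = [t for t, _ in ev]
            assert ages == sorted(ages)

    def test_vectorized_simulator_matches_expm(self, ref_params):
        rng = np.random.default_rng(2)
        n = 100_000
        states = simulate_states_at_ages(ref_params, "F", 1975, np.full(n, 45.0), rng)
        freq = np.bincount(states, minlength=10) / n
        row = transition_probability(ref_params, 1975, "F", 3, 45)[0]
        se = np.sqrt(row * (1 - row) / n)
        assert np.all(np.abs(freq - row) <= 3.5 * se + 1e-12)


class TestPanels:
    def test_empty_panel(self):
        panel = generate_panel(SyntheticConfig(n_individuals=0))
        assert len(panel) == 0
        assert set(panel.columns) >= {"sex", "birth_year", "survey_year",
                                      "bmi_class", "diabetes"}

    def test_determinism_same_seed(self):
        a = generate_panel(SyntheticConfig(n_individuals=500, seed=99))
        b = generate_panel(SyntheticConfig(n_individuals=500, seed=99))
        pd.testing.assert_frame_equal(a, b)
        c = generate_panel(SyntheticConfig(n_individuals=500, seed=100))
        assert not a.equals(c)

    def test_survey_design_respected(self):
        cfg = SyntheticConfig(n_individuals=4000, seed=1)
        panel = generate_panel(cfg)
        age = panel.survey_year - panel.birth_year
        assert age.between(*cfg.age_range).all()
        assert panel.survey_year.isin(cfg.survey_years).all()
        assert abs((panel.sex == "M").mean() - 0.515) < 0.03
        assert abs(age.mean() - 44.7) < 1.5

    def test_diabetes_below_overweight_prevalence(self):
        panel = generate_panel(SyntheticConfig(n_individuals=10_000, seed=42))
        assert 0 < panel.diabetes.mean() < (panel.bmi_class != "NW").mean()

    def test_trajectories_consistent_with_records(self, ref_params):
        cfg = SyntheticConfig(n_individuals=50, seed=8)
        panel, trajs = generate_panel(cfg, return_trajectories=True)
        assert set(trajs) == set(panel.person_id)
        for row in panel.itertuples(index=False):
            s = state_at(trajs[row.person_id], row.survey_year - row.birth_year)
            assert (s >= 5) == bool(row.diabetes)

    def test_misdeclared_diabetes_artifact(self):
        cfg = SyntheticConfig(n_individuals=5000, seed=4, misdeclared_diabetes_rate=0.2)
        raw = generate_panel(cfg)
        young_nw = raw[(raw.bmi_class == "NW")
                       & (raw.survey_year - raw.birth_year < 40)]
        assert young_nw.diabetes.mean() > 0.05  # artifact present for cleaning to undo

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(age_range=(1, 90))
        with pytest.raises(ValueError):
            SyntheticConfig(male_fraction=1.4)
        with pytest.raises(ValueError):
            SyntheticConfig(mortality_thinning=True)


class TestLifeTablesAndCohorts:
    def test_gompertz_lifetable_properties(self):
        lt = make_synthetic_lifetable(years=(2000, 2005))
        assert lt.qx.between(0, 1).all()
        for sex in "MF":
            sub = lt[(lt.sex == sex) & (lt.year == 2000)].sort_values("age")
            q = sub.qx.to_numpy()
            assert np.all(np.diff(q[30:]) > 0)  # monotone beyond 30
            e0 = life_expectancy(lt, sex=sex, year=2000)
            assert 70 < e0 < 90

    def test_zero_alpha_is_immortal(self):
        lt = make_synthetic_lifetable(alpha=0.0, years=(2000, 2001))
        assert (lt.qx == 0).all()

    def test_negative_shape_rejected(self):
        with pytest.raises(ValueError):
            make_synthetic_lifetable(alpha=-1e-5)

    def test_cohort_sizes_cover_years_positive(self):
        sizes = make_cohort_sizes(years=(1895, 2030))
        assert set(sizes.year) == set(range(1895, 2031))
        assert (sizes["size"] > 0).all()
        assert set(sizes.sex) == {"M", "F"}
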