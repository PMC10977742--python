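"""Cohort projection, scenarios and the required-change search."""

import numpy as np
import pytest

from obediab.intensity import build_intensity_matrix
from obediab.projection import (
    CohortProjector,
    MortalityAdjustment,
    RequiredChangeResult,
    ScenarioSpec,
    apply_scenario,
    find_required_change,
    project_cohorts,
    scenario_grid,
)
from obediab.simulate import make_cohort_sizes, make_synthetic_lifetable

from conftest import params_with


def immortal_table(y0=1930, y1=2030):
    return make_synthetic_lifetable(alpha=0.0, years=(y0, y1))


@pytest.fixture(scope="module")
def small_world(ref_params):
    """A reduced population: cohorts from 1960, projection to 2026."""
    life = make_synthetic_lifetable(years=(1960, 2030))
    sizes = make_cohort_sizes(years=(1960, 2030))
    return ref_params, life, sizes


class TestScenarioSpec:
    def test_canonical_scenarios(self):
        assert (ScenarioSpec.status_quo().up_factor, ScenarioSpec.status_quo().down_factor) == (0, 0)
        assert ScenarioSpec.scenario1().up_factor == 0.22
        assert ScenarioSpec.scenario2().down_factor == 0.33
        s3 = ScenarioSpec.scenario3()
        assert (s3.up_factor, s3.down_factor) == (0.22, 0.33)

    def test_multipliers_switch_on_at_start_year(self):
        s = ScenarioSpec(0.22, 0.33, start_year=2022)
        assert s.multipliers(2021) == (1.0, 1.0)
        assert s.multipliers(2022) == (0.78, 1.33)

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(up_factor=1.2)
        with pytest.raises(ValueError):
            ScenarioSpec(down_factor=-0.1)


class TestApplyScenario:
    def test_identity_and_boundary(self, ref_params, reference_profile):
        Q = build_intensity_matrix(ref_params, reference_profile)
        same = apply_scenario(Q, ScenarioSpec.status_quo(), 2025)
        assert np.array_equal(same, Q)
        allup0 = apply_scenario(Q, ScenarioSpec(up_factor=1.0), 2025)
        for layer in (0, 5):
            for b in range(4):
                assert allup0[layer + b, layer + b + 1] == 0.0

    def test_published_factor_scales_up_entries(self, ref_params, reference_profile):
        Q = build_intensity_matrix(ref_params, reference_profile)
        s1 = apply_scenario(Q, ScenarioSpec.scenario1(), 2025)
        for layer in (0, 5):
            for b in range(4):
                assert s1[layer + b, layer + b + 1] == pytest.approx(0.78 * Q[layer + b, layer + b + 1])
                assert s1[layer + b + 1, layer + b] == Q[layer + b + 1, layer + b]
        assert s1[3, 8] == Q[3, 8]  # onset untouched
        assert np.abs(s1.sum(axis=1)).max() < 1e-12


class TestProjection:
    def test_frozen_population_constant(self, silent_params):
        series = project_cohorts(
            silent_params, immortal_table(), make_cohort_sizes(years=(1930, 2030)),
            years=(2020, 2025), first_cohort=1960,
        )
        assert (series.nw == 1.0).all()
        assert (series.obesity == 0.0).all()
        assert (series.diabetes == 0.0).all()

    def test_single_cohort_one_year_step_closed_form(self):
        params = params_with(nw_ow=0.05)
        proj = CohortProjector(params, immortal_table())
        dist = proj.cohort_distribution("M", 2000, 2004, ScenarioSpec.status_quo())
        # one year of exposure at constant rate 0.05, no return flow
        assert dist[1] == pytest.approx(1 - np.exp(-0.05), rel=1e-10)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mass_conservation_with_mortality(self, small_world):
        params, life, sizes = small_world
        proj = CohortProjector(params, life)
        dist = proj.cohort_distribution("F", 1960, 2026, ScenarioSpec.scenario3())
        assert dist.sum() == pytest.approx(1.0, abs=1e-10)
        assert dist[-1] > 0  # some mortality accumulated

    def test_bmi_shares_sum_to_one_among_living(self, small_world):
        params, life, sizes = small_world
        series = project_cohorts(params, life, sizes, (2022, 2026), first_cohort=1960)
        total = series[["nw", "ow", "ob1", "ob2", "ob3"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-10)
        assert ((series.obesity > 0) & (series.obesity < 1)).all()

    def test_missing_lifetable_cell_raises(self, ref_params):
        males_only = make_synthetic_lifetable(years=(2000, 2030),
                                              sex_multiplier={"M": 1.2})
        proj = CohortProjector(ref_params, males_only)
        with pytest.raises(KeyError, match="life table"):
            proj.cohort_distribution("F", 1990, 2010, ScenarioSpec.status_quo())

    def test_obesity_monotone_in_both_levers(self, small_world):
        params, life, sizes = small_world
        kw = dict(years=(2022, 2026), first_cohort=1960)
        base = project_cohorts(params, life, sizes, scenario=ScenarioSpec.status_quo(), **kw)
        for spec in (ScenarioSpec(up_factor=0.3), ScenarioSpec(down_factor=0.4),
                     ScenarioSpec(0.3, 0.4)):
            alt = project_cohorts(params, life, sizes, scenario=spec, **kw)
            assert alt.loc[2026, "obesity"] < base.loc[2026, "obesity"]
            assert alt.loc[2022, "obesity"] == pytest.approx(base.loc[2022, "obesity"])

    def test_up_lever_beats_down_lever_at_equal_strength(self, small_world):
        """Decreasing move-up is the stronger strategy than increasing move-down."""
        params, life, sizes = small_world
        kw = dict(years=(2022, 2026), first_cohort=1960)
        up = project_cohorts(params, life, sizes, scenario=ScenarioSpec(up_factor=0.25), **kw)
        down = project_cohorts(params, life, sizes, scenario=ScenarioSpec(down_factor=0.25), **kw)
        assert up.loc[2026, "obesity"] < down.loc[2026, "obesity"]

    def test_higher_diabetic_mortality_lowers_diabetes_prevalence(self, small_world):
        params, life, sizes = small_world
        kw = dict(years=(2022, 2026), first_cohort=1960)
        hrs = {"NW-D": 2.0, "OW-D": 2.0, "OB1-D": 2.0, "OB2-D": 2.0, "OB3-D": 2.0}
        base = project_cohorts(params, life, sizes, **kw)
        harsh = project_cohorts(params, life, sizes,
                                mort_adj=MortalityAdjustment.from_mapping(hrs), **kw)
        assert harsh.loc[2026, "diabetes"] < base.loc[2026, "diabetes"]

    def test_mortality_adjustment_validation(self):
        with pytest.raises(ValueError):
            MortalityAdjustment(hazard_ratios=(2.0,) * 10)  # reference must stay 1
        with pytest.raises(ValueError):
            MortalityAdjustment(hazard_ratios=(1.0,) * 9 + (-1.0,))


class TestRequiredChange:
    def test_objective_already_met_returns_zero(self, small_world):
        params, life, sizes = small_world
        res = find_required_change(
            params, life, sizes, objective=("relative_reduction", 0.0),
            direction="up", start_year=2022, end_year=2025, first_cohort=1960,
        )
        assert isinstance(res, RequiredChangeResult)
        assert res.value == 0.0 and res.attained

    def test_bisection_matches_grid_scan(self, small_world):
        params, life, sizes = small_world
        kw = dict(start_year=2022, end_year=2025, first_cohort=1960)
        res = find_required_change(params, life, sizes, objective="stabilize",
                                   direction="up", prevalence_tol=1e-5, **kw)
        assert res.attained and 0 < res.value < 1
        grid = np.linspace(0, 1, 101)
        prevs = [
            project_cohorts(params, life, sizes, (2022, 2025),
                            ScenarioSpec(float(d), 0.0, 2022), first_cohort=1960
                            ).loc[2025, "obesity"]
            for d in grid
        ]
        best = grid[np.argmin(np.abs(np.asarray(prevs) - res.target_prevalence))]
        assert abs(res.value - best) <= 0.011  # within one grid step

    def test_unattainable_objective_reports_boundary(self, small_world):
        params, life, sizes = small_world
        res = find_required_change(
            params, life, sizes, objective=("relative_reduction", 0.95),
            direction="up", start_year=2022, end_year=2024, first_cohort=1960,
        )
        assert not res.attained and res.value == 1.0

    def test_grid_surface_monotone_in_both_factors(self, small_world):
        params, life, sizes = small_world
        deltas = np.array([0.0, 0.2, 0.4])
        gammas = np.array([0.0, 0.3])
        surf = scenario_grid(params, life, sizes, deltas, gammas,
                             start_year=2022, end_year=2025, first_cohort=1960)
        assert len(surf) == 6
        wide = surf.pivot(index="delta", columns="gamma", values="obesity_end")
        assert (wide.diff().dropna() < 0).all().all()       # decreasing in delta
        assert (wide.T.diff().dropna() < 0).all().all()     # decreasing in gamma
        assert (surf.loc[surf.delta + surf.gamma > 0, "reduction_vs_statusquo"] > 0).all()
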