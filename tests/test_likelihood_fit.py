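"""Panel likelihood and maximum-likelihood fitting."""

import logging

import numpy as np
import pandas as pd
import pytest

from obediab.model import BmiDiabetesPanelModel
from obediab.params import PARAM_NAMES
from obediab.simulate import SyntheticConfig, generate_panel

from conftest import two_state_closed_form

logging.getLogger("obediab").setLevel(logging.ERROR)


def record(sex="M", birth_year=1980, survey_year=2010, bmi_class="NW", diabetes=0):
    return {"person_id": 0, "sex": sex, "birth_year": birth_year,
            "survey_year": survey_year, "bmi_class": bmi_class, "diabetes": diabetes}


def test_certain_observation_has_zero_loglik(silent_params):
    """All intensities off: staying NW non-diabetic has probability one."""
    m = BmiDiabetesPanelModel(pd.DataFrame([record()]))
    assert m.loglike(silent_params) == pytest.approx(0.0, abs=1e-12)


def test_two_state_record_matches_closed_form(two_state_params):
    m = BmiDiabetesPanelModel(pd.DataFrame([record(birth_year=2000, survey_year=2013,
                                                   bmi_class="OW")]))
    expected = np.log(two_state_closed_form(0.048, 0.027, 10.0))
    assert m.loglike(two_state_params) == pytest.approx(expected, abs=1e-9)


def test_loglik_invariant_to_permutation_and_additive(ref_params):
    panel = generate_panel(SyntheticConfig(n_individuals=300, seed=3))
    m = BmiDiabetesPanelModel(panel)
    m_shuffled = BmiDiabetesPanelModel(panel.sample(frac=1, random_state=0))
    ll = m.loglike(ref_params)
    assert m_shuffled.loglike(ref_params) == pytest.approx(ll, rel=1e-12)
    doubled = BmiDiabetesPanelModel(pd.concat([panel, panel], ignore_index=True))
    assert doubled.loglike(ref_params) == pytest.approx(2 * ll, rel=1e-12)


def test_impossible_observation_flags_minus_inf(two_state_params):
    """Diabetes observed while onset is structurally impossible -> -inf, flagged."""
    m = BmiDiabetesPanelModel(pd.DataFrame([
        record(bmi_class="OW"),
        record(bmi_class="OW", diabetes=1),
    ]))
    assert m.loglike(two_state_params) == -np.inf
    flagged = m.zero_probability_groups_
    assert len(flagged) == 1 and flagged.iloc[0]["birth_year"] == 1980


def test_doubling_the_sample_halves_variances(ref_params):
    """Observed information is additive: duplicated records -> SEs / sqrt(2)."""
    panel = generate_panel(SyntheticConfig(n_individuals=400, seed=11))
    m1 = BmiDiabetesPanelModel(panel)
    m2 = BmiDiabetesPanelModel(pd.concat([panel, panel], ignore_index=True))
    v = ref_params.pack()
    H1 = m1.hessian_numeric(v)
    H2 = m2.hessian_numeric(v)
    assert np.allclose(H2, 2 * H1, rtol=1e-4, atol=1e-4)


def test_fit_recovers_generating_truth_within_ci(ref_params):
    """A medium-sized synthetic fit covers the generating intensity for NW->OW."""
    panel = generate_panel(SyntheticConfig(n_individuals=3000, seed=5))
    res = BmiDiabetesPanelModel(panel).fit()
    assert res.converged
    # the MLE cannot fall below the truth in likelihood
    assert res.llf >= res.model.loglike(ref_params) - 1e-3
    tab = res.parameter_table()
    truth = np.exp(ref_params.pack())
    named = dict(zip(PARAM_NAMES, truth))
    row = tab.loc["q_nw_ow"]
    assert row.ci_low <= named["q_nw_ow"] <= row.ci_high
    # CIs contain their point estimates wherever defined
    ok = tab.dropna()
    assert ((ok.ci_low <= ok.estimate) & (ok.estimate <= ok.ci_high)).all()
    cov = res.cov_params_log
    assert np.allclose(cov, cov.T)
    assert res.summary().startswith("BMI / type 2 diabetes")


def test_uninformative_diabetes_parameters_are_flagged(silent_params, ref_params):
    """Pre-40 normal-weight-only data carry no information on diabetes onset."""
    rng = np.random.default_rng(0)
    rows = [record(birth_year=by, survey_year=sy)
            for by, sy in zip(rng.integers(1975, 1990, 150),
                              rng.integers(1998, 2015, 150))
            if sy - by < 40 and sy - by >= 15]
    res = BmiDiabetesPanelModel(pd.DataFrame(rows)).fit(maxiter=150)
    assert any(name.startswith(("q_dm", "hr_dm")) for name in res.nonidentifiable)


def test_goodness_of_fit_tables(ref_params):
    panel = generate_panel(SyntheticConfig(n_individuals=4000, seed=9))
    model = BmiDiabetesPanelModel(panel)
    # evaluate at the generating truth: predictions should track observations
    from obediab.model import goodness_of_fit

    tables = goodness_of_fit(model, ref_params)
    for name, tab in tables.items():
        pred_cols = [c for c in tab.columns if c.startswith("pred_")]
        assert ((tab[pred_cols] >= 0) & (tab[pred_cols] <= 1)).all().all(), name
        assert (tab["n"] > 0).all()
    by_year = tables["by_year"]
    assert abs(by_year["obs_obesity"] - by_year["pred_obesity"]).max() < 0.08
    assert abs(by_year["obs_diabetes"] - by_year["pred_diabetes"]).max() < 0.05
    # diabetes prevalence rises with BMI category in both columns
    dbb = tables["diabetes_by_bmi"]
    assert dbb["pred_diabetes"].is_monotonic_increasing
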