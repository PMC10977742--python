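"""End-to-end pipeline: simulate -> clean -> fit -> project -> lifetime risk.

Driven by one configuration mapping and one top-level seed; per-stage seeds
are spawned deterministically, every artifact carries a provenance header
(package version, seed, config digest), and any stage failure aborts with
the stage name.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as oio
from .lifetime import lifetime_risk, population_lifetime_risk
from .model import BmiDiabetesPanelModel
from .params import ParameterSet, reference_parameters
from .plotting import plot_goodness_of_fit, plot_lifetime_risk, plot_prevalence_trajectories
from .projection import MortalityAdjustment, ScenarioSpec, project_cohorts, scenario_grid
from .published import start_distribution
from .simulate import SyntheticConfig, generate_panel, make_cohort_sizes, make_synthetic_lifetable

logger = logging.getLogger(__name__)

DEFAULT_PIPELINE_CONFIG: dict = {
    "synthetic": {"n_individuals": 2000},
    "fit": {"maxiter": 500},
    "projection": {"years": [2022, 2027], "first_cohort": 1935, "scenarios": "all"},
    "scenario_grid": {"deltas": [0.0, 0.11, 0.22], "gammas": [0.0, 0.165, 0.33]},
    "lifetime_risk": {"start_age": 25, "start_year": 2022},
    "mortality_hazard_ratios": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def run_pipeline(config: dict | None, out_dir: str | Path, seed: int = 0) -> dict:
    """Run every stage on synthetic data and write all artifacts to ``out_dir``.

    Returns a mapping of artifact names to paths.  Deterministic for a
    given (config, seed).
    """
    cfg = _merge(DEFAULT_PIPELINE_CONFIG, config or {})
    digest = oio.config_digest(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(("simulate", "fit"), ss.spawn(2))
    }
    artifacts: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        oio.write_csv(df, path, seed=seed, digest=digest, index=index)
        artifacts[name] = path

    stage = "simulate"
    try:
        syn = SyntheticConfig(seed=stage_seeds["simulate"],
                              misdeclared_diabetes_rate=0.001,
                              **cfg["synthetic"])
        raw = generate_panel(syn)
        _write("panel_raw.csv", raw)

        stage = "clean"
        clean, audit, rejects = oio.clean_records(raw)
        _write("panel_clean.csv", clean)
        if len(rejects):
            _write("rejects.csv", rejects)
        pd.Series(audit.as_dict()).to_json(out / "cleaning_audit.json")
        artifacts["cleaning_audit.json"] = out / "cleaning_audit.json"

        stage = "fit"
        model = BmiDiabetesPanelModel.from_dataframe(clean)
        res = model.fit(maxiter=cfg["fit"]["maxiter"])
        _write("parameter_table.csv", res.parameter_table(), index=True)
        (out / "fit_summary.txt").write_text(res.summary() + "\n")
        artifacts["fit_summary.txt"] = out / "fit_summary.txt"
        gof = res.goodness_of_fit()
        for name, tab in gof.items():
            _write(f"gof_{name}.csv", tab, index=True)
        axes = plot_goodness_of_fit(gof)
        axes[0].figure.savefig(out / "gof.png", dpi=120, bbox_inches="tight")
        plt.close("all")
        artifacts["gof.png"] = out / "gof.png"

        stage = "project"
        params = res.params
        pj = cfg["projection"]
        years = tuple(pj["years"])
        life = make_synthetic_lifetable(years=(pj["first_cohort"], years[1] + 1))
        cohorts = make_cohort_sizes(years=(pj["first_cohort"], years[1] + 1))
        mort = MortalityAdjustment.from_mapping(cfg["mortality_hazard_ratios"])
        scen_list = [ScenarioSpec.status_quo(), ScenarioSpec.scenario1(),
                     ScenarioSpec.scenario2(), ScenarioSpec.scenario3()]
        series = {}
        for sc in scen_list:
            series[sc.name] = project_cohorts(
                params, life, cohorts, years, sc, mort,
                first_cohort=pj["first_cohort"],
            )
            _write(f"prevalence_{sc.name.replace(' ', '_')}.csv", series[sc.name], index=True)
        ax = plot_prevalence_trajectories(series)
        ax.figure.savefig(out / "prevalence.png", dpi=120, bbox_inches="tight")
        plt.close("all")
        artifacts["prevalence.png"] = out / "prevalence.png"

        stage = "scenario-grid"
        gcfg = cfg["scenario_grid"]
        grid = scenario_grid(
            params, life, cohorts,
            np.asarray(gcfg["deltas"], float), np.asarray(gcfg["gammas"], float),
            start_year=years[0], end_year=years[1], mort_adj=mort,
            first_cohort=pj["first_cohort"],
        )
        _write("scenario_grid.csv", grid)

        stage = "lifetime-risk"
        lcfg = cfg["lifetime_risk"]
        risks: dict[str, dict[str, float]] = {}
        rows = []
        for sex in ("M", "F"):
            risks[sex] = {}
            for sc in scen_list:
                risks[sex][sc.name] = population_lifetime_risk(
                    params, life, sex, start_distribution(sex),
                    start_age=lcfg["start_age"], start_year=lcfg["start_year"],
                    scenario=sc, mort_adj=mort,
                )
                rows.append({"sex": sex, "scenario": sc.name, "risk": risks[sex][sc.name]})
            for bmi in ("NW", "OW", "OB1", "OB2", "OB3"):
                r = lifetime_risk(params, life, sex, bmi,
                                  start_age=lcfg["start_age"],
                                  start_year=lcfg["start_year"], mort_adj=mort)
                rows.append({"sex": sex, "scenario": f"status quo from {bmi}", "risk": r.risk})
        _write("lifetime_risk.csv", pd.DataFrame(rows))
        ax = plot_lifetime_risk(risks)
        ax.figure.savefig(out / "lifetime_risk.png", dpi=120, bbox_inches="tight")
        plt.close("all")
        artifacts["lifetime_risk.png"] = out / "lifetime_risk.png"
    except Exception as exc:
        logger.exception("pipeline failed at stage %r (artifacts so far: %s)",
                         stage, sorted(artifacts))
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from exc

    return artifacts
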