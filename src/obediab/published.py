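"""Published French-population projections used as reference inputs.

Headline numbers reported by the published analysis of the French surveys
(ESPS 1998-2014) that this package models: projected prevalences 2022-2027
under the status quo and the three intervention scenarios, lifetime
diabetes risks for 25-year-olds in 2022, and the starting BMI distributions
of those cohorts.  They are *inputs* for worked-arithmetic checks and
examples — reproducing them exactly requires the restricted survey
microdata and national life tables, which is out of scope here.

All prevalences and risks are percentages.
"""

from __future__ import annotations

import pandas as pd

SCENARIOS = ("status_quo", "scenario1", "scenario2", "scenario3")

#: Projected adult prevalence (%) by indicator, scenario and year, 2022-2027.
_PREVALENCE_ROWS = {
    ("overweight", "status_quo"): (31.6, 31.6, 31.6, 31.6, 31.7, 31.7),
    ("overweight", "scenario1"): (31.6, 31.6, 31.5, 31.5, 31.4, 31.2),
    ("overweight", "scenario2"): (31.6, 31.6, 31.6, 31.5, 31.4, 31.4),
    ("overweight", "scenario3"): (31.6, 31.5, 31.5, 31.3, 31.1, 30.9),
    ("obesity1", "status_quo"): (11.8, 11.8, 11.9, 12.0, 12.1, 12.2),
    ("obesity1", "scenario1"): (11.8, 11.8, 11.8, 11.8, 11.8, 11.7),
    ("obesity1", "scenario2"): (11.8, 11.8, 11.8, 11.8, 11.8, 11.8),
    ("obesity1", "scenario3"): (11.8, 11.8, 11.7, 11.6, 11.4, 11.2),
    ("obesity2", "status_quo"): (4.1, 4.1, 4.2, 4.3, 4.3, 4.4),
    ("obesity2", "scenario1"): (4.1, 4.3, 4.4, 4.5, 4.6, 4.6),
    ("obesity2", "scenario2"): (4.1, 4.3, 4.4, 4.5, 4.6, 4.6),
    ("obesity2", "scenario3"): (4.1, 4.2, 4.4, 4.4, 4.4, 4.3),
    ("obesity3", "status_quo"): (1.5, 1.5, 1.6, 1.6, 1.7, 1.7),
    ("obesity3", "scenario1"): (1.5, 1.4, 1.3, 1.2, 1.1, 1.0),
    ("obesity3", "scenario2"): (1.5, 1.4, 1.2, 1.1, 1.0, 0.9),
    ("obesity3", "scenario3"): (1.5, 1.4, 1.2, 1.1, 1.0, 0.9),
    ("diabetes", "status_quo"): (7.3, 7.5, 7.7, 7.8, 8.0, 8.1),
    ("diabetes", "scenario1"): (7.3, 7.5, 7.7, 7.8, 8.0, 8.1),
    ("diabetes", "scenario2"): (7.3, 7.5, 7.7, 7.8, 8.0, 8.1),
    ("diabetes", "scenario3"): (7.3, 7.5, 7.7, 7.8, 7.9, 8.1),
}

YEARS = tuple(range(2022, 2028))


def prevalence_projections() -> pd.DataFrame:
    """Long-format table: indicator, scenario, year, prevalence (%)."""
    rows = []
    for (indicator, scenario), values in _PREVALENCE_ROWS.items():
        for year, v in zip(YEARS, values):
            rows.append(
                {"indicator": indicator, "scenario": scenario, "year": year, "prevalence": v}
            )
    return pd.DataFrame(rows)


#: Projected overall obesity prevalence (%): 17.3 in 2022 rising to 18.2 in
#: 2027 under the status quo; 16.4 in 2027 under combined scenario 3.
OVERALL_OBESITY = {
    ("status_quo", 2022): 17.3,
    ("status_quo", 2027): 18.2,
    ("scenario3", 2027): 16.4,
}

#: Lifetime risk (%) of type 2 diabetes for 25-year-olds in 2022, mixed over
#: the starting BMI distribution, by sex and scenario.
LIFETIME_RISK = {
    "M": {"status_quo": 33.1, "scenario1": 29.3, "scenario2": 30.0, "scenario3": 26.6},
    "F": {"status_quo": 30.1, "scenario1": 25.5, "scenario2": 25.5, "scenario3": 21.9},
}

#: Projected BMI-category distribution of 25-year-olds in 2022 (shares).
START_DISTRIBUTION_2022 = {
    "M": {"NW": 0.732, "OW": 0.179, "OB1": 0.066, "OB2": 0.019, "OB3": 0.005},
    "F": {"NW": 0.810, "OW": 0.097, "OB1": 0.054, "OB2": 0.026, "OB3": 0.013},
}

#: Lifetime risk (%) for normal-weight 25-year-olds: free BMI dynamics vs
#: remaining normal weight for life.
LIFETIME_RISK_NW = {"M": {"free": 30.9, "constrained": 8.9},
                    "F": {"free": 28.3, "constrained": 8.5}}


def start_distribution(sex: str) -> dict[str, float]:
    """2022 starting BMI distribution, renormalized (printed shares carry
    rounding error of up to 0.1 percentage point)."""
    d = START_DISTRIBUTION_2022[sex]
    total = sum(d.values())
    return {k: v / total for k, v in d.items()}
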