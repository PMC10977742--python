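"""Parameterization of the transition intensities.

Eight baseline transition intensities (per person-year, reference profile:
male, age >= 50, calendar period before 1995) and nineteen hazard ratios
acting multiplicatively on them under a proportional-hazards assumption —
27 free parameters, all carried internally on the log scale.

Sharing constraints keep the model identifiable and parsimonious:

* one shared baseline for the three upward obesity progressions
  (OW->OB1, OB1->OB2, OB2->OB3), with shared covariate effects;
* one shared baseline for the three downward obesity regressions
  (OB1->OW, OB2->OB1, OB3->OB2);
* a single set of covariate effects for *all four* regressions
  (including OW->NW, which keeps its own baseline);
* a shared diabetes-onset baseline for obesity classes II and III;
* a single age effect (<50 vs >=50) on diabetes onset across BMI classes;
* BMI transitions identical in diabetic and non-diabetic states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Baseline intensities, in canonical packing order.
BASELINE_KEYS = (
    "nw_ow",    # normal weight -> overweight
    "prog",     # shared: OW->OB1, OB1->OB2, OB2->OB3
    "ow_nw",    # overweight -> normal weight
    "regr",     # shared: OB1->OW, OB2->OB1, OB3->OB2
    "dm_nw",    # diabetes onset, normal weight
    "dm_ow",    # diabetes onset, overweight
    "dm_ob1",   # diabetes onset, obesity I
    "dm_ob23",  # shared diabetes onset, obesity II and III
)

#: Hazard-ratio groups and the covariate levels within each, packing order.
HR_GROUPS: dict[str, tuple[str, ...]] = {
    "nw_ow": ("female", "p1995_2004", "p2005_2014", "age_lt25", "age_25_49"),
    "prog": ("female", "p1995_2004", "p2005_2014", "age_lt25", "age_25_49"),
    "regr": ("female", "p1995_2004", "p2005_2014", "age_lt25", "age_25_49"),
    "dm": ("female", "p1995_2004", "p2005_2014", "age_lt50"),
}

N_PARAMS = len(BASELINE_KEYS) + sum(len(v) for v in HR_GROUPS.values())  # 27

PARAM_NAMES: tuple[str, ...] = tuple(
    [f"q_{k}" for k in BASELINE_KEYS]
    + [f"hr_{g}_{c}" for g, covs in HR_GROUPS.items() for c in covs]
)


@dataclass
class ParameterSet:
    """Baseline log-intensities and log-hazard-ratios of the model.

    ``log_baseline`` maps each key of :data:`BASELINE_KEYS` to the log of a
    per-person-year intensity; ``log_hr`` maps each group of
    :data:`HR_GROUPS` to a covariate->log-HR mapping.
    """

    log_baseline: dict[str, float] = field(default_factory=dict)
    log_hr: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [k for k in BASELINE_KEYS if k not in self.log_baseline]
        if missing:
            raise ValueError(f"missing baseline parameters: {missing}")
        for g, covs in HR_GROUPS.items():
            got = self.log_hr.get(g, {})
            miss = [c for c in covs if c not in got]
            if miss:
                raise ValueError(f"missing hazard ratios in group {g!r}: {miss}")
        for k in BASELINE_KEYS:
            v = float(self.log_baseline[k])
            if not np.isfinite(v):
                raise ValueError(f"non-finite log-baseline {k!r}: {v}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_natural(
        cls,
        baseline: Mapping[str, float],
        hr: Mapping[str, Mapping[str, float]] | None = None,
    ) -> "ParameterSet":
        """Build from intensities and hazard ratios on the natural scale.

        Hazard ratios omitted from ``hr`` default to 1 (no effect).
        """
        hr = hr or {}
        log_hr = {
            g: {c: float(np.log(hr.get(g, {}).get(c, 1.0))) for c in covs}
            for g, covs in HR_GROUPS.items()
        }
        return cls(
            log_baseline={k: float(np.log(baseline[k])) for k in BASELINE_KEYS},
            log_hr=log_hr,
        )

    @classmethod
    def null(cls, baseline_value: float = 0.01) -> "ParameterSet":
        """Neutral starting point: every baseline at ``baseline_value``/yr, all HRs 1."""
        return cls.from_natural({k: baseline_value for k in BASELINE_KEYS})

    # -- natural-scale accessors --------------------------------------

    def baseline(self, key: str) -> float:
        return float(np.exp(self.log_baseline[key]))

    def hazard_ratio(self, group: str, covariate: str) -> float:
        return float(np.exp(self.log_hr[group][covariate]))

    def baselines(self) -> dict[str, float]:
        return {k: self.baseline(k) for k in BASELINE_KEYS}

    def hazard_ratios(self) -> dict[str, dict[str, float]]:
        return {g: {c: self.hazard_ratio(g, c) for c in covs} for g, covs in HR_GROUPS.items()}

    # -- flat-vector interface (optimizer surface) --------------------

    def pack(self) -> np.ndarray:
        """Flatten to the canonical 27-vector of log parameters."""
        vec = [self.log_baseline[k] for k in BASELINE_KEYS]
        for g, covs in HR_GROUPS.items():
            vec.extend(self.log_hr[g][c] for c in covs)
        return np.asarray(vec, dtype=float)

    @classmethod
    def unpack(cls, vector: np.ndarray) -> "ParameterSet":
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (N_PARAMS,):
            raise ValueError(f"expected a {N_PARAMS}-vector, got shape {vector.shape}")
        log_baseline = dict(zip(BASELINE_KEYS, vector[: len(BASELINE_KEYS)]))
        log_hr: dict[str, dict[str, float]] = {}
        i = len(BASELINE_KEYS)
        for g, covs in HR_GROUPS.items():
            log_hr[g] = dict(zip(covs, vector[i : i + len(covs)]))
            i += len(covs)
        return cls(log_baseline=log_baseline, log_hr=log_hr)


def reference_parameters() -> ParameterSet:
    """Published estimates for the French adult population.

    Point estimates from a maximum-likelihood fit of this model to the
    French ESPS health surveys (97,948 respondents, nine biennial waves
    1998-2014).  Baselines are per-person-year intensities for the
    reference profile (male, age >= 50, period before 1995).  These serve
    as defaults for simulation and as generating truth in recovery
    experiments.
    """
    return ParameterSet.from_natural(
        baseline={
            "nw_ow": 0.0480,
            "prog": 0.0125,
            "ow_nw": 0.0271,
            "regr": 0.0491,
            "dm_nw": 0.0009,
            "dm_ow": 0.0033,
            "dm_ob1": 0.0081,
            "dm_ob23": 0.0156,
        },
        hr={
            "nw_ow": {
                "female": 0.72,
                "p1995_2004": 1.11,
                "p2005_2014": 1.43,
                "age_lt25": 0.24,
                "age_25_49": 0.87,
            },
            "prog": {
                "female": 2.00,
                "p1995_2004": 1.92,
                "p2005_2014": 2.38,
                "age_lt25": 1.48,
                "age_25_49": 1.36,
            },
            "regr": {
                "female": 1.69,
                "p1995_2004": 1.20,
                "p2005_2014": 1.25,
                "age_lt25": 0.67,
                "age_25_49": 1.17,
            },
            "dm": {
                "female": 0.81,
                "p1995_2004": 2.89,
                "p2005_2014": 3.12,
                "age_lt50": 0.24,
            },
        },
    )
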