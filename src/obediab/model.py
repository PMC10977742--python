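"""Maximum-likelihood estimation from interval-censored survey panels.

Each survey record contributes one interval: the individual is normal weight
and non-diabetic at age 3 (by assumption) and is observed in some living
state at the survey age.  The likelihood of a record is the corresponding
entry of the interval transition-probability matrix, a product of matrix
exponentials over the constant-covariate segments of the life course; the
sample log-likelihood sums over records.  Records sharing sex, birth year
and survey year share one matrix product, which makes survey-scale fitting
fast.

The public surface follows the statsmodels idiom: build a
:class:`BmiDiabetesPanelModel` from a data frame, call :meth:`fit`, get a
:class:`PanelFitResults` with estimates, covariance, confidence intervals
and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .intensity import build_intensity_matrix
from .params import BASELINE_KEYS, HR_GROUPS, N_PARAMS, PARAM_NAMES, ParameterSet
from .segments import DEFAULT_CONFIG, CovariateProfile, ModelConfig, make_segments
from .states import N_BMI, N_LIVING, STATE_LABELS, HealthState

logger = logging.getLogger(__name__)

_EXPM_FALLBACK_TOL = 1e-8


def transition_probability(
    params: ParameterSet,
    birth_year: int,
    sex: str,
    from_age: float,
    to_age: float,
    config: ModelConfig = DEFAULT_CONFIG,
    up_mult: float = 1.0,
    down_mult: float = 1.0,
) -> np.ndarray:
    """Interval transition-probability matrix P(from_age, to_age).

    Product over constant-covariate segments of ``expm(Q_k * dt_k)``.
    Rows sum to one; entry ``[i, j]`` is the probability of being in state
    ``j`` at ``to_age`` given state ``i`` at ``from_age``.
    """
    if from_age > to_age:
        raise ValueError("from_age must not exceed to_age")
    P = np.eye(N_LIVING)
    for seg in make_segments(birth_year, sex, end_age=to_age, start_age=from_age, config=config):
        Q = build_intensity_matrix(params, seg.profile, up_mult, down_mult)
        if not np.all(np.isfinite(Q)):
            raise FloatingPointError(
                f"non-finite intensities on segment [{seg.start_age}, {seg.end_age}) "
                f"({seg.profile})"
            )
        P = P @ scipy.linalg.expm(Q * seg.length)
    return P


# ---------------------------------------------------------------------------
# fast likelihood kernel


class _SegmentedLikelihood:
    """Precompiled segment structure for a panel dataset.

    Groups records by (sex, birth_year, survey_year); each group's interval
    is a fixed sequence of (profile, dt) pairs.  Per evaluation, the unique
    profile generators are eigendecomposed once and every unique
    (profile, dt) exponential is assembled from the spectral form (with an
    ``expm`` fallback when the eigenbasis is ill-conditioned), after which
    all group products run as a handful of batched matrix operations.
    """

    def __init__(self, data: pd.DataFrame, config: ModelConfig):
        self.config = config
        key_cols = ["sex", "birth_year", "survey_year"]
        grouped = data.groupby(key_cols + ["state_index"], sort=True).size()
        gframe = grouped.rename("count").reset_index()
        group_keys = gframe[key_cols].drop_duplicates().reset_index(drop=True)
        key_to_gidx = {tuple(r): i for i, r in enumerate(group_keys.itertuples(index=False))}

        self.group_keys = group_keys
        self.n_groups = len(group_keys)
        self.n_records = int(gframe["count"].sum())

        profiles: dict[CovariateProfile, int] = {}
        pairs: dict[tuple[int, float], int] = {}
        seg_lists: list[list[int]] = []
        for sex, by, sy in group_keys.itertuples(index=False):
            age = float(sy - by)
            segs = make_segments(int(by), sex, end_age=age, config=config)
            idxs = []
            for seg in segs:
                p = profiles.setdefault(seg.profile, len(profiles))
                k = pairs.setdefault((p, float(seg.length)), len(pairs))
                idxs.append(k)
            seg_lists.append(idxs)

        self.profiles: list[CovariateProfile] = list(profiles)
        self.pair_profile = np.array([p for p, _ in pairs], dtype=int)
        self.pair_dt = np.array([dt for _, dt in pairs], dtype=float)
        self.n_pairs = len(pairs)

        smax = max((len(s) for s in seg_lists), default=0)
        # identity placeholder at index n_pairs pads ragged segment lists
        self.seg_idx = np.full((self.n_groups, smax), self.n_pairs, dtype=int)
        for g, idxs in enumerate(seg_lists):
            self.seg_idx[g, : len(idxs)] = idxs

        self.obs_group = gframe[key_cols].apply(tuple, axis=1).map(key_to_gidx).to_numpy()
        self.obs_state = gframe["state_index"].to_numpy()
        self.obs_count = gframe["count"].to_numpy(dtype=float)

    def _segment_matrices(self, params: ParameterSet, up_mult=1.0, down_mult=1.0) -> np.ndarray:
        Qs = np.stack(
            [build_intensity_matrix(params, pr, up_mult, down_mult) for pr in self.profiles]
        )
        P = np.empty((self.n_pairs + 1, N_LIVING, N_LIVING))
        P[self.n_pairs] = np.eye(N_LIVING)
        if self.n_pairs == 0:
            return P
        w, V = np.linalg.eig(Qs)
        ok = np.zeros(len(self.profiles), dtype=bool)
        Vinv = np.empty_like(V)
        for i in range(len(self.profiles)):
            try:
                Vinv[i] = np.linalg.inv(V[i])
            except np.linalg.LinAlgError:
                continue
            recon = (V[i] * w[i]) @ Vinv[i]
            scale = max(1.0, np.abs(Qs[i]).max())
            ok[i] = np.abs(recon - Qs[i]).max() < _EXPM_FALLBACK_TOL * scale
        pid = self.pair_profile
        spectral = ok[pid]
        if spectral.any():
            idx = np.flatnonzero(spectral)
            E = np.exp(w[pid[idx]] * self.pair_dt[idx, None])
            P[idx] = np.real(np.einsum("kij,kj,kjl->kil", V[pid[idx]], E, Vinv[pid[idx]]))
            # reject spectral results that are not near-stochastic
            bad = (P[idx].min(axis=(1, 2)) < -1e-9) | (
                np.abs(P[idx].sum(axis=2) - 1.0).max(axis=1) > 1e-7
            )
            spectral[idx[bad]] = False
        for k in np.flatnonzero(~spectral):
            P[k] = scipy.linalg.expm(Qs[pid[k]] * self.pair_dt[k])
        np.clip(P, 0.0, None, out=P)
        return P

    def state_probabilities(self, params: ParameterSet) -> np.ndarray:
        """(n_groups, 10) matrix: P(state at survey age | NW non-diabetic at 3)."""
        P = self._segment_matrices(params)
        rows = np.zeros((self.n_groups, N_LIVING))
        rows[:, 0] = 1.0
        for s in range(self.seg_idx.shape[1]):
            rows = np.einsum("gi,gij->gj", rows, P[self.seg_idx[:, s]])
        return rows

    def loglik(self, params: ParameterSet) -> tuple[float, np.ndarray]:
        """Sample log-likelihood and the indices of zero-probability groups."""
        rows = self.state_probabilities(params)
        probs = rows[self.obs_group, self.obs_state]
        bad = probs <= 0.0
        if bad.any():
            return -np.inf, np.unique(self.obs_group[bad])
        return float(self.obs_count @ np.log(probs)), np.empty(0, dtype=int)


# ---------------------------------------------------------------------------
# public model / results


def _prepare_panel(data: pd.DataFrame, config: ModelConfig) -> pd.DataFrame:
    required = {"sex", "birth_year", "survey_year", "bmi_class", "diabetes"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"panel data missing columns: {sorted(missing)}")
    df = data.copy()
    df["sex"] = df["sex"].astype(str).str.upper()
    if not df["sex"].isin(["M", "F"]).all():
        raise ValueError("sex must be coded M/F")
    df["state_index"] = [
        HealthState.from_label(b, d).index
        for b, d in zip(df["bmi_class"], df["diabetes"])
    ]
    age = df["survey_year"] - df["birth_year"]
    if (age < config.start_age).any():
        raise ValueError("records observed before the simulation origin (age 3)")
    return df


@dataclass
class BmiDiabetesPanelModel:
    """Ten-state BMI / type 2 diabetes model for interval-censored panel data.

    Parameters
    ----------
    data
        One row per observation with columns ``sex`` (M/F), ``birth_year``,
        ``survey_year``, ``bmi_class`` (NW/OW/OB1/OB2/OB3), ``diabetes``
        (0/1).  A ``person_id`` column is carried through if present.
    config
        Structural constants (breakpoints, activation ages).
    """

    data: pd.DataFrame
    config: ModelConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise ValueError("empty panel dataset")
        self._panel = _prepare_panel(self.data, self.config)
        self._kernel = _SegmentedLikelihood(self._panel, self.config)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, config: ModelConfig = DEFAULT_CONFIG
    ) -> "BmiDiabetesPanelModel":
        return cls(data=data, config=config)

    @property
    def nobs(self) -> int:
        return self._kernel.n_records

    # -- likelihood ----------------------------------------------------

    def loglike(self, params: ParameterSet | np.ndarray) -> float:
        """Log-likelihood; ``-inf`` on zero-probability data.

        After a ``-inf`` evaluation the offending observation groups are
        available as :attr:`zero_probability_groups_`.
        """
        if not isinstance(params, ParameterSet):
            params = ParameterSet.unpack(params)
        ll, bad = self._kernel.loglik(params)
        if bad.size:
            self.zero_probability_groups_ = self._kernel.group_keys.iloc[bad]
            logger.info(
                "zero-probability observations for %d (sex, birth_year, survey_year) "
                "groups, e.g. %s", len(bad),
                tuple(self.zero_probability_groups_.iloc[0]),
            )
        return ll

    def score_numeric(self, vector: np.ndarray, step: float = 1e-6) -> np.ndarray:
        """Central-difference gradient of the log-likelihood."""
        vector = np.asarray(vector, dtype=float)
        g = np.empty(N_PARAMS)
        for i in range(N_PARAMS):
            e = np.zeros(N_PARAMS)
            e[i] = step
            g[i] = (self.loglike(vector + e) - self.loglike(vector - e)) / (2 * step)
        return g

    def hessian_numeric(self, vector: np.ndarray, step: float = 1e-4) -> np.ndarray:
        """Central-difference Hessian of the log-likelihood (symmetric)."""
        vector = np.asarray(vector, dtype=float)
        f = self.loglike
        f0 = f(vector)
        H = np.empty((N_PARAMS, N_PARAMS))
        fp = np.empty(N_PARAMS)
        fm = np.empty(N_PARAMS)
        eye = np.eye(N_PARAMS) * step
        for i in range(N_PARAMS):
            fp[i] = f(vector + eye[i])
            fm[i] = f(vector - eye[i])
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / step**2
        for i in range(N_PARAMS):
            for j in range(i + 1, N_PARAMS):
                fpp = f(vector + eye[i] + eye[j])
                fmm = f(vector - eye[i] - eye[j])
                H[i, j] = H[j, i] = (
                    fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
                ) / (2 * step**2)
        return H

    # -- fitting --------------------------------------------------------

    def fit(
        self,
        start_params: ParameterSet | np.ndarray | None = None,
        maxiter: int = 500,
        compute_cov: bool = True,
        gtol: float = 1e-5,
    ) -> "PanelFitResults":
        """Maximize the likelihood over the 27 free log-scale parameters.

        Quasi-Newton (L-BFGS-B) on the unconstrained log scale, with wide
        box bounds that only exclude numerically absurd intensities.
        Standard errors come from the inverse observed information
        (central-difference Hessian).  Non-convergence is reported through
        the results object, not raised.
        """
        if start_params is None:
            start_params = ParameterSet.null()
        x0 = start_params.pack() if isinstance(start_params, ParameterSet) else np.asarray(start_params, float)

        nb = len(BASELINE_KEYS)
        bounds = [(-14.0, 3.0)] * nb + [(-6.0, 6.0)] * (N_PARAMS - nb)

        def nll(v: np.ndarray) -> float:
            ll = self.loglike(v)
            return 1e12 if not np.isfinite(ll) else -ll

        opt = scipy.optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-11, "maxfun": 200_000},
        )
        vector = opt.x
        llf = -opt.fun

        cov = None
        flagged: list[str] = []
        if compute_cov:
            H = self.hessian_numeric(vector)
            info = -H  # observed information
            diag = np.abs(np.diag(info))
            flagged = [PARAM_NAMES[i] for i in np.flatnonzero(diag < 1e-8)]
            try:
                cov = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(info)
            cov = (cov + cov.T) / 2.0
            if not np.all(np.diag(cov) > 0):
                flagged = sorted(
                    set(flagged)
                    | {PARAM_NAMES[i] for i in np.flatnonzero(np.diag(cov) <= 0)}
                )

        return PanelFitResults(
            model=self,
            params_vector=vector,
            llf=llf,
            converged=bool(opt.success),
            message=str(opt.message),
            nfev=int(opt.nfev),
            cov_params_log=cov,
            nonidentifiable=flagged,
        )

    # -- diagnostics -----------------------------------------------------

    def predicted_state_probabilities(self, params: ParameterSet) -> pd.DataFrame:
        """Per (sex, birth_year, survey_year) group: model state distribution."""
        rows = self._kernel.state_probabilities(params)
        out = self._kernel.group_keys.copy()
        for j, lab in enumerate(STATE_LABELS):
            out[lab] = rows[:, j]
        return out


@dataclass
class PanelFitResults:
    """Estimates, uncertainty and diagnostics of a panel-model fit."""

    model: BmiDiabetesPanelModel
    params_vector: np.ndarray
    llf: float
    converged: bool
    message: str
    nfev: int
    cov_params_log: np.ndarray | None
    nonidentifiable: list[str]

    @property
    def params(self) -> ParameterSet:
        return ParameterSet.unpack(self.params_vector)

    @property
    def bse(self) -> np.ndarray:
        """Standard errors on the log scale (NaN where information is singular)."""
        if self.cov_params_log is None:
            return np.full(N_PARAMS, np.nan)
        d = np.diag(self.cov_params_log).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Natural-scale Wald intervals: exp(log-estimate +/- z * SE)."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        se = self.bse
        est = np.exp(self.params_vector)
        lo = np.exp(self.params_vector - z * se)
        hi = np.exp(self.params_vector + z * se)
        return pd.DataFrame(
            {"estimate": est, "ci_low": lo, "ci_high": hi}, index=list(PARAM_NAMES)
        )

    def parameter_table(self) -> pd.DataFrame:
        """Estimates with 95% CIs, natural scale, canonical parameter order."""
        return self.conf_int(0.05)

    def summary(self) -> str:
        """Human-readable fit report in the usual intensity/HR layout."""
        tab = self.parameter_table()
        lines = [
            "BMI / type 2 diabetes multi-state panel model",
            "=" * 62,
            f"records: {self.model.nobs}    log-likelihood: {self.llf:.2f}",
            f"converged: {self.converged}    function evals: {self.nfev}",
        ]
        if self.nonidentifiable:
            lines.append("non-identifiable parameters: " + ", ".join(self.nonidentifiable))
        lines.append("-" * 62)
        lines.append(f"{'parameter':<22}{'estimate':>10}{'95% CI':>24}")
        for name, row in tab.iterrows():
            q = name.startswith("q_")
            fmt = (lambda v: f"{100 * v:.2f}%") if q else (lambda v: f"{v:.2f}")
            ci = f"[{fmt(row.ci_low)}, {fmt(row.ci_high)}]"
            lines.append(f"{name:<22}{fmt(row.estimate):>10}{ci:>24}")
        return "\n".join(lines)

    # -- goodness of fit --------------------------------------------------

    def goodness_of_fit(
        self, age_bins: Sequence[float] = (15, 25, 35, 45, 55, 65, 75, 110)
    ) -> dict[str, pd.DataFrame]:
        """Observed vs predicted prevalence tables.

        Returns three tables: prevalence of obesity and diabetes by survey
        year, by age group, and diabetes prevalence by BMI category.
        Predictions average each record's model state distribution over the
        stratum; empty strata are omitted.
        """
        return goodness_of_fit(self.model, self.params, age_bins=age_bins)


def goodness_of_fit(
    model: BmiDiabetesPanelModel,
    params: ParameterSet,
    age_bins: Sequence[float] = (15, 25, 35, 45, 55, 65, 75, 110),
) -> dict[str, pd.DataFrame]:
    panel = model._panel
    kern = model._kernel
    rows = kern.state_probabilities(params)

    key = panel[["sex", "birth_year", "survey_year"]].apply(tuple, axis=1)
    gk = {tuple(r): i for i, r in enumerate(kern.group_keys.itertuples(index=False))}
    gidx = key.map(gk).to_numpy()
    pred = rows[gidx]  # (n_records, 10)

    obese_cols = [2, 3, 4, 2 + N_BMI, 3 + N_BMI, 4 + N_BMI]
    dm_cols = list(range(N_BMI, N_LIVING))
    obs_state = panel["state_index"].to_numpy()
    obs_obese = np.isin(obs_state, obese_cols).astype(float)
    obs_dm = (obs_state >= N_BMI).astype(float)

    def strata_table(labels: pd.Series) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "stratum": labels.to_numpy(),
                "obs_obesity": obs_obese,
                "obs_diabetes": obs_dm,
                "pred_obesity": pred[:, obese_cols].sum(axis=1),
                "pred_diabetes": pred[:, dm_cols].sum(axis=1),
            }
        )
        out = df.groupby("stratum").agg(
            n=("obs_obesity", "size"),
            obs_obesity=("obs_obesity", "mean"),
            pred_obesity=("pred_obesity", "mean"),
            obs_diabetes=("obs_diabetes", "mean"),
            pred_diabetes=("pred_diabetes", "mean"),
        )
        return out[out["n"] > 0]

    by_year = strata_table(panel["survey_year"])

    age = panel["survey_year"] - panel["birth_year"]
    bins = pd.cut(age, bins=list(age_bins), right=False)
    by_age = strata_table(bins.astype(str))

    # diabetes prevalence within each BMI category
    recs = []
    bmi_obs = obs_state % N_BMI
    for b, lab in enumerate(("NW", "OW", "OB1", "OB2", "OB3")):
        mask = bmi_obs == b
        if not mask.any():
            continue
        p_class = pred[:, [b, b + N_BMI]].sum(axis=1)
        p_dm_class = pred[:, b + N_BMI]
        recs.append(
            {
                "bmi_class": lab,
                "n": int(mask.sum()),
                "obs_diabetes": float(obs_dm[mask].mean()),
                "pred_diabetes": float(p_dm_class.sum() / p_class.sum()),
            }
        )
    by_bmi = pd.DataFrame(recs).set_index("bmi_class")

    return {"by_year": by_year, "by_age": by_age, "diabetes_by_bmi": by_bmi}
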