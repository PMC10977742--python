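# Methods

## Model

The population process is a time-inhomogeneous continuous-time Markov
chain on 10 living states: BMI category (NW, OW, OB1, OB2, OB3 at
cut-points 25/30/35/40 kg/m², lower bound inclusive) × type 2 diabetes
status. Allowed moves are one BMI step up or down with diabetes status
unchanged, and diabetes onset with BMI unchanged. Diabetes remission is
excluded: long-term sustained remission is a marginal event at the
population level, and the surveys the model is designed for carry no
information to identify it.

Printed "annual risks" such as 4.80% are interpreted as transition
*intensities* of 0.0480 per person-year, not one-year probabilities: only
intensities compose correctly over arbitrary intervals through
P(t) = exp(Q·t), and a probability reading would make the interval
likelihood incoherent.

### Parameters and sharing constraints

27 free parameters, all estimated on the log scale:

| block | parameters | default (reference estimates) |
|---|---|---|
| baselines (per yr) | q_nw_ow; q_prog (OW→OB1 = OB1→OB2 = OB2→OB3); q_ow_nw; q_regr (OB1→OW = OB2→OB1 = OB3→OB2); q_dm_nw; q_dm_ow; q_dm_ob1; q_dm_ob23 | 0.0480, 0.0125, 0.0271, 0.0491, 0.0009, 0.0033, 0.0081, 0.0156 |
| HRs on NW→OW | female, 1995–2004, 2005–2014, <25, 25–49 | 0.72, 1.11, 1.43, 0.24, 0.87 |
| HRs on progression | same five | 2.00, 1.92, 2.38, 1.48, 1.36 |
| HRs on all regressions | same five | 1.69, 1.20, 1.25, 0.67, 1.17 |
| HRs on diabetes onset | female, 1995–2004, 2005–2014, <50 | 0.81, 2.89, 3.12, 0.24 |

BMI-transition rows are identical in the diabetic and non-diabetic layers
(no evidence that diabetes itself alters BMI-category dynamics). The
diabetes age effect uses a single <50 class, distinct from the three-class
age covariate on BMI moves. Reference cell: men, ≥50, before 1995.

### Covariate segmentation conventions

Age in calendar year y is y − birth_year (surveys record years only;
mid-year effects are ignored). Age intervals are half-open [a, b); period
boundaries sit at January 1 of 1995 and 2005; the 2005–2014 period is
carried forward indefinitely, matching the projection assumption that the
2015+ trend continues the last observed period. A life course is split at
ages {25, 40, 50} and at the ages corresponding to 1995 and 2005, giving
segments with constant generator; interval probabilities are ordered
products of matrix exponentials. Periods are evaluated at exact calendar
dates (segment boundaries), not interval midpoints — with annual data the
two conventions differ by at most the treatment of a single boundary year.

Diabetes onset is *activated* at age 40 in normal weight and 25 otherwise
(the surveys show no type 2 diabetes below those ages); activation is
encoded as exact zeros in the generator rather than by truncating the time
axis, so one segmented expm product handles everything uniformly.

## Estimation

Everyone is normal-weight and non-diabetic at age 3 — the earliest age at
which overweight is defined. Each record contributes one interval, from
that origin to the survey age; repeated observations of one person are
supported by the likelihood machinery but not assumed (whether survey
respondents recur across waves is not knowable from the public record;
the one-interval design is the conservative reading).

Likelihood evaluation groups records by (sex, birth year, survey year):
each group shares one product of segment exponentials. The unique segment
generators (≈24 per evaluation) are eigendecomposed once and every unique
(profile, Δt) exponential is assembled spectrally; any result that is not
near-stochastic (negative entry < −1e−9 or row-sum error > 1e−7, e.g. from
an ill-conditioned eigenbasis at extreme trial parameters) is recomputed
with `scipy.linalg.expm`. Group products then run as a handful of batched
matrix operations, which makes one evaluation ~3 ms at n = 10,000 and a
full fit under a minute on one CPU.

Optimization: L-BFGS-B on the unconstrained log scale from a neutral start
(all baselines 0.01/yr, all HRs 1), with wide box bounds (log-intensities
in [−14, 3], log-HRs in [−6, 6]) that only exclude numerically absurd
values. A zero-probability observation contributes −∞ (surfaced with the
offending group keys); inside the optimizer this is mapped to a large
finite penalty. Standard errors come from the inverse observed information
(central-difference Hessian, step 1e−4 on the log scale); parameters whose
information diagonal is ~0 (e.g. diabetes parameters in a dataset with no
post-activation person-time) are flagged non-identifiable rather than
given fake intervals. Wald CIs are exp(log-estimate ± 1.96·SE).

Mortality is deliberately absent from estimation: surveys observe
survivors only, and the two-step design (fit to survivors, then project
with mortality) keeps the likelihood simple. The synthetic generator
therefore omits mortality thinning by default, keeping recovery
experiments unbiased; an optional thinning flag exists for realism
studies.

### What the synthetic generator does and does not emulate

It reproduces: the nine biennial waves 1998–2014, truncated-normal age at
survey (mean 44.7, SD 18.7, range 15–90), 51.5% male, one record per
person, exact simulation of the chain from age 3 (competing exponential
clocks per constant-covariate segment), and an optional small rate of
under-40 normal-weight respondents mis-declaring diabetes, to exercise the
cleaning rule. It does not emulate household sampling, survey weights,
non-response, self-report measurement error in weight/height, or panel
re-contact. Passing recovery tests therefore demonstrate correctness of
the likelihood/optimizer pair under the stated design — not robustness to
those real-data features.

A consequence worth stating plainly: with a single interval per person
anchored at age 3, the baseline (pre-1995, ≥50) intensities and the
period/age hazard ratios are separated only by cohort variation, and the
profile likelihood has wide, gently curved ridges. At n = 10,000 the
log-scale standard errors of the baseline intensities are ≈0.4–0.6, so
individual point estimates routinely sit 20–50% from the generating
values while remaining well inside their own confidence intervals (and
the MLE exceeds the truth in log-likelihood, confirming this is sampling
spread, not optimizer failure). Recovery is therefore judged against the
fit's own uncertainty, not a fixed relative error.

## Cleaning rules

Rows missing BMI (category, or weight/height to compute it) or the
diabetes indicator are dropped and counted. Under-40 normal-weight
respondents declaring diabetes are treated as type 1/genetic cases:
reclassified to non-diabetic normal weight and counted (the rule boundary
is age < 40 at survey). Malformed rows (unparseable years, unknown sex
codes) go to a rejects table with reasons.

## Projection

Each birth cohort (default from 1895) starts at age 3 entirely NW
non-diabetic and advances in annual steps through an 11-state generator:
the living generator plus an absorbing death state with intensity
−ln(1−qx)·HR(state). Annual stepping matches the life table's resolution;
the O(Δt²) error of freezing covariates within a year is accepted and
shared by every scenario being compared. Prevalences are cohort-weighted
shares of the living population aged ≥18 (configurable).

State-specific mortality hazard ratios default to 1 (no excess): the
external estimates that would populate them are not part of the public
record, so they are configuration, not constants. The monotonicity
property — raising diabetic-state mortality lowers projected diabetes
prevalence — is tested, so wiring in real HRs changes levels, not
mechanics.

Scenario factors (move-up decrease δ ∈ [0,1], move-down increase γ ≥ 0)
multiply the eight BMI intensities from the start year (default 2022);
onset and death intensities are never touched. `find_required_change`
bisects the monotone map δ ↦ end-year obesity prevalence (or γ ↦ …) to a
prevalence tolerance of 1e−3 (tighter on request); an unattainable
objective returns the boundary with a flag rather than raising.
`scenario_grid` reports the end-year prevalence surface with the relative
reduction under *both* conventions — versus the status-quo end year and
versus the start year — because published figures use the former while
headline "relative increase" numbers use the latter.

## Lifetime risk

The chain is augmented with death split into died-never-diabetic /
died-after-onset; the lifetime risk from a living non-diabetic state at
age 25 (default) is the terminal mass of {diabetic living} ∪
{died-after-onset} at the horizon. Horizon: age 110, with the life table
extrapolated at its last hazard beyond its range; with a realistic table
the residual survivor mass at 110 is of order 1e−3–1e−4, so the
cumulative-incidence curve is flat to ~1e−4 per year at the horizon (the
practical convergence criterion used in the tests). The risk conditions on
being alive and non-diabetic at the starting age; calendar effects are
frozen at the 2005–2014 level for all future years. `constrain_bmi=True`
zeroes all BMI transitions — the "remains normal weight all life" variant.
Population-level risk mixes per-state risks over a starting BMI
distribution (validated to sum to 1 within 1e−6; the published 2022
distributions carry 0.1-point rounding excess and are renormalized by
`published.start_distribution`).

## Numerical choices and problem sizes

* expm via scipy (Padé); spectral shortcut only where verifiably accurate
  (see above); probabilities clipped at 0 after assembly.
* Bisection tie-break: the search returns the midpoint at the first
  iterate within the prevalence tolerance; comparisons against grid scans
  should use a tolerance of (prevalence tol)/(local slope) plus one grid
  step.
* Degenerate inputs: zero-length observation intervals yield empty segment
  lists and identity transition matrices; α=0 Gompertz tables are immortal
  and legal; n=0 synthetic panels are empty but well-formed.
* Test problem sizes are chosen for single-CPU runs: recovery fit at
  n = 10,000 (one seeded replicate), Monte-Carlo oracle at 10⁶ replicates
  (vectorized), projections over reduced cohort ranges (first cohort
  1960–1975) for monotonicity and search tests; the full 1895+ cohort
  range is used in the README example and the pipeline default.

## Known limitations

* Single-interval likelihood: no within-person longitudinal correlation,
  and the wide baseline/period ridges described above.
* No random effects, no continuous BMI, no transitions skipping a class,
  no diabetes remission, no migration; cohort sizes are births, with
  pre-adult mortality folded into the life table from age 3 onward.
* The synthetic life table and cohort sizes are deliberately simple
  stand-ins; absolute projected levels depend on them, while the tested
  claims are structural (monotonicity, conservation, direction of
  scenario effects).
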