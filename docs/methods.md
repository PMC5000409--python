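# Methods

`cmrctsim` simulates cluster-randomised trials embedded in a standing cohort
(the "trial within cohorts" / cmRCT design) and quantifies what
post-randomisation treatment refusal does to effect estimates and power.
This note records the model, the numerical choices, and what the built-in
checks do and do not demonstrate.

## Generative model

The cohort mimics a UK primary-care population at elevated cardiovascular
(CVD) risk, clustered by practice. For subject *i* in cluster *k*:

* random effects: individual `eps_ik ~ N(0, sigma2_eps)` and cluster
  `U_k ~ N(0, sigma2_u)`, both acting additively on the log hazard (i.e.
  shared lognormal frailties). Default variance pair (0.6, 0.2); the
  alternative (0.57, 0.27) is carried under the label "ICC 0.05".
* time to CVD event: hazard
  `h_c(t) = gamma_c t^(gamma_c-1) / lambda_c^gamma_c * exp(beta X_ik + eps_ik + U_k)`,
  with Weibull shape `gamma_c = 1.2` and scale `lambda_c = 36` years;
  equivalently `T_c ~ Weibull(gamma_c, lambda_c exp(-(beta X + eps + U)/gamma_c))`.
* time to death: same form with `gamma_m = 1.2`, `lambda_m = 55`, and no
  treatment term — the intervention affects only the CVD hazard. Because
  both times share `eps + U`, death acts as an *informative* censoring
  process.
* counterfactual 10-year risk under usual care:
  `r_ik = 1 - exp(-(10/lambda_c)^gamma_c * exp(eps_ik + U_k))`.
* observed data: `Y = min(T_c, T_m, T_max)` with `T_max = 3` years and
  censoring indicator `C = I(T_c >= min(T_m, T_max))`.

Refusal: each subject carries a patient refusal probability `p_ik` and a
clinician refusal probability `q_ik`. Subjects are ranked by `r_ik` over the
whole cohort and probabilities are assigned linearly between a lower and an
upper limit along that ranking: `(LL, UL)` is `(p, p)`, `(2p/3, 4p/3)`,
`(p/3, 5p/3)` or `(0, 2p)` for the zero/low/medium/high correlation tiers.
The mean is exactly `p` by symmetry of the grid; the *sign* of the
refusal-risk correlation is set by traversing the grid up (positive: the
riskiest refuse most) or down the ranking. Ranks tie only under degenerate
variances; ties are broken by a seeded uniform jitter so assignment is
deterministic given the seed. Patient and clinician probabilities are laid
out on the same risk ordering, each with its own tier and sign, so when both
are non-degenerate they are mutually correlated through risk — nothing in
the design says otherwise, and a shared ordering is the simplest reading.

A trial randomises whole clusters 4:1 control:intervention
(`round(K/5)` intervention clusters, at least one). Allocated subjects
receive the intervention iff two independent Bernoulli draws clear both
refusal probabilities, so uptake probability is `(1-p_ik)(1-q_ik)`;
controls are never treated. Event times are drawn by inverse-CDF so one
uniform maps to one time (monotone in the linear predictor at a fixed
draw), and every stochastic component hangs off one `numpy` SeedSequence
stream per replicate.

### Calibration caveat

The design constants above are commonly quoted alongside three calibration
statements: mean 10-year risk 21.1% (SD 8.6%), corr(T_c, T_m) = 0.25, and
"censoring of 5% of all events". Direct Monte-Carlo at the stated constants
gives mean 24.2%, SD 17.6% and correlation 0.38, and no single total
random-effect variance reproduces all three statements at once (the risk
mean/SD would need ~0.22, the correlation ~0.38, while the stated pair sums
to 0.8). This package implements the stated generative constants and reports
the realised calibration rather than forcing the quoted one. The ~25% mean
relative risk reduction implied by `beta = -0.32` does verify. The "5% of
all events" phrase has no unambiguous denominator at these parameters
(~95% of subjects are administratively censored); the simulator reports the
realised fraction of events pre-empted by death instead of enforcing it.

## Analysis methods

Four estimators of the treatment effect (log hazard ratio for *accepting*
the intervention), each on top of any of three Cox-model clustering
treatments:

* **ITT** — Cox on allocation `Z`; attenuated towards the null by refusal
  (dilution), approximately by the acceptance rate for small effects.
* **PP** — drops intervention-cluster refusers, Cox on receipt `X`; subject
  to selection bias whenever refusal tracks risk.
* **2SPS** — linear first stage of `X` on `Z` (allocation is the
  instrument; least squares on a saturated binary design returns the arm
  means), Cox on the fitted uptake. Because the fitted value is exactly
  `acceptance x Z`, the 2SPS coefficient is the ITT coefficient divided by
  the acceptance rate — an identity the tests exploit.
* **2SRI** — Cox on `(X, first-stage residual)`; the residual proxies the
  latent acceptance propensity and absorbs risk-correlated refusal. With
  full compliance the residual is constant and is dropped (logged on the
  estimate), reducing 2SRI to ITT.

A logistic first stage would be degenerate here (X is forced to 0 when
Z = 0), so the linear probability model is the right first stage, and it is
what the two-stage recipes for nonlinear second stages prescribe.

Second-stage model SEs understate two-stage uncertainty, so a
nonparametric bootstrap is provided; it resamples *clusters* with
replacement (the randomisation unit — resampling subjects would break the
dependence structure) and re-runs both stages per resample. Power
computations use the naive second-stage Wald p-value by default, which
mirrors recording one p-value per simulated trial inside the replication
loop; bootstrap SEs are an option (`--bootstrap-B`), not the default.

## Cox fitting

All three model variants run on one Breslow partial-likelihood engine
(`_ppl.py`). Risk sets are suffixes of the time-sorted data, so risk-set
sums are suffix sums over segments delimited by distinct event times — one
`bincount` pass per quantity, O(N) per Newton iteration regardless of the
number of clusters. Ties use the Breslow approximation (event times are
continuous here, so ties have measure zero); time-scaling invariance and a
brute-force six-subject partial-likelihood oracle guard the implementation.

* **Marginal**: plain partial likelihood; variance either model-based or a
  cluster-grouped sandwich built from score residuals (validated against
  lifelines' `cluster_col` robust variance to 4+ digits).
* **Lognormal frailty**: penalised partial likelihood with a normal
  cluster intercept; the variance `theta` is profiled with the
  Laplace/REML-type fixed point `theta = (b'b + tr V_bb)/K`, accelerated by
  Aitken extrapolation. Collapse below 1e-5 returns a plain Cox fit with
  variance 0.
* **Gamma frailty**: penalised Newton with the gamma penalty
  `(b - e^b)/theta` (whose stationary point is the EM estimate), and
  `theta` chosen by golden section on the EM profile (observed-data)
  likelihood with the Breslow baseline profiled out. The `theta -> 0` limit
  of that profile is the plain partial likelihood minus the event count
  (since the Breslow baseline makes the cluster hazard totals sum to the
  event count), which is the collapse criterion.

Convergence: Newton stops on score sup-norm < 1e-6 or relative objective
change < 1e-9, 50 iterations max; the frailty outer loops stop on relative
`theta` change < 1e-4 (lognormal) or a log-theta bracket < 1e-3 (gamma).
Both inner solvers were checked against `survival::coxph` with
`frailty.gaussian` / `frailty.gamma` at fixed `theta` (agreement ~1e-4 on
the coefficient); free-`theta` estimates agree to the precision the
different outer criteria allow. Wald tests throughout. Degenerate
replicates (no events, constant covariate, single cluster for a frailty
variance) raise a fit error and are excluded from summaries with a count.

## Replication engine and summaries

Per scenario: `reps` independent replicates, each a fresh cohort, one
trial, all requested methods. Summaries per method: mean estimate,
percentage bias `100 (mean - beta)/beta`, a 95% CI from
`se(mean) = sd/sqrt(reps)`, empirical SE (SD of replicate estimates), and
power (fraction of Wald p < 0.05). A printed formula dividing the SD by the
replicate *count* rather than its square root is treated as a typo — with
the literal reading the CI would be degenerate. Scenarios with > 20% failed
replicates are flagged invalid. Grids expand a flat INI config
Cartesian-wise (zero-tier sign duplicates collapsed — the zero tier has no
orientation, so a "24-panel" layout with the zero tier shown under both
signs corresponds to 21 distinct scenarios), derive one deterministic seed
per scenario from the base seed, and write results incrementally with
resume support; a JSON manifest (config hash, seeds, version) makes result
tables reproducible byte-for-byte.

## Sample size by simulation

No closed-form sample-size formula covers informatively censored clustered
survival data, so the required size is searched by simulation: for
candidate K (N = 620 K, 4:1 allocation), simulate trials with
*non-informative* refusal at the assumed rate (Bernoulli per subject,
zero-correlation tier), analyse with ITT (lognormal frailty by default),
and take the smallest K whose empirical power reaches 0.8 at alpha 0.05.
Recruitment method 1 assumes no refusal; method 2 plugs in an assumed rate.
A pilot at moderate K estimates the attenuated effect and its empirical SE;
the normal approximation with `se ~ 1/sqrt(K)` brackets K, and bisection at
single-cluster granularity finishes the search. All candidates share one
random-number stream, so the minimality decision is taken on a
deterministic, near-monotone power curve rather than independent noise.
`update_sample_size` re-runs the search at an observed refusal rate, for
interim sample-size revision. At the default constants and zero refusal the
search lands around K ~ 114 (N ~ 70,000) with realised power just above
0.8; the realised value sits above the 0.8 target because K is the first
candidate to clear it (with 1000-replicate estimates this overshoot is the
"0.83 rather than 0.80" effect; fewer replicates widen it).

## Problem sizes and Monte-Carlo tolerances

Bias checks run at a reduced cluster count, K = 25, where the expected
percentage bias is essentially the large-N value but each replicate's ITT
estimate has SD ~ 0.24 (driven by the five intervention clusters' random
effects; the IV estimates are noisier still). A 300-replicate mean
therefore carries ~4.3 bias points of Monte-Carlo error for ITT and ~6 for
2SRI; test tolerances are set at 2-2.5 times these SDs, and all scenarios
in a comparison share one seed stream (common random numbers) so that
cross-scenario contrasts — bias growing with refusal, minima/maxima over
correlation settings — are decided by the refusal mechanism rather than by
independent cluster noise. The acceptance script uses 300 replicates per
grid scenario and 1500 for the high-refusal corner (a single scenario is
cheap enough to run at higher precision); the test suite runs the
negative-correlation scenarios (the published range statements) at the same
replicate count. The design-power check runs the full search at 100
replicates per candidate K, which adds ~0.04 binomial noise to the realised
power; its acceptance band is widened accordingly.

## What the synthetic cohort does not capture

Constant cluster size (variable size mainly perturbs power, not bias),
homogeneous treatment effect (no complier-average machinery; with
heterogeneous effects the IV estimand changes), no staggered entry or
loss to follow-up beyond death and the 3-year horizon, no covariates beyond
the two random effects, and a single trial per cohort. Passing tests show
the estimators behave as theory predicts *under this generative model*;
they say nothing about refusal mechanisms that do not operate through a
rank-linear function of baseline risk.
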