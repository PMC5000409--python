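# cmrctsim

Simulation engine for **cluster cohort-multiple randomised controlled
trials (cmRCT)** with treatment refusal: how badly do refusals bias the
estimated treatment effect, which analysis repairs it, and how many
clusters does the trial need?

In a cmRCT a standing cohort (here: primary-care patients at elevated
cardiovascular risk, clustered by practice) supplies both arms: whole
clusters are randomised 4:1 usual-care:intervention, and the intervention
is *offered* to the selected clusters. Refusal happens after
randomisation — by the patient or by the clinician — and is often
correlated with the patient's underlying risk, which biases naive analyses
and drains power.

## Model

Per subject *i* in cluster *k*, with individual and cluster random effects
`eps_ik ~ N(0, 0.6)` and `U_k ~ N(0, 0.2)` shared between processes:

* CVD event time: hazard `h_c(t) e^(beta X_ik + eps_ik + U_k)` with Weibull
  baseline `h_c(t) = gamma_c t^(gamma_c-1)/lambda_c^gamma_c`,
  `gamma_c = 1.2`, `lambda_c = 36`; treatment effect `beta = -0.32`
  (hazard ratio 0.73, ~25% mean reduction in 10-year risk).
* Mortality (informative censoring): same form, `lambda_m = 55`, no
  treatment term; follow-up truncated at `T_max = 3` years.
* Refusal probabilities are assigned rank-linearly over the counterfactual
  10-year risk `r_ik = 1 - exp(-(10/lambda_c)^gamma_c e^(eps_ik + U_k))`,
  between limits `(LL, UL) in {(p,p), (2p/3,4p/3), (p/3,5p/3), (0,2p)}`
  (zero/low/medium/high correlation tiers, either sign).

Each simulated trial is analysed by **ITT**, **per protocol**, and the
two-stage instrumental-variable estimators **2SPS** and **2SRI**
(allocation as instrument), on top of a marginal (cluster-robust),
lognormal-frailty, or gamma-frailty Cox model. A replication engine
summarises percentage bias `100(mean(beta_hat) - beta)/beta`, empirical SE
and power, and a simulation-based search returns the smallest number of
clusters reaching 80% power, with or without an assumed refusal rate
factored in. See `docs/methods.md` for the full model and numerical
details.

## Worked example

Simulate one trial (25 practices of 620 patients, patient refusal 0.2
concentrated in the *lowest*-risk patients) and analyse it:

```sh
$ cmrct simulate --config examples/example.cfg --seed 7 --export trial.csv
wrote trial.csv: N=15500, events=1093
$ cmrct analyse --data trial.csv --methods itt,pp,2sps,2sri --model lognormal
method      coef       se        p  n_used  converged
   ITT -0.134521 0.309993 0.664326   15500       True
    PP -0.043569 0.304258 0.886133   14911       True
  2SPS -0.166075 0.382708 0.664326   15500       True
  2SRI -0.186137 0.378899 0.623244   15500       True
```

`coef` is the log hazard ratio. One 25-cluster trial is dominated by
cluster-level noise (SE ~ 0.31 against a true effect of -0.32) — that is
exactly why conclusions come from replication. Running 100 replicates per
scenario:

```sh
$ cmrct grid --config examples/grid_example.cfg --out results.csv
```

| scenario (p = 0.2) | method | mean beta | % bias [95% CI] | power |
|---|---|---|---|---|
| zero tier | ITT | -0.231 | -27.9 [-41.4, -14.4] | 0.19 |
| zero tier | 2SRI | -0.300 | -6.2 [-23.1, +10.7] | 0.19 |
| high tier, negative | ITT | -0.257 | -19.7 [-34.5, -5.0] | 0.17 |
| high tier, negative | 2SRI | -0.340 | +6.3 [-12.9, +25.5] | 0.19 |

ITT is diluted by a fifth to a quarter (refusers in the intervention arm
never receive the treatment), while 2SRI recovers the effect of *accepting*
the treatment to within Monte-Carlo error; power at 25 clusters is far
below the 0.8 a powered design (~114 clusters at zero refusal) achieves.
`cmrct samplesize --refusal 0.2` searches for that powered size with the
refusal rate factored in, and `cmrct report` renders bias/power panels
from a grid table.

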