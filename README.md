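# owlsurv

Bayesian seasonal survival analysis for radio-tracked juvenile birds, built
around the **Cormack–Jolly–Seber (CJS) mark–recapture model** with biweekly
encounter occasions, season-specific survival intercepts, a snow-cover
covariate, and tracking-effort-stratified detection.

The package targets the demography of juvenile little owls (*Athene noctua*)
— roughly 300 fledglings radio-tagged across three annual cohorts and
followed from fledging in early summer through natal dispersal, winter, and
their first breeding spring — but every component (time axis, weather
covariates, likelihood, sampler, derivations) is generic for staggered-entry
telemetry studies with discrete occasions.

## The model

Encounter histories `y[i,t] ∈ {0,1}` over 14-day occasions are modelled
conditional on each bird's first release occasion `f_i`:

```
logit φ[i,t] = α_season(t) + β_snow · x_t + β_mass · m_i · 1[t ∈ S_mass]
               + β_sex · sex_i · 1[t ∈ S_sex] + β_fed · fed_i · 1[t ∈ S_fed]

p[i,t] = 0                                          if effort(t) = none
logit p[i,t] = logit(p_regime(t)) + β_snow,p · x_t + ε_i   otherwise
```

where `x_t` is the standardised count of days with ≥ 1 cm snow cover in
occasion `t` (zero outside winter), `S_·` are season masks (by default body
mass and nestling supplementary feeding act only on the summer post-fledging
period, sex year-round), `p_regime` is a full- or reduced-effort detection
baseline, and `ε_i ~ N(0, σ)` captures individual detection heterogeneity.
The likelihood is the exact marginal CJS likelihood (forward algorithm over
the latent alive/dead chain), verified in the tests against brute-force
enumeration over death times.

Inference is MCMC with mildly informative priors — Beta(95, 10) on each
seasonal baseline survival, Uniform(0.7, 1) and Uniform(0.3, 0.9) on the
detection baselines, Normal(0, 1) coefficients, half-Normal(1) on σ — with
rank-normalised split R-hat diagnostics and a posterior predictive check
(Freeman–Tukey discrepancy on a season-pooled m-array).

Derived demography: seasonal survival (biweekly survival powered by season
length: summer 4, autumn 6, winter 10, spring 6 biweekly periods), annual
survival (product over the 26-period year), harsh-winter scenarios (60 snow
days across the 10 winter occasions vs none), the seasonal partition of
first-year mortality, and 26-period cohort trajectories — all computed per
posterior draw, then summarised as medians with 95% credible intervals.

## Worked example

```python
import numpy as np
import owlsurv as o

# synthetic study-scale dataset with known truth (300 birds, 79 occasions)
data, truth, individuals = o.simulate_study_dataset(seed=1)

samples = o.sample_posterior(
    data, mcmc=o.MCMCSettings(n_chains=2, n_iter=1000, burn_in=400, thin=2), seed=101
)
from scipy.special import expit
for s in o.SEASONS:
    med = np.median(expit(samples.flat(f"alpha_{s}")))
    print(f"biweekly survival {s}: {med:.3f}  (truth {truth.truth_dict()['baseline_survival'][s]:.3f})")
print("snow effect:", np.round(np.median(samples.flat("beta_snow_surv")), 3))
```

prints (seeds as above):

```
biweekly survival summer: 0.840  (truth 0.844)
biweekly survival autumn: 0.939  (truth 0.936)
biweekly survival winter: 0.953  (truth 0.956)
biweekly survival spring: 0.952  (truth 0.945)
snow effect: -0.544
```

i.e. the fit recovers the generating seasonal biweekly survival
probabilities and the negative effect of snow-cover duration on winter
survival (generating value −0.389, here estimated from one dataset; the
winter intercept refers to survival at *average* winter snow under the
default covariate scaling — snow-free winter survival is the derived
quantity `expit(α_winter + β_snow·z(0))`). Derived tables follow with

```python
derived = o.derive_demography(samples, data.snow_scaling)
print(derived.summary_annual("mild"))   # {'median': 0.193, 'lo95': 0.138, 'hi95': 0.265}
print(derived.summary_annual("harsh"))  # {'median': 0.091, 'lo95': 0.05, 'hi95': 0.143}
```

A command-line pipeline wraps the same functions:

```bash
owlsurv simulate --seed 1 --out-dir simdata
owlsurv fit simdata --seed 2 --chains 3 --out-dir fit
owlsurv derive fit --out-dir derived
owlsurv report derived --out trajectory.png
```

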