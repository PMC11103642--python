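# Methods

## Model

`owlsurv` implements a Cormack–Jolly–Seber (CJS) mark–recapture model for
radio-tracked juvenile birds observed over consecutive 14-day ("biweekly")
encounter occasions. The model conditions on each individual's release
occasion and estimates apparent biweekly survival φ and detection p jointly;
mortality and permanent emigration are confounded, as in any CJS analysis.

**Survival.** On the logit scale, survival over the interval from occasion
*t* to *t*+1 is a seasonal intercept (summer / autumn / winter / spring)
plus a snow covariate and individual covariates:

- `α_season` — four intercepts: biweekly survival of an average-mass,
  unfed female at zero snow covariate.
- `β_snow` — effect of the standardised per-occasion count of days with
  ≥ 1 cm snow cover (a proxy for food inaccessibility in winter).
- `β_mass`, `β_fed`, `β_sex` — effects of age-corrected standardised body
  mass, nestling supplementary feeding, and sex, each gated by a *season
  mask*. Default masks restrict mass and feeding to summer (the
  post-fledging period) and let sex act year-round; a second formulation
  with mass/feeding in every season is available via
  `SeasonMask.all_seasons()`. The fitted masks are recorded in the run
  manifest.

The interval *t* → *t*+1 uses occasion *t*'s season and snow value. Season
labels come from fixed date windows (summer 15 May–1 Aug, autumn 2 Aug–23
Oct, winter 24 Oct–12 Mar, spring 13 Mar–15 Jun). The deliberate four-week
spring/summer overlap between study years is resolved per bird: overlap
occasions count as summer until the bird's first 2 August and as spring
afterwards (its first breeding season). The occasion grid is anchored at a
configurable origin (default 15 May of the first cohort year) with half-open
14-day intervals; an occasion's season is that of its midpoint.

**Detection.** Detection is structured by known field effort: structurally
zero in occasions without tracking, otherwise an effort-regime baseline
(`p_full` for full effort, `p_reduced` for reduced effort, both on the
probability scale) shifted on the logit scale by the same snow covariate
(possible temporary emigration or reduced trackability in severe weather)
and an individual random effect `ε_i ~ N(0, σ)`. The hybrid
parameterisation — probability-scale baselines with bounded uniform priors,
logit-additive offsets — is forced by the combination of uniform priors on
two regime probabilities and covariate effects on detection.

**Snow covariate.** Daily snow depths (generic CSV or DWD "KL daily" files;
the −999 sentinel maps to missing) are reduced to the per-occasion count of
days with depth ≥ 1 cm. The default standardisation is a z-score over
winter-season occasions only (`winter_snow_scaling`), since snow is
structurally near-zero elsewhere; the covariate entering the predictors is
the standardised value on winter occasions and exactly 0 elsewhere, keeping
the non-winter intercepts clean. Centring at the winter mean matters for
inference, not just interpretation: with an uncentred covariate (all z ≥ 0)
the winter intercept sits at the edge of the design and is strongly
collinear with the snow slope, which inflates and biases both posteriors.
Under the centred default the winter intercept is biweekly survival at
*average* winter snow; snow-free winter survival is the derived quantity
`expit(α_winter + β_snow·z(0))`. Centre and scale are always stored with
the data and the run manifest, because a logit-scale snow coefficient is
meaningless without them. Missing days are an error in strict mode and
count as snow-free in permissive mode.

## Likelihood

The marginal CJS likelihood sums over all death times with a two-state
(alive/dead) forward recursion per individual, conditioning on first
release; individual likelihoods multiply. This is exact and fast, in
contrast to sampling the latent alive matrix by data augmentation, and it
makes the likelihood directly testable: a brute-force enumeration over every
possible death interval (`brute_force_loglik`) serves as an independent
oracle, and the suite checks agreement to 10⁻¹² exhaustively for all
histories of up to 8 occasions and on 1000 random 20-occasion cases.
Occasions with zero effort contribute a factor of 1 whenever no detection is
recorded, so the likelihood is exactly invariant to those cells (verified by
a collapse test that removes them and folds their survival intervals
together). A recorded detection where p = 0 is an impossible datum and
raises an error.

The sampler's inner loop uses a numerically scaled (probability-space)
implementation of the same recursion, cross-checked against the reference
log-space implementation; when numba is available this loop and the
m-array expectation run as JIT-compiled kernels (identical operation
sequence, agreement with the numpy paths is part of the test suite).

## Priors and sampling

Priors (all proper, supports enforced):

| parameter | prior | rationale |
|---|---|---|
| baseline biweekly survival, each season | Beta(95, 10) | mildly informative from prior knowledge of little owl survival; mean 0.905 |
| `p_full` | Uniform(0.7, 1) | full tracking effort is highly reliable |
| `p_reduced` | Uniform(0.3, 0.9) | reduced effort |
| coefficients (`β_·`) | Normal(0, 1) | vague on the logit scale; SD configurable up to 2 |
| `σ` (detection heterogeneity) | half-Normal(1) | weakly informative scale |

The Beta prior is attached to each season's baseline independently; the
prior is placed on the probability scale with the logit Jacobian applied
when evaluating intercepts.

Sampling is blocked adaptive random-walk Metropolis-within-Gibbs:

1. the four season intercepts (joint proposal),
2. the four survival coefficients (joint),
3. `p_full`, `p_reduced`, `β_snow,p` (scalar updates),
4. `σ` via a log-scale walk (no likelihood needed given ε),
5. a joint (σ, ε) *rescaling* move, `ε′ = ε·σ′/σ`, which moves the chain
   along the funnel axis of the hierarchical prior (the ε-prior and
   transform Jacobians cancel exactly),
6. all ε_i in parallel element-wise Metropolis steps — valid because the
   marginal likelihood factorises over individuals.

Proposal scales adapt toward standard acceptance targets (0.25 joint, 0.44
scalar) only during burn-in, so retained draws form a valid Markov chain.
Initial values: baselines from the Beta prior, coefficients and ε at zero,
detection baselines from their uniform priors. Defaults are 3 chains ×
3500 iterations, burn-in 200, thinning 6 (550 retained draws per chain);
every run records sampler, settings, priors, masks and seed in its
manifest. Given a seed, runs are exactly reproducible (each chain gets an
independent child stream). With an empty dataset the sampler explores the
prior, which doubles as the prior-sensibility check.

Convergence is assessed with rank-normalised split R-hat (via ArviZ),
flagging parameters at R-hat ≥ 1.02. The detection-heterogeneity scale σ is
the slowest-mixing parameter — it is weakly identified when detection is
near one — and can need longer chains than the survival parameters.

## Posterior predictive check

Goodness of fit uses a Freeman–Tukey discrepancy on the m-array (releases ×
first-recapture occasion), aggregated into (release season-block) ×
(recapture lag 1 / 2 / ≥3 / never) cells. Aggregation matters: at occasion
resolution most m-array cells have expectations far below one, and the
statistic is then dominated by placement noise that no model parameter
tracks, which destroys the calibration of the check. The pooled cells map
directly onto model structure — detection level, missed-detection rate, and
season-specific mortality — so the posterior can absorb dataset-level
fluctuations and the p-value is conservative for well-specified data, while
retaining power against structural misfit (a wrong effort layout shifts
detections from lag 1 to lags 2–4 and is flagged at p ≈ 0).

Because the model carries unit-level random effects that are weakly
identified, the check is a *mixed* posterior predictive check: replicates
draw fresh ε from N(0, σ_draw), and both the observed and the replicate
m-array are compared against expectations built from the ε-marginalised
detection probabilities (Gauss–Hermite quadrature, 21 nodes). Conditioning
on the estimated (shrunken) ε would treat observed and replicated data
asymmetrically and bias the p-value low. Ties count toward the upper tail;
the Bayesian p-value is P(D_rep ≥ D_obs) over (a sub-sample of) retained
draws.

## Derived demography

All derived quantities are computed per posterior draw and only then
summarised (median, central 95% interval); summarising first would bias
non-linear transforms. Season lengths are summer 4, autumn 6, winter 10,
spring 6 biweekly periods (26 = one annual cycle, 1 July–30 June):

- season survival = biweekly survival ^ season length;
- winter scenarios: a composition of per-period snow days for the 10 winter
  periods — mild = all zero; harsh = (12, 12, 8, 8, 8, 4, 4, 4, 0, 0),
  i.e. two extreme, three high, three intermediate and two snow-free
  periods totalling 60 of 140 winter days (43%) under snow. The class
  structure and the 60-day total are fixed by the harshest observed winter;
  the per-class day counts are a documented configuration default;
- annual survival = product of the four seasonal survivals;
- mortality partition: share of first-year deaths falling in season *k* =
  (survival through seasons 1..k−1) × (1 − S_k) / (1 − S_annual) × 100;
- cohort trajectories: deterministic multiplication of 100 birds through
  26 scenario-specific biweekly survival values per draw;
- relative change between scenarios = 100 × (reference − alternative) /
  reference.

Percentages are reported to one decimal and probabilities to three.

## Synthetic data generator

The generator emulates the study design with known truth: three annual
cohorts of ~100 radio-tagged fledglings in broods of 1–5 siblings (sizes
weighted toward 3–4), tagging dates shared within broods and drawn from a
normal centred on 10 June (SD 14 days, truncated 15 May–15 July),
brood-level supplementary feeding with probability 0.5, fair-coin sex, and
standard-normal age-corrected mass. The occasion grid is 79 biweekly
occasions from 15 May of year one (just over three years); four occasions
have no tracking effort and six reduced effort, placed in the first and
second winters as in the field campaign. Daily snow is a two-state Markov
chain active November–March (onset 0.06/day, persistence 0.82, depth
1 cm + Exp(5 cm)), giving ≈ 25% snow-day frequency with strong
between-winter variation — from nearly snow-free to the harsh 60-day
regime observed in the study region. Generating parameter defaults are the
published posterior medians (biweekly survival 0.844 / 0.936 / 0.970 /
0.945; snow −0.389; mass 0.480; sex 0.153; feeding 0.345; detection
0.994 / 0.803; snow-on-detection −0.229) with σ = 0.5 for detection
heterogeneity (not reported for the original study; a moderate value).
The stated winter survival 0.970 refers to a *snow-free* winter occasion;
since the covariate is centred on the dataset's winter mean, the generator
shifts its winter intercept by `β_snow·centre/scale` so the predictor
still evaluates to logit(0.970) at zero snow days, and records the shifted
intercept as the truth.

Deliberate simplifications, hence limits of what passing tests show about
real data: survival has no brood random effect (matching the fitted model,
which has none), feeding occurs in all three cohorts rather than the last
two, there is no tag-failure process (battery life exceeded the tracking
window), no movement or emigration process, and censoring occurs only at
the calendar end. Tagging-date stagger and brood sizes are plausible
stand-ins where no empirical distributions are available.

## Test and script problem sizes

The parameter-recovery and predictive-check studies fit 20 study-scale
synthetic datasets (300 birds × 79 occasions) with 2 chains × 1000
iterations (burn-in 400, thinning 2), a deliberately short but adequate
chain length for interval coverage; the acceptance script's single
pipeline run uses 3 chains × 2500 iterations (burn-in 500, thinning 4).
Coverage is assessed for the four seasonal intercepts and the snow effect
at the 95% level over the 20 fits; the snow-effect direction check uses the
median across fits of P(β_snow < 0).

## Known limitations

- σ mixes slowly when detection is near one; its R-hat can exceed 1.02 at
  short chain lengths while survival parameters are well converged.
- Apparent survival confounds mortality with permanent emigration.
- The snow coefficient's numerical value is tied to the stored covariate
  scaling; comparisons across datasets require rescaling.
- The m-array pooling (season-block × lag) is one defensible omnibus
  choice; statistics targeted at other failure modes (e.g. individual
  heterogeneity in survival) would need different discrepancies.
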