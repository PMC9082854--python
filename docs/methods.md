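# Methods

## The estimation problem

Households in a system with near-universal mandatory health coverage decide
whether to buy a voluntary private health insurance (VPHI) plan on top of it.
An expenditure survey records, per household, the monthly amount spent on
such plans (zero for most households), household income, and a set of
characteristics of the household and its head. The quantity of interest is
the price elasticity of take-up: by how much the share of participating
households falls when premiums rise by 1%.

Two features of the data make a naive probit of participation on the
observed premium wrong:

1. **Selection** — the premium is observed only for purchasers, and
   purchasers are a self-selected, atypical slice of the population.
2. **Endogeneity** — unobserved taste and risk factors move both the premium
   a household would face and its willingness to buy (in the model below,
   `corr(u, eps) = rho != 0`).

## Model

Participation follows a probit:

    vphi_i = 1  iff  beta0 + beta1*ln(p_i) + beta2*ln(y_i) + X_i'gamma + eps_i > 0,
    eps_i ~ N(0, 1)

with premium `p_i`, income `y_i`, and controls `X_i` (head's gender, age
group, education; member over 65; income level; region fixed effects). The
premium itself satisfies a log-linear pricing equation on the wider design
`Z_i = {X_i, ln(y_i), m_i}`:

    ln(p_i) = Z_i'delta + u_i,     u_i ~ N(0, sigma_u^2)

where `m_i`, the number of household members, is the **instrument**: family
plans charge per covered member, so household size moves the bill, but —
the exclusion restriction — size affects the purchase decision only through
the premium.

Estimation proceeds in three stages:

1. **Reduced-form probit** of `vphi` on `Z` (maximum likelihood,
   Newton iterations with step-halving, convergence at score max-norm 1e-8,
   separation flagged at |standardized coefficient| > 25).
2. **Selection-corrected price equation**: OLS of `ln(p)` on `Z` and the
   inverse Mills ratio `lambda_i = phi(q_i)/Phi(q_i)` at the stage-1 fitted
   index `q_i`, over purchasers only. The Mills coefficient estimates
   `cov(u, xi)/sd(xi)` with `xi = beta1*u + eps` the reduced-form error
   (`rho*sigma_u` in the pure-selection case `beta1 = 0`). `lambda` is
   computed as `sqrt(2/pi)/erfcx(-q/sqrt(2))`, stable in both tails.
3. **Fitted-value structural probit**: probit of `vphi` on
   `{1, Z'delta_hat, ln(y), X}`. Replacing the premium by its stage-2
   prediction removes the correlation with `eps`; household size stays out
   of this design, which is what identifies `beta1`. (A linear-probability
   2SLS second stage exists behind `method="lpm2sls"` for comparison runs
   only.)

Semi-elasticities are probit average marginal effects,
`AME(v) = mean_i phi(x_i'beta_hat) * beta_v`, and elasticities divide by the
take-up share: `eps_p = AME(p)/E[vphi]`, `eps_y = AME(y)/E[vphi]`.

**Scale caveat.** A fitted-value probit identifies coefficients up to
`s = sd(eps + beta1*u) = sqrt(1 + beta1^2 sigma_u^2 + 2 beta1 rho sigma_u)`,
because the unprojected part of the premium, `beta1*u`, folds into the error.
Under the default synthetic calibration `s = 0.917`, so the estimated price
coefficient converges to `-1/0.917 = -1.09` when the truth is -1. AMEs and
elasticities inherit only part of this distortion (the density term
re-normalizes); the recovery tests use tolerances wide enough to see bias
that matters against sampling spread, not this bookkeeping factor.

## Inference

The structural probit consumes a generated regressor (`Z'delta_hat`), so
single-stage analytic standard errors are invalid. All reported uncertainty
comes from a nonparametric household bootstrap that re-runs every stage per
resample (default B = 200); p-values are two-sided normal-approximation
tests of zero. Replicates failing to estimate (separation, lost covariate
variation) are dropped and counted; more than 20% failures aborts inference.

## Data rules

- **Truncation**: reported premiums below the 30 USD/month cut-off are
  treated as misclassified non-premium insurance payments (product-linked
  policies, school-emergency policies) and those households are **dropped**
  (not recoded as non-participants): their true status is unknown. The
  comparison is inclusive (`premium >= threshold` participates) and the
  threshold is a config parameter; `threshold = 0` disables truncation.
- **Restrictions**: reporting columns for the full sample, non-informal
  heads (informal workers lack the mandatory-scheme membership VPHI
  presupposes), and middle-income-or-higher households (defined by the
  income-level categorical). Dummy matrices are rebuilt after restriction so
  lost category levels do not produce rank-deficient designs.
- **Currency**: COP amounts convert at a configurable rate (2,951 COP/USD
  for the survey period); the threshold is always in USD.
- **Heterogeneity**: one refit per grouping variable (head's age group,
  member over 65, child under 5) with the fitted log premium *and* log
  income interacted with the group dummies; per-group AMEs average the
  density over that group's rows and per-group elasticities use the group's
  own take-up share. Run on the truncated non-informal sample. Group
  equality is tested pairwise on bootstrap replicates of the group AMEs.

## The synthetic survey

The generator draws covariates with marginals loosely matched to an urban
household budget survey (head male 0.58; age groups 0.12/0.20/0.21/0.47;
education 0.50/0.28/0.22; informality 0.19; region shares renormalized over
the five named regions), log income Normal(5.2, 1.3) in USD terms with
income-level categories cut at its 70th/92nd percentiles, and household
size 1 + Poisson(2.5) capped at 10 (mean ~3.5). Errors `(u, eps)` are
bivariate normal with `sd(u) = sigma_u`, `sd(eps) = 1`, correlation `rho`;
the premium is recorded exactly as `exp(ln p)` for purchasers and 0
otherwise. A latent sidecar (true log premium, errors, true index,
contamination flags) accompanies every draw; regeneration from `(params,
seed)` is bit-identical.

Default structural parameters: `beta1 = -1` (elastic demand), `beta2 = 0.6`,
`rho = 0.5`, `sigma_u = 0.2`, `delta_members = 0.40`, intercepts calibrated
by simulation so that take-up is ~4% and the purchasers' mean premium is
~140 USD with ~9% of genuine premiums under 30 USD.

Two calibration choices deserve explanation:

- **sigma_u = 0.2.** Premiums for regulated prepaid-medicine plans are
  largely schedule-determined by observables (age-rated, per-member rates),
  so the idiosyncratic dispersion of log premiums is small. This matters
  statistically: the Mills ratio is nearly linear over the selected sample
  when take-up is rare, so the stage-2 regression separates `delta` from the
  Mills term only weakly, and the sampling noise of that separation scales
  with `sigma_u`. With a large `sigma_u` the two-step estimator is
  honest-to-goodness heavy-tailed at survey-scale n — a real property of
  the method worth knowing.
- **Take-up ~4%.** At the ~0.4-1.5% take-up of the real VPHI market the
  same weak-separation problem leaves `beta1_hat` noisy even at n = 50,000
  (hundreds of purchasers against an 18-column price equation). The default
  sits at the upper end of plausible so that validation measures estimator
  properties rather than noise; users studying the rare-take-up regime can
  lower `beta0` and watch the dispersion grow.

**Contamination** mimics the misreported low-value insurance payments: a
fraction (2% of non-purchasers on average) record a spurious expenditure
uniform on (1, 29) USD. The per-household probability grows with the square
of household size — compulsory school-linked and product-linked policies
are a family phenomenon — which routes the spurious participation through
the instrument and biases the *untruncated* price estimate upward/positive,
the failure mode the truncation rule exists to prevent. Truncation at
30 USD removes every contaminated record by construction.

What the generator does **not** emulate: plan characteristics and quality
(unobserved in expenditure surveys), within-household member-level choices,
survey weights, item non-response, and any correlation between informality
and the covariates (flags are drawn independently). Passing recovery tests
therefore show the estimator works when its assumptions hold — they say
nothing about misspecification on real data beyond the contamination
scenario modeled explicitly.

## Numerical choices

- Probit ML: observed-Hessian Newton with step-halving (the probit
  log-likelihood is globally concave), start at 0, score max-norm tolerance
  1e-8, cap 100 iterations, honest `converged` flag; covariance from the
  expected information. Covariates are standardized internally only for the
  separation check and conditioning; reported coefficients are unscaled.
- Mills ratio via `erfcx` (no tail underflow for |c| < 37); validated
  against Gauss-Legendre quadrature of `E[z | z > c]` to 1e-8 on [-8, 8].
- Stage-2 OLS by `lstsq`; rank deficiencies raise rather than silently
  pseudo-inverting.
- Ties and degeneracies: empty heterogeneity levels are skipped with a
  warning; single-observation groups are flagged untestable; sweep rows
  with under 30 purchasers are flagged `insufficient`.
- All randomness flows from one seed through `SeedSequence` spawning
  (generation, per-restriction bootstraps, heterogeneity bootstraps), so
  reports are replayable byte-for-byte from the manifest.

## Problem sizes used in validation

Parameter recovery: 200 Monte-Carlo replicates at n = 50,000 (uncontaminated,
no truncation). Contamination contrast: 100 replicates at n = 50,000,
threshold 0 vs 30 on the same draw. Bootstrap calibration: 100 outer
replicates at n = 2,500 with B = 200 percentile intervals, on a
raised-intercept (~18% take-up) variant of the default population —
`beta1`, `sigma_u`, `rho` unchanged, so the recovery target is unchanged
(percentile rather than normal-approximation intervals because the
replicate distribution of the price coefficient is left-skewed; the normal
interval's SD is inflated by tail replicates and over-covers). Equality-test size/power: n = 3,000 with
B = 60 on the income panel (a planted price-slope interaction is masked by
the probit scale factor, which saturates the estimable slope at
`-1/sigma_u`; income-slope interactions pass through cleanly).

## Known limitations

- The two-step estimator is weakly identified when take-up is rare and
  `sigma_u` is large; estimates are then heavy-tailed and a per-dataset
  point estimate can sit anywhere near the naive value. The bootstrap SEs
  honestly reflect this (they blow up), but normal-approximation p-values
  should not be trusted in that regime.
- The probit scale factor `s` means structural coefficients are recovered
  up to a known calibration-dependent constant; cross-study comparisons
  should be made on AMEs/elasticities, as the source literature does.
- No survey weights: estimates describe the estimation sample, not the
  national population.
- Bootstrap inference treats households as independent; no clustering at
  region or PSU level.
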