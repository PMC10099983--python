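# Methods

## Population model

The model is female-based with a pre-breeding census and two age classes:
yearlings (age 1) and adults (older). Reproductive output differs between
the classes; the adult class is not subdivided further, so senescence is out
of scope, as are males, density dependence and multiple clutches per season.
"Apparent" survival throughout means survival × site fidelity: death and
permanent emigration are confounded, which is the standard limitation of
single-site mark–recapture.

Expected dynamics follow the 2×2 projection in the README. Immigration
enters as additive counts before the census; the per-capita immigration
rate is defined against the previous year's total female count,
`omega_a[t] = Imm_a[t+1] / Ntot[t]`, which makes annual growth *additive*
in `omega` and gives immigration a sensitivity of exactly 1 in the LTRE —
the same convention the transient-LTRE literature uses for survival.

### Realized-rate decomposition

`lambda_decomposed` is exact, not approximate, when fed realized per-capita
components. The components are defined so the products telescope to counts:
realized `pNS` is the fraction of eggs escaping complete nest failure,
realized `sN_a = fledged_a / (eggs_a · pNS)`, and realized
`sJ = recruits[t+1] / (0.5 · fledged_total[t])`, which absorbs the binomial
female-share draw so the fixed 0.5 stays exact. Zero denominators yield
zero components and the identity still holds (their numerators are zero
counts). This identity is the anchor for all three LTRE designs.

## Likelihoods

* **CJS**: individuals ringed as nestlings survive their first interval
  with `sJ[t]` and are yearlings at their first anniversary; everyone else
  uses adult rates. Recapture probability is `pB[a,t] · pCapB[t]`, with
  `pCapB` approximated by the proportion of monitored nests whose female
  was identified. The reference implementation conditions on first capture
  with recursive never-seen-again terms; the sampler uses the equivalent
  m-array multinomial form (the two agree to 1e-8 by test, and to 1e-10
  against exhaustive enumeration over mortality times).
* **Clutch size**: plain Poisson on clutches of known-age mothers. At six
  to seven eggs the zero-truncation correction is ~1e-3 and ignored.
* **Nest fate**: mixture folding complete failure and all-egg loss into the
  zero-fledged outcome: `P(f=0) = (1-pNS) + pNS (1-sN)^clutch`; successful
  nests contribute `pNS · Binomial(f | clutch, sN_a)`.
* **Counts**: Poisson observations around latent expectations (breeders,
  eggs, fledglings through the fecundity chain; newly ringed adults thinned
  by `pCapB` around the expected immigrant total). Poisson rather than
  deterministic sums keeps the posterior off a measure-zero constraint
  surface. The newly-ringed term starts in year 1: at the study start every
  bird is unringed and no immigration is defined for year 0.
* **State transitions**: local recruits are Poisson around
  `0.5 · sJ · Σ_a N_a F_a`, adult survivors Binomial(Ntot, sA), immigrant
  counts Poisson with a time-constant age mix `q` (the data cannot separate
  immigrant ages; `q` is weakly identified by design and its posterior
  stays close to the prior).

## Temporal variation and covariates

Every vital rate carries a normal year random effect on its link scale
(logit for probabilities, log for clutch size; SD `sigma_year`).
Environmental effects follow the established biology: post-hatch rainfall
and minimum temperature act on nest success and nestling survival;
post-fledging rainfall acts on juvenile survival; clutch size, breeding
probability and adult survival carry no covariates.

Windows are built per population-year: hatch date = first egg + laying days
(one egg/day) + 14 days incubation; the post-hatch window is ±8 days around
the 0.25 quantile of hatch dates (17 days; linear-interpolation quantile
rounded half-down to a whole day); fledging is hatch + 17, and the
post-fledge window spans fledge day to fledge day + 7 inclusive (8 days —
the inclusive convention is a package choice, as "7 days from fledging" is
ambiguous). A year without estimable windows can borrow a donor's windows
via config. Covariates are z-standardized with the sample (n−1) SD;
missing standardized covariates become standard-normal latent parameters
imputed within the MCMC. Missing `pCapB` years take the mean of observed
years (deterministic, applied before sampling).

## Priors and MCMC

Priors are noninformative with biologically sensible upper bounds:
Uniform(0,1) for probabilities and the immigrant age mix, Uniform(0,12) for
mean clutch sizes, Uniform(−5,5) for covariate slopes per SD, Uniform(0,3)
for year-effect SDs, Uniform(0, 2·max(newly ringed)+10) for yearly expected
immigrant totals and discrete-uniform up to 4·max(first clutches)+40 for
the initial abundances. All bounds are overridable in config.

The sampler is single-site adaptive Metropolis-within-Gibbs, compiled with
numba. Latent integer abundances use symmetric rounded-normal random walks
(zero steps deflected to ±1 with equal probability, preserving symmetry).
Proposal scales adapt in batches of 50 during burn-in towards ~0.44
acceptance and are frozen afterwards, so the retained chain satisfies
detailed balance. Likelihood deltas are component-local; for the CJS
m-array a change at year *t* only touches release cohorts that can reach
year *t*, which roughly halves the dominant cost. Initial values are
simulated (data-informed latent states, moderate rates) and redrawn until
the joint density is finite, up to 100 retries. Chain *c* uses seed
`base + c`; runs are bit-identical under a fixed config.

Defaults mirror a full production run (4 chains × 200,000, 50,000 burn-in,
thin 30); the `test_profile` (3 × 20,000, 5,000 burn-in, thin 10) is what
the simulation studies and the acceptance script use, sized so a 40-year
fit takes about a minute. Convergence is summarized by the Gelman–Rubin
statistic `R̂ = sqrt(((n−1)/n·W + B/n)/W)` with a 1.1 threshold; a
leave-one-out heuristic flags a single non-converging chain, and flagged
chains are excluded from summaries.

## Model testing

Three complementary checks, since no global goodness-of-fit test exists for
integrated models: (1) posterior-predictive tables of every count stream
with 95% intervals and empirical coverage; (2) single-component fits (CJS
alone, clutch model alone, nest-fate model alone) with the same likelihood
and priors, aligned to the integrated manifest for overlap comparison;
(3) stochastic forward projection from posterior-median rates with
demographic Binomial/Poisson noise.

## Transient LTREs

* **Random design**: contributions of among-year (co)variation to
  `var(lambda_t)`: `c_i = Σ_j cov(θ_i, θ_j) s_i s_j`, sample (n−1)
  covariances, sensitivities at the temporal mean. The total equals
  `sᵀΣs` exactly and tracks the sample variance of `lambda_t` to first
  order (within 10% at CV ≤ 0.1 in tests).
* **Fixed design**: `c_i = Δθ_i · s_i` per year step. Sensitivities are
  evaluated at the span mean; for a single step that is the midpoint of the
  two years, which cancels the second-order error (growth is multilinear in
  the components), keeping the total within 5% of the true `Δlambda` at
  ≤10% simultaneous perturbations.
* **Period design**: contributions of changes in component means and SDs
  between two equal-length periods to `Δ log lambda_g`, via real-time
  elasticities computed numerically: perturb the within-period values
  (mean: scale by 1+ε; SD: scale deviations by 1+ε; ε = 1e-4, first-order
  stable under halving), re-propagate age structure through the
  realized-rate recursion, and difference `log lambda_g`. The direct part
  freezes the structure path at the baseline; the structure-mediated
  (indirect) part is the remainder. Elasticities are averaged over the two
  periods — the reference point is genuinely open, and the sum identity to
  `Δ log lambda_g` (within 10% at ≤20% mean shifts) anchors the choice. A
  component whose SD is zero in exactly one period has its sigma term
  flagged missing and excluded with a warning; equal SDs contribute zero.

Posterior LTREs run the chosen design per retained draw, with rates from
the draw's link models and `omega`/structure from its latent states, and
summarize contributions by the standard grouping (reproduction = breeding
probability, clutch size, nest success, nestling survival; survival =
juvenile + adult; immigration; structure).

Note one deliberate asymmetry: growth is monotone non-decreasing in all 11
rate components but *not* in the yearling share `n_Y`, whose sensitivity
`0.5·sJ·(F_Y − F_A)` is negative whenever adults are the more fecund class.

## Synthetic data

The generator tracks individual females through breeding, ringing,
survival, recapture and immigration, and emits the exact CSV dialects the
readers parse. Defaults describe a flycatcher-like life history: single
brood, adult clutch 6.5 eggs (yearlings 6.0), breeding probability 0.9
(adults) / 0.65 (yearlings, first breeding often delayed), nest success
0.85, per-egg survival 0.9/0.85, apparent survival 0.45 (adult) and 0.10
(juvenile), year-effect SDs ~0.2–0.3 on the link scale, negative rain
effects (−0.3 per SD) on nest success, nestling survival and juvenile
survival, and a per-capita immigration rate of 0.35 with yearling share
0.15 — chosen so immigration balances the local deficit and mean annual
growth sits near 1 (realized 1.01 ± 0.02 across replicates at the default
40 years × 150 boxes, the dimensions of a mid-sized long-term study).
Weather is a seasonal sinusoid + AR(1) for minimum temperature and
Bernoulli–Gamma rainfall; the generating link models standardize window
covariates with fixed long-run constants of that process, while the
analysis re-standardizes empirically — a deliberate, realistic mismatch
that stays well inside posterior uncertainty over a 40-year study.

Further realism the observation model does not capture: 5% of nestlings go
unringed, so a few local recruits are later counted as immigrants; newly
ringed adult counts include previously unidentified immigrants identified
in a later year. Both inflate immigrant counts mildly relative to the
Poisson(`pCapB`·Ω) observation model and are absorbed by the free yearly Ω.
Breeder numbers are not capped at the nestbox count (boxes are assumed
provided in excess, as in the studies this emulates).

What passing tests on these data do and do not show: they validate the
estimator and the LTRE machinery under the model's own assumptions plus the
mild mismatches above; they cannot detect biases from heterogeneous
detection, natal dispersal structure, density dependence or trends in
observer effort, none of which the generator emulates.

## Numerical choices

Probabilities inside likelihoods are floored at 1e-300 before logs; a
degenerate Poisson expectation supports only a zero count (−inf otherwise).
Impossible latent states (negative recruits, survivors exceeding the
previous total) get −inf rather than raising. Quantile rounding is
half-down; growth rates and breeding fractions in years with zero
population are flagged missing (NaN) rather than raising, so
multi-population batch runs survive local extinctions. Covariances in the
random design snap numerically constant components to exact zeros so
"never varies ⇒ zero contribution" holds exactly.
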