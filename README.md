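# nestipm

Integrated population models (IPMs) and transient life table response
experiments (LTREs) for hole-nesting birds monitored in nestbox studies —
built for demographic analyses of species like the pied flycatcher
(*Ficedula hypoleuca*), where decades of nest surveys, ringing data and
annual counts exist but the drivers of population change (local reproduction
vs. survival and dispersal outside the breeding season) are entangled.

The package is aimed at population ecologists who want to fit one coherent
model to the three observation streams a nestbox study produces, estimate
age-specific vital rates with environmental effects, and then ask *which*
demographic pathway — reproduction, survival, immigration or population
structure — drives short-term fluctuations and long-term trends.

## The model

Females are censused pre-breeding in two age classes, yearlings (Y) and
adults (A). From spring *t* to spring *t+1*:

```
[ N_Y,t+1 ]   [ 0.5 F_Y,t sJ_t   0.5 F_A,t sJ_t ] [ N_Y,t ]   [ ImmY,t+1 ]
[ N_A,t+1 ] = [      sA_t             sA_t      ] [ N_A,t ] + [ ImmA,t+1 ]
```

with age-specific fecundity `F_a = pB_a · CS_a · pNS · sN_a` (breeding
probability × clutch size × nest-success probability × per-egg survival to
fledging), apparent juvenile survival `sJ`, apparent yearling/adult survival
`sA`, and immigrant females `Imm` entering before the census.

The joint likelihood integrates:

* an age-structured **Cormack–Jolly–Seber** model for capture histories, in
  which recapture probability factors as `p[a,t] = pB[a,t] · pCapB[t]`
  (`pCapB` = proportion of monitored nests with an identified female), which
  makes breeding probability estimable;
* **Poisson / mixture GLMMs** for individual clutch sizes and nest fates of
  known-age mothers (a zero-fledged nest arises from complete failure with
  probability `1 − pNS` or from losing every egg);
* **Poisson count models** for the annual numbers of first clutches, eggs,
  fledglings and newly ringed adult females, around latent abundances;
* normally distributed **year random effects** on the link scale for every
  vital rate, and rainfall/temperature effects in automatically constructed
  post-hatching and post-fledging windows.

Sampling is by adaptive Metropolis-within-Gibbs (latent integer abundances
are updated natively), fully reproducible under a fixed seed.

Realized growth decomposes additively as

```
lambda_t = n_Y 0.5 F_Y sJ + n_A 0.5 F_A sJ + sA + omega_Y + omega_A
```

(`omega_a` = immigrants per previous-year female), which supplies analytic
sensitivities for the **random-** and **fixed-design** transient LTREs and a
realized-rate recursion for the **period-design** LTRE with numerically
computed real-time elasticities, including immigration and
structure-mediated (indirect) components.

A synthetic-data module simulates complete studies — individual females,
nest records, ringing and recapture, daily weather — from known parameters,
so every claim the package makes is testable without field data.

## Worked example

`examples/03_fit_ipm.py` simulates a 15-year, 80-nestbox study and fits the
integrated model with two chains:

```
parameter          truth   median            95% CrI  R-hat
sA                 0.450    0.449  [ 0.397,  0.513]  1.001
sJ                 0.100    0.111  [ 0.087,  0.145]  1.000
pB_A               0.900    0.914  [ 0.821,  0.964]  1.006
CS_A               6.500    6.567  [ 6.280,  6.886]  1.004
pNS                0.850    0.837  [ 0.800,  0.872]  1.000
sN_A               0.900    0.901  [ 0.878,  0.922]  1.010
beta_rain_sJ      -0.300   -0.361  [-0.716,  0.022]  1.011
```

Each row is a vital-rate parameter: the posterior median and 95% credible
interval recover the generating value (apparent adult survival 0.45,
mean adult clutch 6.5 eggs, a negative effect of post-fledging rainfall on
juvenile survival), and R-hat near 1 shows the chains agree.
`examples/04_transient_ltre.py` then attributes the variance of annual
growth rates to demographic pathways; on a scenario where immigration
carries the among-year variance it reports `immigration 0.02753 (100.0% of
total)` against a directly computed `var(lambda_t) = 0.02752`.

The other examples cover simulation (`01`), the exact growth decomposition
(`02`) and the three-step model-testing procedure (`05`). A thin CLI wraps
the same workflow: `nestipm simulate | fit | diagnose | ltre | project`,
driven by one YAML config.

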