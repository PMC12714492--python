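# tigerocc

Two-scale Bayesian occupancy modelling of tigers (*Panthera tigris tigris*)
and their prey from sign surveys, with a rescue-conflict association
analysis and a seasonality analysis of rescue events.

The package is aimed at wildlife biologists and quantitative ecologists
working with gridded sign-survey designs around protected areas such as
Nepal's Chitwan–Parsa complex: a landscape tiled by large 10 km × 10 km
grids (approximating a tiger home range) subdivided into 2 km × 2 km
subgrids, with tiger and prey sign recorded every 100 m along up to 40 km
of trail per grid.

## The model

Occupancy is modelled at two nested scales with imperfect detection.  With
`logit⁻¹` the logistic function and standardized covariates NDVI
(vegetation greenness), HPD (log₁₀ human population density, floored at the
minimum observed nonzero density of 11 persons/km²) and elevation:

```
Z_i      ~ Bernoulli(ψ_i)          logit(ψ_i)    = b0 + b1·Prey_i + b2·NDVI_i + b3·HPD_i + b4·Elev_i
z^x_ij   ~ Bernoulli(ψ^x_ij)       logit(ψ^x_ij) = β0x + β2x·NDVI_ij + β3x·HPD_ij + β4x·Elev_ij
z^y_ij   ~ Bernoulli(ψ^y_ij)       logit(ψ^y_ij) = β0y + β1y·z^x_ij + β2y·NDVI_ij + β3y·HPD_ij + β4y·Elev_ij
x_ij     ~ Binomial(n_ij, p^x_ij · z^x_ij)           logit(p^x_ij) = d0x + d1x·NDVI_ij + d2x·Elev_ij
y_ij     ~ Binomial(n_ij, p^y_ij · Z_i · z^y_ij)     logit(p^y_ij) = d0y + d1y·NDVI_ij + d2y·Elev_ij
```

`Z_i` is tiger occupancy of grid *i*, `z^x`/`z^y` are prey/tiger *use* of
subgrid *j*, and the detections `x` (prey) and `y` (tiger) are binomial
over the `n_ij` surveyed 100-m segments, *gated* by the latent states so
sign is impossible where the species is absent.  Three gating modes are
provided (`tiger_gated` default, `as_printed`, `both_gated`); see
`docs/methods.md`.

Inference is Metropolis-within-Gibbs with data augmentation: exact
Bernoulli full conditionals for all latent indicators, blockwise adaptive
random-walk Metropolis for the five coefficient blocks under uniform
priors, split-chain Gelman–Rubin R-hat for convergence.  A brute-force
enumeration oracle over all latent configurations validates the sampler on
small instances.

Downstream, posterior use maps are classified high/low against thresholds
(tiger use > 0.54, prey use > 0.80, population > 141 persons/km²) and
cross-tabulated against tiger rescue locations: odds ratios with one-sided
Z-tests on the log odds ratio, Woolf's inverse-variance chi-square test of
odds-ratio homogeneity across population strata (Breslow–Day optional),
and a closed-form least-squares sinusoid (period 12 months) for rescue
seasonality.

## Worked example

Simulate a survey at the default study conditions (62 grids × 25 subgrids,
realistic coefficients), fit it, and summarize:

```sh
tigerocc simulate --seed 3 --out runs/sim
tigerocc fit --survey runs/sim/survey.csv --grids runs/sim/grids.csv \
             --adjacency runs/sim/adjacency.csv --seed 4 --out runs/fit
tigerocc summarize --draws runs/fit --out runs/summary
```

`fit` prints `max R-hat 1.004 (converged)` (about a minute on one core)
and writes the retained draws, convergence table and posterior use maps.  The rescue-conflict
analysis on the packaged buffer-zone tables:

```sh
python -c "from tigerocc.published import write_conflict_fixture; \
           write_conflict_fixture('runs/fixture')"
tigerocc conflict --use-map runs/fixture/use_map.csv \
                  --population runs/fixture/population.csv \
                  --rescues runs/fixture/rescues.csv --out runs/conflict
```

prints

```
tiger_use: OR=2.166 logOR=0.7731 SE=0.5488 Z=1.409 p=0.07944 (greater)
population: OR=1.095 logOR=0.09042 SE=0.5266 Z=0.1717 p=0.4318 (greater)
prey_use: OR=3.812 logOR=1.338 SE=0.6485 Z=2.064 p=0.01952 (greater)
homogeneity (woolf): chi2=6.132 df=1 p=0.01327; stratum ORs low_population=0.3448, high_population=10.98
prey-by-population marginal OR=33.61 (cells 150/71/11/175)
```

Read: subgrids with above-average prey use have 3.8× the odds of containing
a tiger rescue (one-sided p = 0.020); the prey effect is concentrated in
high-population subgrids (OR 10.98), and the odds ratios differ
significantly between population strata (χ² = 6.13, p = 0.013).  Above-
average prey use is itself 33.6× more likely in low-population subgrids.

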