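# Methods

## Survey model

The package models a settlement/plankton survey along a one-dimensional
distance gradient from a larval source. Distance is the only covariate: no
hydrodynamics, currents or directionality enter the model. The elementary
sampling units are the settlement panel (for settlers) and the plankton tow
(for larvae), and all kernel intercepts are expected counts **per unit** —
R₀ is the expected count per panel/tow at the source, R₁ the expected count
per unit at 1 km. Published analyses of this design rarely state the unit of
R; per-unit is the only choice under which the generator, the GLM and the
distance inversion are mutually consistent, and every output (truth
manifests, model reports) records it.

The station inside continuous source habitat is carried at D = 0.05 km rather
than 0: the power-law kernel diverges at the origin, and 50 m is the
effective scale of a station sitting in the source population itself. The
remaining stations sit at 0.5, 5, 15 and 50 km.

## Kernels and likelihoods

Two mean functions: exponential R(D) = R₀e^(βD) and power law R(D) = R₁D^γ.
Both are fit as log-link count GLMs (predictor D or log D) via statsmodels —
`GLM` with a Poisson family, or the `NegativeBinomial` discrete model (NB2,
Var = μ + μ²/θ) with the dispersion estimated jointly by maximum likelihood.
statsmodels parameterises NB2 by α = 1/θ; the package converts and reports θ.
Confidence intervals are 95% Wald intervals on the linear-predictor scale,
exponentiated for the intercept; the distribution's own likelihood
(`count_log_likelihood`, built on scipy's log-pmfs) defines the reported
log-likelihood and AIC = 2k − 2 ln L with k = 2 (Poisson) or 3 (negative
binomial) — the dispersion is counted as a parameter, otherwise
Poisson-vs-NB comparisons by AIC are meaningless. Distances enter in km,
unstandardised.

If the statsmodels Newton fit fails or returns a degenerate solution (it can
when the data are equidispersed and α → 0), the fit falls back to direct
Nelder-Mead + BFGS maximisation of the same likelihood with numerical-Hessian
standard errors. The estimator records which path produced the estimates
(`fit_method_`); tests pin the primary path and verify both against an
independent optimiser.

Preconditions: counts at ≥ 3 distinct distances, not all zero; the power
family requires strictly positive distances; non-convergence raises rather
than returning garbage.

## Distance quantiles and MCMC

D_r is the distance at which the fitted kernel's expectation falls to r
(r = 1 and 0.5 individuals per unit by default): D_r = ln(R₀/r)/(−β) or
(r/R₁)^(1/γ). Point inversion of the MLEs is exact but ignores parameter
uncertainty, so the package also samples the likelihood under improper flat
priors on (log intercept, slope, log θ) — making the posterior the
likelihood, mode at the MLE — with an adaptive random-walk Metropolis
sampler:

- three chains by default, initialised by 2-SE overdispersed jitter around
  the MLE;
- Gaussian proposals with per-parameter scales started at 2.38/√p times the
  Wald SE and adapted every 200 iterations toward ~30% acceptance **during
  burn-in only**, frozen afterwards so the retained chains satisfy detailed
  balance;
- thinning (default 5) applied before recording; the default
  30000 recorded samples per chain minus 10000 burn-in pool to 60000 draws;
- per-parameter Gelman–Rubin R̂ reported with every summary; acceptance rates
  outside [0.05, 0.8] after adaptation are recorded as warnings.

D_r is computed **per draw** and summarised by the pooled median and
2.5/97.5 percentiles — never by inverting median parameters, which differs
as soon as the posterior is skewed (a regression test enforces this).
Draws where the inversion is undefined (slope ≥ 0, or an exponential
intercept below r) are excluded and counted; more than 50% exclusions aborts
the summary. θ is sampled jointly on the log scale for negative-binomial
models; it does not enter the inversion but shapes the likelihood.

## Nested PERMANOVA

For a balanced design (a stations × b islands × n panels) the squared
dissimilarities are partitioned as SS_total = (1/N)Σ_{i<j}d²ᵢⱼ with
within-group terms computed per station and per island, giving the
station / island-within-station / residual decomposition with df
(a−1, a(b−1), ab(n−1)). Station is fixed, island random, so
pseudo-F(station) = MS_station/MS_island and pseudo-F(island) =
MS_island/MS_residual. With Euclidean distances on univariate data this
reproduces classical nested ANOVA to machine precision (tested at 10⁻⁸).

Permutation schemes follow the exchangeability argument for each stratum:
the station test permutes **whole islands** across stations — under the null
of no station effect the island units, which carry the random island
variance, are the exchangeable objects; permuting panels (or within-island
residuals) instead would test against the wrong error stratum and inflate
the type-I error whenever islands vary. The island test permutes panels
among islands within their station. p = (#{F* ≥ F} + 1)/(n_perm + 1), so the
observed statistic is always in the reference set and p ≥ 1/(n_perm+1).
A 500-simulation null calibration at 199 permutations keeps the station
test's empirical size within 0.05 ± 0.02.

Only balanced designs are supported — matching the field practice of
subsampling to equal replication (`balance_design` does this with a seeded
uniform draw and refuses, naming the station, when replication is
insufficient). Univariate counts are treated as length-1 abundance vectors;
Bray–Curtis between two all-zero vectors is defined as 0. Reported
permutation counts are the requested number; no attempt is made to enumerate
the number of *unique* permutations of a small design, so permutation
tallies from software that does will differ even when p-values agree.

## Synthetic surveys

The generator emulates the study conditions: 5 stations at
0.05/0.5/5/15/50 km, 2 islands × 8 panels per station (80 panels), 3 tows
per station, counts per unit drawn Poisson or negative-binomial (mean/size
parameterisation) around the kernel mean, and species confirmation as
independent per-individual binomial thinning. Default per-station
confirmation probabilities (0.08, 0.12, 0.08, 0.04, 0.04) follow the
positive-assay fractions such surveys report. Plankton assays are capped at
50 individuals per station, allocated across the station's tows by a
multivariate hypergeometric draw. Tow geometry defaults to a 2-minute,
3-knot tow with a 0.5 m net (the knot is converted exactly, 1.852 km h⁻¹;
a tow-length override exists to reproduce worked examples that round the
tow length to whole metres first); a zero-duration tow sweeps no water and
forces zero larvae.

What the generator does **not** emulate: spatial correlation between panels
on an island beyond the shared kernel mean, temporal variation in larval
supply, current-driven anisotropy, observer error in counts, or
cross-amplification error in the molecular assay. Passing recovery tests
therefore show the estimator chain is correct and calibrated under the
stated count model, not that field data meet that model.

## Simulation-study sizes and numerical choices

Recovery studies use 200 replicate surveys per scenario and report the
median ML slope — the median, not the mean, because occasional near-flat
replicates produce outlying estimates. Plankton-recovery scenarios raise
replication to 20 tows per station: 15 tows carry too little information for
a stable median of a two-parameter-plus-dispersion fit. Model-selection and
interval-coverage studies use 100 replicates; coverage replicates run
3 × 800 retained draws, which is ample for a 95% interval of a
2–3-parameter posterior. All replicate seeds derive from one master seed via
`numpy.random.SeedSequence`, so every study is exactly reproducible.

Ties in AIC ranking keep declaration order; fits are only comparable when
made on byte-identical data (enforced via a data signature). Degenerate
inputs fail loudly: all-zero counts, repeated distances, zero volumes and
malformed CSVs (errors name the offending row) raise before any statistics
are computed.

## Known limitations

- No zero-inflated or hurdle count models; heavy excess zeros will bias θ.
- Wald intervals can misbehave when the slope is near zero or counts are
  tiny; the MCMC intervals are the better-calibrated summary there.
- The PERMANOVA is univariate-or-multivariate in the dissimilarity only;
  no pairwise post-hoc tests or dispersion (PERMDISP) checks.
- The exponential D_r inversion is undefined when the fitted intercept is
  below r; surveys whose near-source counts are below the threshold cannot
  yield a finite D_r, which is a property of the question, not the code.
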