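# dispersalfit

Estimating how far marine larvae disperse — and still settle successfully —
from field surveys along a distance gradient. The package is built for the
classic settlement-station design: replicate artificial habitat units
("artificial islands" carrying settlement panels) moored at increasing
distances from the only plausible larval source, paired with plankton tows at
each station, with a molecular marker confirming which individuals belong to
the focal species. It targets invertebrates with long-lived pelagic larvae
(weeks in the water column), where counts are sparse, overdispersed, and
decline steeply with distance.

## What it computes

Expected counts *R* per sampling unit (panel or tow) at distance *D* (km)
from the source follow one of two dispersal kernels:

- exponential: R(D) = R₀ · e^(βD), with R₀ the expected count at the source
  and β (km⁻¹) the decline rate;
- power law: R(D) = R₁ · D^γ, with R₁ the expected count at 1 km and γ the
  decline exponent.

Both are log-linear, so each is fit as a log-link count GLM (predictor D or
log D) with Poisson or negative-binomial errors (NB2: Var = μ + μ²/θ, θ
estimated jointly by ML). Models are compared by AIC = 2k − 2 ln L (k = 2 for
Poisson, 3 for negative binomial).

Maximum dispersal distances are summarised by inverting the kernel at
R = 1 (D₁) and R = 0.5 (D₀.₅). Uncertainty is propagated with an
empirical-Bayes MCMC: an adaptive random-walk Metropolis sampler targets the
likelihood under flat priors (three chains, thinned, burn-in discarded), the
kernel is inverted draw by draw, and D_r is reported as the posterior median
with a 2.5–97.5 percentile interval, plus a Gelman–Rubin R̂ per parameter.
The median is used because shallow-slope draws occasionally produce enormous
distances that badly skew the mean.

Station/island structure in the counts is tested with a nested PERMANOVA on
Bray–Curtis dissimilarities (station fixed, island random nested in station),
with pseudo-F(station) = MS_station/MS_island tested by permuting whole
islands across stations and pseudo-F(island) = MS_island/MS_residual by
permuting panels within stations.

A synthetic-survey generator reproduces the study design (5 stations at
0.05/0.5/5/15/50 km, 2 islands × 8 panels per station, 3 tows per station,
binomial thinning for molecular confirmation) with a serialisable truth
manifest, so every stage is testable against known generating parameters.

## Worked example

```python
import numpy as np
from dispersalfit import (KernelTruth, McmcConfig, compare_models,
                          default_design, fit_kernel, gen_settlement,
                          sample_posterior, summarize_distance)

design = default_design()
truth = KernelTruth(family="power", intercept=4.3, slope=-0.31, dispersion=2.0)
survey = gen_settlement(design, truth, seed=12)

d, y = survey.distance_km.to_numpy(), survey.total_gastropods.to_numpy()
fits = [fit_kernel(d, y, fam, err) for fam in ("exponential", "power")
        for err in ("poisson", "negbin")]
print(compare_models(fits).to_string(index=False))

best = min(fits, key=lambda f: f.aic)
cfg = McmcConfig(retained_samples_per_chain=6000, thin=5,
                 burn_in_samples=2000, seed=12)
chains = sample_posterior(d, y, best.family, best.error_family,
                          config=cfg, mle=best)
for r in (1.0, 0.5):
    post = summarize_distance(chains, r)
    print(f"D_{r:g}: median {post.median_km:.0f} km, "
          f"95% CI ({post.interval_km[0]:.0f}, {post.interval_km[1]:.0f}) km")
```

prints

```
 rank      family error_family        aic  delta_aic  best
    1       power       negbin 376.448100   0.000000  True
    2 exponential       negbin 398.172665  21.724565 False
    3       power      poisson 489.990222 113.542122 False
    4 exponential      poisson 594.194167 217.746067 False
D_1: median 95 km, 95% CI (31, 541) km
D_0.5: median 812 km, 95% CI (183, 9413) km
```

The negative-binomial power law wins by a wide AIC margin (the data are
overdispersed and generated from a power law), the fitted exponent
γ̂ = −0.32 (95% CI −0.40 to −0.24) recovers the generating −0.31, and the
wide, right-skewed D_r intervals show how weakly the far tail of a dispersal
kernel is constrained by a 50 km survey: the point summary says roughly one
settler per panel is still expected ~100 km from the source.

The same pipeline is scriptable from the shell:

```sh
dispersalfit simulate --family power --intercept 4.3 --slope -0.31 \
    --dispersion 2 --seed 12 --out-dir out/
dispersalfit fit out/settlement.csv
dispersalfit distances out/settlement.csv --seed 1
dispersalfit permanova out/settlement.csv --seed 1
dispersalfit run --seed 12 --out-dir out/full   # everything, with reports
```

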