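"""Replicated simulation studies: parameter recovery, model selection,
distance-interval coverage.

Each study regenerates synthetic surveys from a stated generating truth at the
survey design, refits the kernels, and aggregates across replicates. Seeds for
the replicates are derived deterministically from one master seed.
"""

from __future__ import annotations

import numpy as np

from .design import KernelTruth, SurveyDesign, TowGeometry, default_design
from .kernels import fit_kernel
from .mcmc import McmcConfig, distance_at_level, sample_posterior, summarize_distance
from .synthetic import gen_plankton, gen_settlement

__all__ = ["slope_recovery", "model_selection_rate", "distance_interval_coverage"]


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def _generate(design: SurveyDesign, truth: KernelTruth, kind: str, seed: int):
    if kind == "settlement":
        df = gen_settlement(design, truth, seed)
        return df["distance_km"].to_numpy(), df["total_gastropods"].to_numpy()
    df = gen_plankton(design, truth, TowGeometry(), seed)
    return df["distance_km"].to_numpy(), df["counted_larvae"].to_numpy()


def slope_recovery(
    truth: KernelTruth,
    n_reps: int,
    seed: int,
    design: SurveyDesign | None = None,
    kind: str = "settlement",
    error_family: str = "negbin",
) -> np.ndarray:
    """Slope (beta or gamma) ML estimates across replicate synthetic surveys.

    Fits the same kernel family the data were generated from; replicates
    whose fit fails are dropped (counted via the returned array's length).
    """
    design = design or default_design()
    out = []
    for s in _replicate_seeds(seed, n_reps):
        d, y = _generate(design, truth, kind, int(s))
        try:
            out.append(fit_kernel(d, y, truth.family, error_family).slope)
        except ValueError:
            continue
    return np.asarray(out)


def model_selection_rate(
    truth: KernelTruth,
    n_reps: int,
    seed: int,
    design: SurveyDesign | None = None,
    kind: str = "settlement",
    error_family: str = "negbin",
) -> float:
    """Fraction of replicates in which AIC prefers the generating family over
    the alternative family under the same error distribution."""
    design = design or default_design()
    other = "power" if truth.family == "exponential" else "exponential"
    wins = 0
    n_ok = 0
    for s in _replicate_seeds(seed, n_reps):
        d, y = _generate(design, truth, kind, int(s))
        try:
            fit_true = fit_kernel(d, y, truth.family, error_family)
            fit_other = fit_kernel(d, y, other, error_family)
        except ValueError:
            continue
        n_ok += 1
        wins += fit_true.aic < fit_other.aic
    if n_ok == 0:
        raise RuntimeError("all replicate fits failed")
    return wins / n_ok


def distance_interval_coverage(
    truth: KernelTruth,
    n_reps: int,
    seed: int,
    r: float = 1.0,
    design: SurveyDesign | None = None,
    kind: str = "settlement",
    error_family: str = "negbin",
    mcmc: McmcConfig | None = None,
) -> dict:
    """Coverage of the MCMC 95% interval for D_r over replicate surveys.

    Returns the empirical coverage of the true D_r, the replicate count used,
    and the median of the per-replicate posterior medians.
    """
    design = design or default_design()
    base = mcmc or McmcConfig(
        retained_samples_per_chain=1200, thin=1, burn_in_samples=400
    )
    true_d = distance_at_level((truth.family, truth.intercept, truth.slope), r)
    seeds = _replicate_seeds(seed, 2 * n_reps).reshape(-1, 2)
    covered = 0
    n_ok = 0
    medians = []
    for s_data, s_mcmc in seeds:
        d, y = _generate(design, truth, kind, int(s_data))
        try:
            mle = fit_kernel(d, y, truth.family, error_family)
            cfg = McmcConfig(
                n_chains=base.n_chains,
                retained_samples_per_chain=base.retained_samples_per_chain,
                thin=base.thin,
                burn_in_samples=base.burn_in_samples,
                seed=int(s_mcmc),
            )
            chains = sample_posterior(
                d, y, truth.family, error_family, config=cfg, mle=mle
            )
            post = summarize_distance(chains, r)
        except ValueError:
            continue
        n_ok += 1
        lo, hi = post.interval_km
        covered += lo <= true_d <= hi
        medians.append(post.median_km)
    if n_ok == 0:
        raise RuntimeError("all replicates failed")
    return {
        "coverage": covered / n_ok,
        "n_reps": n_ok,
        "true_distance_km": true_d,
        "median_of_medians_km": float(np.median(medians)),
    }
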