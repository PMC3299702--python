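"""Distance inversion, Metropolis sampling and convergence diagnostics."""

import numpy as np
import pytest

from dispersalfit import (
    KernelTruth,
    McmcConfig,
    PosteriorChains,
    Station,
    SurveyDesign,
    convergence_statistic,
    distance_at_level,
    fit_kernel,
    gen_settlement,
    sample_posterior,
    summarize_distance,
)


class TestDistanceAtLevel:
    def test_exponential_inversion(self):
        d = distance_at_level(("exponential", 15.5, -0.04), 1.0)
        assert d == pytest.approx(np.log(15.5) / 0.04, rel=1e-10)
        assert d == pytest.approx(68.5, abs=0.1)

    def test_power_inversion(self):
        d = distance_at_level(("power", 4.3, -0.31), 1.0)
        assert d == pytest.approx(4.3 ** (1 / 0.31), rel=1e-10)
        assert d == pytest.approx(110.5, abs=0.2)

    def test_reference_distance_identities(self):
        # r equal to the intercept recovers the kernel's reference distance
        assert distance_at_level(("exponential", 7.0, -0.2), 7.0) == 0.0
        assert distance_at_level(("power", 7.0, -0.2), 7.0) == pytest.approx(1.0)

    def test_non_declining_kernel_rejected(self):
        with pytest.raises(ValueError, match="does not decline"):
            distance_at_level(("exponential", 5.0, 0.01), 1.0)

    def test_unreachable_level_rejected(self):
        with pytest.raises(ValueError, match="not reachable"):
            distance_at_level(("exponential", 0.5, -0.1), 1.0)


class TestMcmcConfig:
    def test_defaults_pool_sixty_thousand(self):
        cfg = McmcConfig()
        assert (cfg.n_chains, cfg.retained_samples_per_chain, cfg.thin,
                cfg.burn_in_samples) == (3, 30000, 5, 10000)
        assert cfg.pooled_samples == 60000

    def test_burn_in_must_leave_samples(self):
        with pytest.raises(ValueError):
            McmcConfig(retained_samples_per_chain=100, burn_in_samples=100)


@pytest.fixture(scope="module")
def big_poisson_chains():
    """Well-behaved case: n = 500 Poisson observations, exponential truth."""
    design = SurveyDesign(
        tuple(Station(f"S{i+1}", d, n_islands=2, panels_per_island=50)
              for i, d in enumerate((0.05, 0.5, 5.0, 15.0, 50.0)))
    )
    truth = KernelTruth(family="exponential", intercept=15.5, slope=-0.04,
                        dispersion=None, id_probability=0.1)
    df = gen_settlement(design, truth, seed=314)
    d = df.distance_km.to_numpy()
    y = df.total_gastropods.to_numpy()
    mle = fit_kernel(d, y, "exponential", "poisson")
    cfg = McmcConfig(retained_samples_per_chain=4000, thin=1,
                     burn_in_samples=1500, seed=99)
    chains = sample_posterior(d, y, "exponential", "poisson", config=cfg, mle=mle)
    return mle, chains


class TestSamplePosterior:
    def test_pooled_count_identity(self, big_poisson_chains):
        _, chains = big_poisson_chains
        assert chains.pooled.shape == (3 * (4000 - 1500), 2)

    def test_flat_prior_posterior_centres_on_mle(self, big_poisson_chains):
        mle, chains = big_poisson_chains
        pooled = chains.pooled
        med_b0, med_b1 = np.median(pooled, axis=0)
        sd_b0, sd_b1 = pooled.std(axis=0)
        # posterior = likelihood, so the median sits at the MLE up to MC error
        assert abs(np.exp(med_b0) - mle.intercept) < 0.25 * mle.intercept * sd_b0
        assert abs(med_b1 - mle.slope) < 0.25 * sd_b1

    def test_chains_converge(self, big_poisson_chains):
        _, chains = big_poisson_chains
        rhat = convergence_statistic(chains)
        assert all(v < 1.1 for v in rhat.values())
        assert chains.warnings == []

    def test_reproducible_for_fixed_seed(self, settlement):
        d = settlement.distance_km.to_numpy()
        y = settlement.total_gastropods.to_numpy()
        cfg = McmcConfig(retained_samples_per_chain=200, thin=1,
                         burn_in_samples=50, seed=5)
        a = sample_posterior(d, y, "power", "negbin", config=cfg)
        b = sample_posterior(d, y, "power", "negbin", config=cfg)
        assert np.array_equal(a.draws, b.draws)


class TestConvergenceStatistic:
    def test_same_distribution_near_one(self, rng):
        chains = rng.normal(size=(3, 20000))
        assert convergence_statistic(chains) < 1.05

    def test_divergent_chains_flagged(self, rng):
        chains = rng.normal(size=(3, 2000)) + np.array([[0.0], [1.0], [5.0]])
        assert convergence_statistic(chains) > 1.2

    def test_identical_chains_at_most_one(self, rng):
        one = rng.normal(size=2000)
        chains = np.stack([one, one, one])
        assert convergence_statistic(chains) <= 1 + 1e-6

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError, match="2 chains"):
            convergence_statistic(rng.normal(size=(1, 100)))


def _chains_from(draws, family="power"):
    draws = np.asarray(draws, dtype=float)
    return PosteriorChains(
        param_names=("log_intercept", "slope"),
        draws=draws, acceptance_rates=(0.3,) * draws.shape[0],
        family=family, error_family="poisson",
    )


class TestSummarizeDistance:
    def test_degenerate_chain_equals_analytic(self):
        draws = np.tile([np.log(4.3), -0.31], (2, 100, 1))
        post = summarize_distance(_chains_from(draws), 1.0)
        analytic = distance_at_level(("power", 4.3, -0.31), 1.0)
        assert post.median_km == pytest.approx(analytic)
        assert post.interval_km == (pytest.approx(analytic), pytest.approx(analytic))
        assert post.n_excluded == 0

    def test_noninvertible_draws_counted_and_excluded(self, rng):
        slopes = np.where(rng.random((1, 1000)) < 0.2, 0.1, -0.4)
        draws = np.stack([np.full((1, 1000), np.log(5.0)), slopes], axis=-1)
        chains = _chains_from(draws)
        chains.draws = np.concatenate([chains.draws, chains.draws])  # 2 chains
        post = summarize_distance(chains, 1.0)
        assert post.n_excluded == int((slopes > 0).sum()) * 2
        assert post.n_pooled == 2000

    def test_mostly_noninvertible_is_error(self):
        draws = np.tile([np.log(5.0), +0.3], (2, 50, 1))
        with pytest.raises(ValueError, match="non-invertible"):
            summarize_distance(_chains_from(draws), 1.0)

    def test_skewed_posterior_median_below_mean(self, rng):
        # shallow-slope draws blow the distance up: right-skewed D_r
        slopes = -np.exp(rng.normal(np.log(0.3), 0.4, size=(2, 5000)))
        b0 = np.full((2, 5000), np.log(4.3))
        post = summarize_distance(_chains_from(np.stack([b0, slopes], axis=-1)), 1.0)
        dr = (1 / 4.3) ** (1 / slopes.ravel())
        assert post.median_km < dr.mean()
        assert post.median_km == pytest.approx(np.median(dr), rel=1e-9)

    def test_per_draw_inversion_differs_from_inverting_median_params(self, rng):
        """D_r must be computed draw by draw; inverting the median parameters
        gives a different (wrong) summary on a skewed posterior."""
        slopes = -np.exp(rng.normal(np.log(0.3), 0.5, size=(2, 4000)))
        b0 = np.log(4.3) + rng.normal(0, 0.3, size=(2, 4000))
        chains = _chains_from(np.stack([b0, slopes], axis=-1))
        post = summarize_distance(chains, 1.0)
        med_params_inv = distance_at_level(
            ("power", float(np.exp(np.median(b0))), float(np.median(slopes))), 1.0
        )
        assert post.median_km != pytest.approx(med_params_inv, rel=1e-3)
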