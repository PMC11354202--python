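"""Sampler tests: truncated-normal priors against scipy, stage-1 greedy
search on a known-optimum toy, stage-2 DE-MCMC against conjugate closed
forms, split R-hat against constructed converged/divergent chains and the
arviz implementation, and posterior-summary bookkeeping."""

import math

import arviz as az
import numpy as np
import pytest
from scipy import integrate, stats

from tvddm import (
    PosteriorDraws,
    PriorSet,
    SamplerConfig,
    TruncNormPrior,
    credible_interval,
    default_priors,
    eap,
    log_prior,
    planned_draw_counts,
    split_rhat,
    stage1_search,
    stage2_demcmc,
)

# --- conjugate normal-normal toy -------------------------------------------
# y_i ~ N(theta, sigma^2) with sigma known; prior theta ~ N(mu0, tau^2)
# (truncation at +-30 is numerically immaterial).  Posterior is
# N(mu_n, tau_n^2) in closed form.
SIGMA_Y = 0.5
Y = np.array([0.61, 0.18, 0.64, 0.43, -0.12, 0.76, 0.35, 0.22, 0.55, 0.41,
              0.13, 0.48, 0.29, 0.67, 0.09, 0.52, 0.38, 0.71, 0.26, 0.44])
PRIOR_TOY = PriorSet({"theta": TruncNormPrior(0.0, 1.0, -30.0, 30.0)})


def toy_loglik(theta, seed=None):
    th = float(np.asarray(theta).ravel()[0])
    return float(-0.5 * np.sum((Y - th) ** 2) / SIGMA_Y**2
                 - len(Y) * math.log(SIGMA_Y * math.sqrt(2 * math.pi)))


def toy_posterior():
    tau2, mu0 = 1.0, 0.0
    prec = 1 / tau2 + len(Y) / SIGMA_Y**2
    mu_n = (mu0 / tau2 + Y.sum() / SIGMA_Y**2) / prec
    return mu_n, math.sqrt(1 / prec)


@pytest.fixture(scope="module")
def conjugate_draws():
    cfg = SamplerConfig(n_chains=8, stage1_iters=100, stage2_iters=2000,
                        burn_in=400, purify_prob=0.0, seed=2024)
    rng = np.random.default_rng(2024)
    pop, _post, ll = stage1_search(toy_loglik, PRIOR_TOY, cfg, rng)
    return stage2_demcmc(pop, toy_loglik, PRIOR_TOY, cfg, rng, init_ll=ll)


class TestTruncNormPrior:
    def test_logpdf_matches_scipy(self):
        p = TruncNormPrior(0.26, 0.26, 0.0, np.inf)
        ref = stats.truncnorm(-1.0, np.inf, loc=0.26, scale=0.26)
        for x in (0.01, 0.1, 0.26, 0.9, 2.5):
            assert p.logpdf(x) == pytest.approx(ref.logpdf(x), abs=1e-10)

    def test_outside_bounds_is_minus_inf(self):
        p = TruncNormPrior(0.26, 0.26)
        assert p.logpdf(-1e-9) == -np.inf

    def test_density_normalizes(self):
        p = TruncNormPrior(0.17, 0.17, 0.0, np.inf)
        val, _ = integrate.quad(lambda x: math.exp(p.logpdf(x)), 0.0, 10.0)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_log_prior_sums_marginals(self):
        priors = default_priors("ddm")
        theta = priors.means
        expected = sum(priors[n].logpdf(x) for n, x in zip(priors.names, theta))
        assert log_prior(theta, priors) == pytest.approx(expected, abs=1e-10)
        assert np.isfinite(log_prior(theta, priors))
        theta_bad = theta.copy()
        theta_bad[0] = -0.01  # below the zero lower truncation
        assert log_prior(theta_bad, priors) == -np.inf


class TestStage1:
    @staticmethod
    def _quadratic_setup():
        priors = PriorSet({
            "a": TruncNormPrior(1.0, 2.0, -50.0, 50.0),
            "b": TruncNormPrior(-0.5, 2.0, -50.0, 50.0),
        })
        mode = np.array([0.8, -0.3])

        def ll(theta, seed=None):
            return float(-0.5 * np.sum((np.asarray(theta) - mode) ** 2) / 0.05**2)

        # the posterior mode of prior * quadratic likelihood, found once by
        # direct optimization of the deterministic log posterior
        from scipy.optimize import minimize
        res = minimize(lambda th: -(ll(th) + priors.log_density(th)), mode)
        return priors, ll, -res.fun

    def test_finds_known_optimum(self):
        priors, ll, post_at_mode = self._quadratic_setup()
        cfg = SamplerConfig(n_chains=10, stage1_iters=200, stage2_iters=10,
                            burn_in=1, seed=7)
        rng = np.random.default_rng(7)
        _pop, post, _ll = stage1_search(ll, priors, cfg, rng)
        assert post_at_mode - post.max() < 1e-3

    def test_greedy_best_is_nondecreasing(self):
        # same seed: a longer run replays the shorter run's generations,
        # so its final best can never be worse
        priors, ll, _ = self._quadratic_setup()
        bests = []
        for iters in (25, 100):
            cfg = SamplerConfig(n_chains=10, stage1_iters=iters, stage2_iters=10,
                                burn_in=1, seed=3)
            _pop, post, _ = stage1_search(ll, priors, cfg, np.random.default_rng(3))
            bests.append(post.max())
        assert bests[1] >= bests[0]

    def test_seed_determinism(self):
        priors, ll, _ = self._quadratic_setup()
        cfg = SamplerConfig(n_chains=10, stage1_iters=50, stage2_iters=10,
                            burn_in=1, seed=11)
        pops = [
            stage1_search(ll, priors, cfg, np.random.default_rng(11))[0]
            for _ in range(2)
        ]
        assert np.array_equal(pops[0], pops[1])

    def test_chain_count_validated(self):
        priors, ll, _ = self._quadratic_setup()
        cfg = SamplerConfig(n_chains=3, stage1_iters=10, stage2_iters=10, burn_in=1)
        with pytest.raises(ValueError, match="chains"):
            stage1_search(ll, priors, cfg, np.random.default_rng(0))


class TestStage2:
    def test_flat_likelihood_recovers_prior(self):
        priors = PriorSet({
            "a": TruncNormPrior(0.5, 0.2, 0.0, 1.0),
            "b": TruncNormPrior(0.2, 0.3, 0.0, np.inf),
        })
        cfg = SamplerConfig(n_chains=8, stage1_iters=0, stage2_iters=2500,
                            burn_in=500, purify_prob=0.0, seed=5)
        rng = np.random.default_rng(5)
        pop = priors.sample(rng, 8)
        draws = stage2_demcmc(pop, lambda th, seed=None: 0.0, priors, cfg, rng)
        flat = draws.flat()
        for j, name in enumerate(priors.names):
            p = priors[name]
            a = (p.lower - p.mu) / p.sigma
            b = (p.upper - p.mu) / p.sigma
            ref = stats.truncnorm(a, b, loc=p.mu, scale=p.sigma)
            ess = float(az.ess(np.asarray(draws.retained()[:, :, j])))
            se = ref.std() / math.sqrt(max(ess, 1.0))
            assert abs(flat[:, j].mean() - ref.mean()) < 3 * se
            assert flat[:, j].std() == pytest.approx(ref.std(), rel=0.1)
            assert flat[:, j].min() >= p.lower and flat[:, j].max() <= p.upper

    def test_conjugate_posterior_moments(self, conjugate_draws):
        mu_n, sd_n = toy_posterior()
        flat = conjugate_draws.marginal("theta")
        ess = float(az.ess(np.asarray(conjugate_draws.retained()[:, :, 0])))
        assert abs(flat.mean() - mu_n) < 3 * sd_n / math.sqrt(ess)
        assert flat.std() == pytest.approx(sd_n, rel=0.1)

    def test_conjugate_marginal_passes_ks(self, conjugate_draws):
        # detailed-balance check: thinned retained draws against the known
        # normal posterior at alpha = 0.01
        mu_n, sd_n = toy_posterior()
        thinned = conjugate_draws.marginal("theta")[::40]
        res = stats.kstest(thinned, stats.norm(mu_n, sd_n).cdf)
        assert res.pvalue > 0.01
        assert 0.0 < conjugate_draws.meta["acceptance_rate"] < 1.0

    def test_reference_budget_bookkeeping(self):
        cfg = SamplerConfig(n_chains=30, stage1_iters=1000, stage2_iters=3000,
                            burn_in=500)
        counts = planned_draw_counts(cfg)
        assert counts == {"generated": 90_000, "retained": 75_000}

    def test_draws_shape_and_counts(self, conjugate_draws):
        assert conjugate_draws.samples.shape == (8, 2000, 1)
        assert conjugate_draws.n_generated == 16_000
        assert conjugate_draws.n_retained == 8 * 1600


class TestSplitRhat:
    def test_converged_chains_near_one(self, rng):
        x = rng.standard_normal((6, 2000, 2))
        assert np.all(split_rhat(x, burn_in=0) < 1.01)

    def test_divergent_chains_flagged(self, rng):
        x = rng.standard_normal((6, 1000, 1))
        x[:3] += 10.0
        assert np.all(split_rhat(x, burn_in=0) > 2.0)

    def test_matches_arviz_split_implementation(self, rng):
        x = rng.standard_normal((4, 500, 3)).cumsum(axis=1) * 0.01 + rng.standard_normal((4, 500, 3))
        ours = split_rhat(x, burn_in=0)
        theirs = np.array([
            float(az.rhat(np.asarray(x[:, :, j]), method="split")) for j in range(3)
        ])
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_degenerate_chains_error(self):
        x = np.ones((4, 100, 1))
        with pytest.raises(ValueError, match="degenerate"):
            split_rhat(x, burn_in=0)

    def test_too_few_iterations_error(self):
        with pytest.raises(ValueError):
            split_rhat(np.random.default_rng(0).standard_normal((4, 3, 1)), burn_in=0)


class TestPosteriorSummaries:
    def test_eap_of_constant_draws(self):
        d = PosteriorDraws(np.full((4, 100, 1), 3.14), ("c",), burn_in=10)
        assert eap(d)["c"] == pytest.approx(3.14)
        lo, hi = credible_interval(d)["c"]
        assert lo == hi == pytest.approx(3.14)

    def test_eap_equals_median_for_symmetric_draws(self, rng):
        x = rng.standard_normal((4, 5000, 1)) + 1.5
        d = PosteriorDraws(x, ("s",), burn_in=0)
        assert eap(d)["s"] == pytest.approx(np.median(x), abs=0.03)

    def test_conjugate_eap_matches_closed_form(self, conjugate_draws):
        mu_n, sd_n = toy_posterior()
        ess = float(az.ess(np.asarray(conjugate_draws.retained()[:, :, 0])))
        assert abs(eap(conjugate_draws)["theta"] - mu_n) < 3 * sd_n / math.sqrt(ess)

    def test_credible_interval_has_nominal_mass(self, conjugate_draws):
        lo, hi = credible_interval(conjugate_draws, prob=0.9)["theta"]
        flat = conjugate_draws.marginal("theta")
        inside = np.mean((flat >= lo) & (flat <= hi))
        assert inside == pytest.approx(0.9, abs=0.01)


def test_sampler_config_validation():
    with pytest.raises(ValueError):
        SamplerConfig(purify_prob=1.5)
    with pytest.raises(ValueError):
        SamplerConfig(stage2_iters=100, burn_in=100)
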