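"""Two-stage differential-evolution MCMC (DE-MCMC) with truncated-normal
priors, purification for noisy likelihoods, convergence diagnostics, and
posterior summaries.

Stage 1 runs the *current-to-best* DE transition rule with greedy
acceptance to locate the high-posterior region; its final population seeds
stage 2, where the standard DE-MCMC transition rule (scaled difference of
two randomly chosen chains plus a small uniform jitter) with a Metropolis
accept step generates the posterior sample.  Because the PDA likelihood is
noisy, each chain's stored log-likelihood is stochastically re-evaluated
("purification") with 30% probability per generation, which stops chains
sticking at overestimated likelihood values.

Log-likelihood callables have signature ``log_like(theta, seed) -> float``;
deterministic likelihoods simply ignore the seed, which is how the
analytic plug-ins used by the test oracles enter the same machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .model_core import DDMParams, TVDDMParams

__all__ = [
    "TruncNormPrior",
    "PriorSet",
    "SamplerConfig",
    "PosteriorDraws",
    "DEFAULT_PRIORS",
    "default_priors",
    "log_prior",
    "stage1_search",
    "stage2_demcmc",
    "split_rhat",
    "eap",
    "credible_interval",
    "planned_draw_counts",
    "fit_model",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class TruncNormPrior:
    """Truncated normal prior TN(mu, sigma, lower, upper)."""

    mu: float
    sigma: float
    lower: float = 0.0
    upper: float = math.inf

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.lower < self.upper):
            raise ValueError(f"invalid TruncNormPrior: {self}")

    @property
    def _log_z(self) -> float:
        # log of the truncation normalizer Phi(b) - Phi(a), in standard units
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        if math.isinf(b):
            return float(special.log_ndtr(-a))
        # log(Phi(b) - Phi(a)) via the complementary tail for stability
        return float(np.log(special.ndtr(b) - special.ndtr(a)))

    def logpdf(self, x: float) -> float:
        if x < self.lower or x > self.upper:
            return -math.inf
        u = (x - self.mu) / self.sigma
        return -0.5 * u * u - _LOG_SQRT_2PI - math.log(self.sigma) - self._log_z

    def rvs(self, rng: np.random.Generator, size=None):
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        return stats.truncnorm.rvs(a, b, loc=self.mu, scale=self.sigma,
                                   size=size, random_state=rng)


class PriorSet:
    """Ordered collection of per-parameter priors with a vectorized
    log-density (the sampler hot path)."""

    def __init__(self, priors: dict[str, TruncNormPrior]):
        self.names = tuple(priors)
        self.priors = priors
        self._mu = np.array([p.mu for p in priors.values()])
        self._sigma = np.array([p.sigma for p in priors.values()])
        self._lower = np.array([p.lower for p in priors.values()])
        self._upper = np.array([p.upper for p in priors.values()])
        self._const = -(
            _LOG_SQRT_2PI + np.log(self._sigma)
            + np.array([p._log_z for p in priors.values()])
        )

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> TruncNormPrior:
        return self.priors[name]

    @property
    def means(self) -> np.ndarray:
        return self._mu.copy()

    @property
    def sds(self) -> np.ndarray:
        return self._sigma.copy()

    def log_density(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if np.any(theta < self._lower) or np.any(theta > self._upper):
            return -np.inf
        u = (theta - self._mu) / self._sigma
        return float(np.sum(-0.5 * u * u + self._const))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        cols = [p.rvs(rng, size) for p in self.priors.values()]
        return np.column_stack(cols)


def log_prior(theta, priors) -> float:
    """Sum of truncated-normal log-densities; -inf outside any bound."""
    if isinstance(priors, PriorSet):
        return priors.log_density(np.asarray(theta, dtype=float))
    return float(sum(p.logpdf(x) for p, x in zip(priors, theta)))


# Informed priors for both models: truncated normals TN(mu, mu, 0, inf)
# with means taken from earlier maximum-likelihood fits of the two models.
DEFAULT_PRIORS: dict[str, dict[str, TruncNormPrior]] = {
    "ddm": {
        "A": TruncNormPrior(0.17, 0.17),
        "ter": TruncNormPrior(0.26, 0.26),
        "v": TruncNormPrior(0.25, 0.25),
        "sz": TruncNormPrior(0.05, 0.05),
        "sv": TruncNormPrior(0.07, 0.07),
        "ster": TruncNormPrior(0.28, 0.28),
    },
    "tvddm": {
        "A": TruncNormPrior(0.2, 0.2),
        "ter": TruncNormPrior(0.18, 0.18),
        "v": TruncNormPrior(0.3, 0.3),
        "beta": TruncNormPrior(25.0, 25.0),
        "n": TruncNormPrior(5.0, 5.0),
        "sigma2": TruncNormPrior(0.1, 0.1),
        "sv": TruncNormPrior(0.25, 0.25),
    },
}


def default_priors(model: str) -> PriorSet:
    order = {"ddm": DDMParams.names(), "tvddm": TVDDMParams.names()}[model]
    return PriorSet({k: DEFAULT_PRIORS[model][k] for k in order})


@dataclass(frozen=True)
class SamplerConfig:
    """Budgets and tuning constants for the two-stage sampler.

    Defaults follow the reference configuration: 30 chains, 1000 stage-1
    generations, 3000 stage-2 generations with a 500-generation burn-in,
    30% purification.  gamma_de defaults to 2.38/sqrt(2d); jitter is
    uniform with half-width ``jitter_scale`` times each prior SD.
    """

    n_chains: int = 30
    stage1_iters: int = 1000
    stage2_iters: int = 3000
    burn_in: int = 500
    purify_prob: float = 0.3
    gamma_de: float | None = None  # None -> 2.38/sqrt(2d)
    gamma1: float = 0.5  # stage-1 current-to-best weight
    gamma2: float = 0.5  # stage-1 difference-vector weight
    jitter_scale: float = 1e-4
    mode_jump_prob: float = 0.1  # stage-2 proposals with gamma = 1
    migrate_prob: float = 0.1  # per-generation chance of a migration step
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.purify_prob <= 1.0):
            raise ValueError("purify_prob must be in [0, 1]")
        if not self.burn_in < self.stage2_iters:
            raise ValueError("burn_in must be < stage2_iters")

    def validate_for(self, d: int) -> None:
        if self.n_chains < d + 2:
            raise ValueError(
                f"n_chains={self.n_chains} < d+2={d + 2}: DE proposals need "
                "at least d+2 chains"
            )


def planned_draw_counts(cfg: SamplerConfig) -> dict[str, int]:
    """Bookkeeping for a stage-2 run: per-parameter draws generated
    (chains x iterations) and retained after burn-in."""
    return {
        "generated": cfg.n_chains * cfg.stage2_iters,
        "retained": cfg.n_chains * (cfg.stage2_iters - cfg.burn_in),
    }


@dataclass
class PosteriorDraws:
    """chains x iterations x parameters array with burn-in metadata."""

    samples: np.ndarray  # (n_chains, n_iters, d)
    param_names: tuple[str, ...]
    burn_in: int
    log_likelihood: np.ndarray | None = None  # (n_chains, n_iters)
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    @property
    def n_iters(self) -> int:
        return self.samples.shape[1]

    @property
    def n_generated(self) -> int:
        return self.n_chains * self.n_iters

    @property
    def n_retained(self) -> int:
        return self.n_chains * (self.n_iters - self.burn_in)

    def retained(self) -> np.ndarray:
        """Post-burn-in draws, shape (n_chains, n_iters - burn_in, d)."""
        return self.samples[:, self.burn_in:, :]

    def flat(self) -> np.ndarray:
        """Post-burn-in draws pooled over chains, shape (n_retained, d)."""
        return self.retained().reshape(-1, self.samples.shape[2])

    def marginal(self, name: str) -> np.ndarray:
        return self.flat()[:, self.param_names.index(name)]


def _de_rng_pair(rng: np.random.Generator, n: int, i: int) -> tuple[int, int]:
    r1 = int(rng.integers(n - 1))
    if r1 >= i:
        r1 += 1
    r2 = int(rng.integers(n - 2))
    for taken in sorted((i, r1)):
        if r2 >= taken:
            r2 += 1
    return r1, r2


def _fresh_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31))


def _init_population(priors: PriorSet, n: int, rng: np.random.Generator,
                     validate=None, max_redraws: int = 200) -> np.ndarray:
    """Prior draws for the initial population, rejection-sampled to satisfy
    joint model constraints (e.g. sz < A) that single-parameter prior
    bounds cannot express.

    A -inf-posterior state can only enter the population at initialization
    (greedy and Metropolis acceptance both reject -inf moves), and the
    current-to-best pull cannot repair a jointly invalid chain whose
    violation exceeds the best chain's margin — so invalid starts are
    excluded here once and for all.
    """
    pop = priors.sample(rng, n)
    if validate is None:
        return pop
    for i in range(n):
        for _ in range(max_redraws):
            if validate(pop[i]):
                break
            pop[i] = priors.sample(rng, 1)[0]
        else:
            raise RuntimeError(
                "could not initialize a jointly valid chain from the prior"
            )
    return pop


def stage1_search(log_like, priors: PriorSet, cfg: SamplerConfig,
                  rng: np.random.Generator, validate=None):
    """Stage 1: current-to-best differential evolution with greedy acceptance.

    Proposal: x_i + gamma1*(x_best - x_i) + gamma2*(x_r1 - x_r2) + jitter.
    Returns (population, log_posterior, log_likelihood) of the final
    generation, which seeds stage 2.
    """
    d = len(priors)
    cfg.validate_for(d)
    n = cfg.n_chains
    jitter = cfg.jitter_scale * priors.sds

    if validate is None:
        validate = getattr(log_like, "valid", None)
    pop = _init_population(priors, n, rng, validate)
    ll = np.array([log_like(pop[i], _fresh_seed(rng)) for i in range(n)])
    lp = np.array([priors.log_density(pop[i]) for i in range(n)])
    post = lp + ll
    if not np.any(np.isfinite(post)):
        raise RuntimeError("prior/data mismatch: no chain initialized at "
                           "finite posterior density")

    for _gen in range(cfg.stage1_iters):
        best = int(np.nanargmax(np.where(np.isfinite(post), post, -np.inf)))
        for i in range(n):
            r1, r2 = _de_rng_pair(rng, n, i)
            prop = (
                pop[i]
                + cfg.gamma1 * (pop[best] - pop[i])
                + cfg.gamma2 * (pop[r1] - pop[r2])
                + rng.uniform(-jitter, jitter)
            )
            lp_new = priors.log_density(prop)
            if not np.isfinite(lp_new):
                continue
            ll_new = log_like(prop, _fresh_seed(rng))
            post_new = lp_new + ll_new
            if post_new > post[i]:  # greedy
                pop[i], post[i], ll[i] = prop, post_new, ll_new
    return pop, post, ll


def stage2_demcmc(init_pop: np.ndarray, log_like, priors: PriorSet,
                  cfg: SamplerConfig, rng: np.random.Generator,
                  init_ll: np.ndarray | None = None) -> PosteriorDraws:
    """Stage 2: DE-MCMC with Metropolis acceptance and purification.

    Per generation and chain: with probability ``purify_prob`` the chain's
    stored log-likelihood is re-evaluated with a fresh simulation seed;
    the proposal is x_i + gamma*(x_r1 - x_r2) + jitter (gamma = 1 with
    probability ``mode_jump_prob`` for mode jumping) and is accepted on
    the (noisy) posterior ratio.
    """
    d = len(priors)
    cfg.validate_for(d)
    n = cfg.n_chains
    if init_pop.shape != (n, d):
        raise ValueError(f"init population must have shape {(n, d)}")
    gamma = cfg.gamma_de if cfg.gamma_de is not None else 2.38 / math.sqrt(2 * d)
    jitter = cfg.jitter_scale * priors.sds

    pop = init_pop.copy()
    if init_ll is None:
        ll = np.array([log_like(pop[i], _fresh_seed(rng)) for i in range(n)])
    else:
        ll = np.asarray(init_ll, dtype=float).copy()
    lp = np.array([priors.log_density(pop[i]) for i in range(n)])

    samples = np.empty((n, cfg.stage2_iters, d))
    ll_trace = np.empty((n, cfg.stage2_iters))
    n_accept = 0
    n_purify = 0
    for g in range(cfg.stage2_iters):
        if cfg.migrate_prob > 0 and rng.random() < cfg.migrate_prob:
            # migration: cyclically permute the states of a random chain
            # subset.  All chains target the same posterior, so a state
            # permutation leaves the joint target exactly invariant while
            # relocating lagging chains.
            k = int(rng.integers(2, n + 1))
            sel = rng.choice(n, size=k, replace=False)
            rolled = np.roll(sel, 1)
            pop[sel], lp[sel], ll[sel] = pop[rolled], lp[rolled], ll[rolled]
        for i in range(n):
            if cfg.purify_prob > 0 and rng.random() < cfg.purify_prob:
                ll[i] = log_like(pop[i], _fresh_seed(rng))
                n_purify += 1
            r1, r2 = _de_rng_pair(rng, n, i)
            g_i = 1.0 if rng.random() < cfg.mode_jump_prob else gamma
            prop = pop[i] + g_i * (pop[r1] - pop[r2]) + rng.uniform(-jitter, jitter)
            lp_new = priors.log_density(prop)
            if np.isfinite(lp_new):
                ll_new = log_like(prop, _fresh_seed(rng))
                if math.log(rng.random()) < (lp_new + ll_new) - (lp[i] + ll[i]):
                    pop[i], lp[i], ll[i] = prop, lp_new, ll_new
                    n_accept += 1
        samples[:, g, :] = pop
        ll_trace[:, g] = ll

    return PosteriorDraws(
        samples=samples,
        param_names=priors.names,
        burn_in=cfg.burn_in,
        log_likelihood=ll_trace,
        meta={
            "acceptance_rate": n_accept / (n * cfg.stage2_iters),
            "purification_count": n_purify,
            **planned_draw_counts(cfg),
        },
    )


def split_rhat(draws, burn_in: int | None = None) -> np.ndarray:
    """Split potential-scale-reduction statistic, one value per parameter.

    Each retained chain is split in half; R-hat compares between- and
    within-half-chain variances.  Values near 1 indicate convergence
    (criterion 1.1 is the conventional gate).
    """
    if isinstance(draws, PosteriorDraws):
        x = draws.retained()
    else:
        x = np.asarray(draws, dtype=float)
        if burn_in:
            x = x[:, burn_in:, :]
    m, n, d = x.shape
    if n < 4:
        raise ValueError("need >= 4 post-burn-in iterations per chain")
    half = n // 2
    # split each chain into two halves -> 2m chains of length `half`
    chains = np.concatenate([x[:, :half, :], x[:, half: 2 * half, :]], axis=0)
    cm = chains.mean(axis=1)  # (2m, d)
    cv = chains.var(axis=1, ddof=1)  # (2m, d)
    w = cv.mean(axis=0)
    if np.any(w == 0):
        raise ValueError("degenerate chains: zero within-chain variance")
    b = half * cm.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * w + b / half
    return np.sqrt(var_plus / w)


def eap(draws: PosteriorDraws) -> dict[str, float]:
    """Expected a posteriori estimate: mean of each marginal posterior."""
    flat = draws.flat()
    return {name: float(flat[:, j].mean()) for j, name in enumerate(draws.param_names)}


def credible_interval(draws: PosteriorDraws, prob: float = 0.95) -> dict[str, tuple[float, float]]:
    """Central credible interval per parameter."""
    flat = draws.flat()
    lo, hi = (1 - prob) / 2 * 100, (1 + prob) / 2 * 100
    return {
        name: tuple(np.percentile(flat[:, j], [lo, hi]))
        for j, name in enumerate(draws.param_names)
    }


def fit_model(log_like, priors: PriorSet, cfg: SamplerConfig,
              seed: int | None = None) -> PosteriorDraws:
    """Run both sampler stages and return the posterior draws."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pop, _post, ll = stage1_search(log_like, priors, cfg, rng)
    draws = stage2_demcmc(pop, log_like, priors, cfg, rng, init_ll=ll)
    draws.meta["max_split_rhat"] = float(np.max(split_rhat(draws)))
    return draws
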