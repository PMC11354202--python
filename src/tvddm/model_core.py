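"""Forward simulators for the drift-diffusion model (DDM) and its
time-varying drift-rate extension (TV-DDM).

Both models describe a two-choice decision as a Wiener diffusion between
two absorbing boundaries (lower at 0, upper at ``A``, unbiased start at
``A/2``): evidence ``x`` accumulates with drift ``v`` and diffusion
coefficient ``sigma`` until a boundary is hit.  The observed response time
is the first-passage (decision) time plus a non-decision time ``ter``
covering stimulus encoding and motor execution.  The TV-DDM replaces the
assumption that a fully formed percept drives accumulation from t=0 with a
perceptual-integration stage: drift and stimulus-driven diffusion are
modulated by a growth function theta(t) — the regularized lower incomplete
gamma function of ``beta * t`` with shape ``n``, interpretable as ``n``
cascaded linear filters — while a constant premature-sampling noise
``sigma2`` is present throughout.

Trajectories are integrated with the Euler-Maruyama scheme on a fixed grid
(default 1 ms steps, diffusion coefficient 0.1, in seconds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
from scipy import special

from ._kernels import RUNNING, ddm_chunk, tvddm_chunk

__all__ = [
    "DDMParams",
    "TVDDMParams",
    "SimConfig",
    "TrialOutcome",
    "Trials",
    "LOWER",
    "UPPER",
    "TIMEOUT",
    "growth_theta",
    "sample_trial_variability",
    "simulate_ddm",
    "simulate_tvddm",
    "simulate",
]

# response codes used throughout the package
LOWER = 0
UPPER = 1
TIMEOUT = -1

_RESPONSE_LABELS = {LOWER: "lower", UPPER: "upper", TIMEOUT: "timeout"}


@dataclass(frozen=True)
class DDMParams:
    """Per-condition parameters of the standard 6-parameter DDM.

    Parameters
    ----------
    A : boundary separation (evidence units), > 0.
    ter : non-decision time (s), >= 0.
    v : mean drift rate (evidence/s).
    sz : start-point range (evidence units); start point is uniform on
        ``A/2 ± sz/2`` and must stay strictly inside (0, A).
    sv : between-trial drift-rate SD (evidence/s), >= 0.
    ster : non-decision-time range (s); per-trial non-decision time is
        uniform on ``ter ± ster/2`` and must stay non-negative.
    """

    A: float
    ter: float
    v: float
    sz: float = 0.0
    sv: float = 0.0
    ster: float = 0.0

    def __post_init__(self) -> None:
        if not self.is_valid_vector([self.A, self.ter, self.v, self.sz, self.sv, self.ster]):
            raise ValueError(f"invalid DDM parameters: {self}")

    @staticmethod
    def names() -> tuple[str, ...]:
        return ("A", "ter", "v", "sz", "sv", "ster")

    @staticmethod
    def is_valid_vector(theta) -> bool:
        A, ter, v, sz, sv, ster = theta
        return bool(
            np.all(np.isfinite(theta))
            and A > 0
            and ter >= 0
            and sz >= 0
            and sz < A
            and sv >= 0
            and ster >= 0
            and ster <= 2 * ter
        )

    @classmethod
    def from_vector(cls, theta) -> "DDMParams":
        return cls(*map(float, theta))

    def to_vector(self) -> np.ndarray:
        return np.array([self.A, self.ter, self.v, self.sz, self.sv, self.ster])


@dataclass(frozen=True)
class TVDDMParams:
    """Per-condition parameters of the 7-parameter TV-DDM.

    The model has no start-point or non-decision-time variability: the
    start point is fixed at ``A/2`` and non-decision time at ``ter``.

    Parameters
    ----------
    A : boundary separation, > 0.
    ter : non-decision time (s), >= 0.
    v : asymptotic drift rate (evidence/s), reached once theta(t) -> 1.
    beta : evidence growth rate (1/s), > 0.
    n : evidence growth shape (number of cascaded filter stages,
        real-valued), > 0.
    sigma2 : premature-sampling diffusion coefficient (evidence/sqrt(s)),
        >= 0; constant noise present before the percept has formed.
    sv : between-trial drift-rate SD, >= 0.
    """

    A: float
    ter: float
    v: float
    beta: float
    n: float
    sigma2: float = 0.0
    sv: float = 0.0

    def __post_init__(self) -> None:
        if not self.is_valid_vector(
            [self.A, self.ter, self.v, self.beta, self.n, self.sigma2, self.sv]
        ):
            raise ValueError(f"invalid TV-DDM parameters: {self}")

    @staticmethod
    def names() -> tuple[str, ...]:
        return ("A", "ter", "v", "beta", "n", "sigma2", "sv")

    @staticmethod
    def is_valid_vector(theta) -> bool:
        A, ter, v, beta, n, sigma2, sv = theta
        return bool(
            np.all(np.isfinite(theta))
            and A > 0
            and ter >= 0
            and beta > 0
            and n > 0
            and sigma2 >= 0
            and sv >= 0
        )

    @classmethod
    def from_vector(cls, theta) -> "TVDDMParams":
        return cls(*map(float, theta))

    def to_vector(self) -> np.ndarray:
        return np.array([self.A, self.ter, self.v, self.beta, self.n, self.sigma2, self.sv])


PARAM_CLASSES = {"ddm": DDMParams, "tvddm": TVDDMParams}


@dataclass(frozen=True)
class SimConfig:
    """Euler-Maruyama integration settings.

    dt=0.001 s and sigma=0.1 are the conventional settings for this class
    of model (1 ms integration constant, diffusion coefficient 0.1, all
    times in seconds).  Trials that have not been absorbed by ``max_t``
    are re-simulated up to ``max_attempts`` times and then recorded as
    timeouts.
    """

    dt: float = 0.001
    sigma: float = 0.1
    max_t: float = 10.0
    seed: int | None = None
    max_attempts: int = 10

    def __post_init__(self) -> None:
        if not (self.dt > 0 and self.sigma > 0 and self.max_t > self.dt):
            raise ValueError(f"invalid SimConfig: {self}")


class TrialOutcome(NamedTuple):
    response: str  # "upper" | "lower" | "timeout"
    rt: float  # total response time (s)


@dataclass
class Trials:
    """Compact array-of-trials container.

    ``response`` holds integer codes (UPPER=1, LOWER=0, TIMEOUT=-1); ``rt``
    is decision time plus the sampled non-decision time.  Iterating yields
    :class:`TrialOutcome` records with string labels.
    """

    response: np.ndarray
    rt: np.ndarray

    def __len__(self) -> int:
        return len(self.response)

    def __iter__(self) -> Iterator[TrialOutcome]:
        for r, t in zip(self.response, self.rt):
            yield TrialOutcome(_RESPONSE_LABELS[int(r)], float(t))

    @property
    def n_timeout(self) -> int:
        return int(np.sum(self.response == TIMEOUT))

    def decided(self) -> "Trials":
        """Trials absorbed at a boundary (timeouts dropped)."""
        keep = self.response != TIMEOUT
        return Trials(self.response[keep], self.rt[keep])


def growth_theta(t, beta: float, n: float):
    """Evidence growth function theta(t).

    The regularized lower incomplete gamma function evaluated at
    ``(n, beta*t)``: the fraction (in [0, 1]) of the perceptual
    representation formed by time ``t`` after stimulus onset.  Vectorizes
    over ``t``; non-decreasing in ``t``.
    """
    if not (beta > 0 and n > 0):
        raise ValueError(f"growth_theta requires beta > 0 and n > 0, got beta={beta}, n={n}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("growth_theta requires t >= 0")
    out = special.gammainc(n, beta * t)
    return float(out) if out.ndim == 0 else out


def sample_trial_variability(params: DDMParams, rng: np.random.Generator):
    """Draw one trial's start point, drift and non-decision time.

    z ~ Uniform(A/2 - sz/2, A/2 + sz/2); v_trial ~ Normal(v, sv);
    ter_trial ~ Uniform(ter - ster/2, ter + ster/2).  With all variability
    parameters zero this returns (A/2, v, ter) exactly.
    """
    z = params.A / 2 + (rng.uniform(-0.5, 0.5) * params.sz if params.sz > 0 else 0.0)
    v_trial = params.v + (params.sv * rng.standard_normal() if params.sv > 0 else 0.0)
    ter_trial = params.ter + (
        rng.uniform(-0.5, 0.5) * params.ster if params.ster > 0 else 0.0
    )
    return z, v_trial, ter_trial


def _resolve_seed(cfg: SimConfig, seed: int | None) -> int:
    if seed is not None:
        return int(seed)
    if cfg.seed is not None:
        return int(cfg.seed)
    raise ValueError("a seed is required (SimConfig.seed or the seed argument)")


_NOISE_CHUNK = 256  # Euler steps advanced per block of pre-drawn normals


def _sim_rng(seed: int) -> np.random.Generator:
    # SFC64: fastest installed bit generator for the block-noise hot path
    return np.random.Generator(np.random.SFC64(seed))


def _run_cohort(advance, m: int, n_steps_max: int, rng: np.random.Generator):
    """Drive one attempt cohort of ``m`` trials to absorption or timeout.

    ``advance(act, noise, steps, status, dec_steps)`` moves the active
    trials through up to one chunk of pre-drawn standard-normal increments
    (float32: increment noise needs no more precision than the Euler error).
    Returns (status, dec_steps).
    """
    steps = np.zeros(m, dtype=np.int64)
    status = np.full(m, RUNNING, dtype=np.int8)
    dec_steps = np.zeros(m, dtype=np.int64)
    act = np.arange(m)
    while act.size:
        base = _NOISE_CHUNK if act.size >= 64 else 4 * _NOISE_CHUNK
        chunk = min(base, n_steps_max - int(steps[act].min()))
        noise = rng.standard_normal((act.size, chunk), dtype=np.float32)
        advance(act, noise, steps, status, dec_steps)
        running = status[act] == RUNNING
        hit_cap = steps[act] >= n_steps_max
        status[act[running & hit_cap]] = TIMEOUT
        act = act[running & ~hit_cap]
    return status, dec_steps


def simulate_ddm(
    params: DDMParams, n_trials: int, cfg: SimConfig = SimConfig(), *, seed: int | None = None
) -> Trials:
    """Simulate ``n_trials`` DDM trials by Euler-Maruyama integration.

    Each trial starts at a sampled start point z and evolves as
    ``dx = v_trial*dt + sigma*sqrt(dt)*N(0,1)`` until it crosses A (upper)
    or 0 (lower); rt = decision time + sampled non-decision time.
    Deterministic given (params, n_trials, cfg, seed).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _sim_rng(_resolve_seed(cfg, seed))
    n_steps_max = int(round(cfg.max_t / cfg.dt))
    c = cfg.sigma * np.sqrt(cfg.dt)
    A = params.A

    resp = np.full(n_trials, TIMEOUT, dtype=np.int8)
    rt = np.full(n_trials, cfg.max_t + params.ter)
    pending = np.arange(n_trials)
    for _attempt in range(cfg.max_attempts):
        if pending.size == 0:
            break
        m = pending.size
        x = A / 2 + (rng.random(m) - 0.5) * params.sz
        vt_dt = (params.v + params.sv * rng.standard_normal(m)) * cfg.dt
        tert = params.ter + (rng.random(m) - 0.5) * params.ster

        def advance(act, noise, steps, status, dec_steps):
            ddm_chunk(x, vt_dt, steps, status, dec_steps, act, noise, c, A, n_steps_max)

        status, dec_steps = _run_cohort(advance, m, n_steps_max, rng)
        done = status >= 0
        idx = pending[done]
        resp[idx] = status[done]
        rt[idx] = dec_steps[done] * cfg.dt + tert[done]
        rt[pending[~done]] = cfg.max_t + tert[~done]  # provisional timeout rt
        pending = pending[~done]
    return Trials(resp, rt)


def _theta_grid(beta: float, n: float, cfg: SimConfig) -> np.ndarray:
    """theta evaluated at the left endpoint of every Euler step."""
    n_steps = int(round(cfg.max_t / cfg.dt))
    t = np.arange(n_steps, dtype=float) * cfg.dt
    return special.gammainc(n, beta * t)


def simulate_tvddm(
    params: TVDDMParams, n_trials: int, cfg: SimConfig = SimConfig(), *, seed: int | None = None
) -> Trials:
    """Simulate ``n_trials`` TV-DDM trials.

    Each trial starts at A/2 and evolves as
    ``dx = v_trial*theta(t)*dt + sqrt(sigma^2*theta(t) + sigma2^2)*sqrt(dt)*N(0,1)``
    with theta evaluated at the within-trial clock measured from stimulus
    onset (the drift/diffusion coefficients use the left endpoint of each
    Euler step).  Absorption and rt rules as in :func:`simulate_ddm`.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _sim_rng(_resolve_seed(cfg, seed))
    n_steps_max = int(round(cfg.max_t / cfg.dt))
    theta = _theta_grid(params.beta, params.n, cfg)
    # per-step drift multiplier and noise SD, precomputed on the grid
    drift_dt = theta * cfg.dt
    noise_sd = np.sqrt(cfg.sigma**2 * theta + params.sigma2**2) * np.sqrt(cfg.dt)
    A = params.A

    resp = np.full(n_trials, TIMEOUT, dtype=np.int8)
    rt = np.full(n_trials, cfg.max_t + params.ter)
    pending = np.arange(n_trials)
    for _attempt in range(cfg.max_attempts):
        if pending.size == 0:
            break
        m = pending.size
        x = np.full(m, A / 2)
        vt = params.v + params.sv * rng.standard_normal(m)

        def advance(act, noise, steps, status, dec_steps):
            tvddm_chunk(
                x, vt, steps, status, dec_steps, act, noise, drift_dt, noise_sd, A, n_steps_max
            )

        status, dec_steps = _run_cohort(advance, m, n_steps_max, rng)
        done = status >= 0
        idx = pending[done]
        resp[idx] = status[done]
        rt[idx] = dec_steps[done] * cfg.dt + params.ter
        pending = pending[~done]
    return Trials(resp, rt)


def simulate(
    params, n_trials: int, cfg: SimConfig = SimConfig(), *, seed: int | None = None
) -> Trials:
    """Dispatch on parameter type (DDMParams or TVDDMParams)."""
    if isinstance(params, DDMParams):
        return simulate_ddm(params, n_trials, cfg, seed=seed)
    if isinstance(params, TVDDMParams):
        return simulate_tvddm(params, n_trials, cfg, seed=seed)
    raise TypeError(f"unsupported parameter type: {type(params)!r}")
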