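"""Simulation-based likelihood (probability density approximation, PDA).

The models have no tractable likelihood once between-trial variability or
the time-varying drift is in play, so the likelihood of an observed
(choice, RT) pair is approximated by a *defective* kernel density built
from trials simulated at the candidate parameters: each response category
gets a Gaussian KDE over its RTs weighted by the category's choice
probability, so the per-category densities integrate to the choice
probabilities rather than to 1.  Densities are floored at a small positive
value so isolated data points cannot produce -inf.

The likelihood is therefore *noisy*: repeated calls at the same parameters
return different values because a fresh simulation is run each time.  The
sampler's purification step exists to correct for this.

:func:`analytic_wiener_density` is the exact first-passage density of the
variability-free DDM (series solution with two absorbing boundaries); it
serves as an independent oracle for the PDA machinery, never as the
production likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import gaussian_kde_eval
from .model_core import (
    LOWER,
    UPPER,
    PARAM_CLASSES,
    SimConfig,
    Trials,
    simulate,
)

__all__ = [
    "LikelihoodConfig",
    "DefectiveKDE",
    "build_defective_kde",
    "pda_log_likelihood",
    "PDALikelihood",
    "analytic_wiener_density",
    "wiener_absorption_probability",
]


@dataclass(frozen=True)
class LikelihoodConfig:
    """PDA settings: simulated trials per call, density floor, bandwidth rule.

    ``eval_method`` selects how the Gaussian KDE is evaluated: "grid"
    (linear binning + Gaussian smoothing in Fourier space + interpolation,
    the fast default) or "direct" (exact kernel sum, used as the
    cross-check route in tests).
    """

    n_sim: int = 1000
    floor: float = 1e-10
    bandwidth_rule: str = "silverman"  # or "scott"
    log_transform: bool = False  # build the KDE on log-rt instead of rt
    eval_method: str = "grid"
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        if not self.floor > 0:
            raise ValueError("floor must be > 0")
        if self.bandwidth_rule not in ("silverman", "scott"):
            raise ValueError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        if self.eval_method not in ("grid", "direct"):
            raise ValueError(f"unknown eval_method {self.eval_method!r}")


def _bandwidth(x: np.ndarray, rule: str) -> float:
    m = len(x)
    sd = float(np.std(x))
    if rule == "silverman":
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        h = 0.9 * spread * m ** (-0.2)
    else:  # scott
        h = 1.06 * sd * m ** (-0.2)
    # degenerate samples (all RTs on the same grid point) get a floor of
    # one integration step so the density stays proper
    return max(h, 1e-4)


_GRID_SIZE = 4096


def _grid_density(x: np.ndarray, h: float) -> tuple[float, float, np.ndarray]:
    """Gaussian KDE of sample ``x`` on a regular grid via FFT smoothing.

    Linear binning followed by multiplication with the Gaussian
    characteristic function exp(-2 pi^2 h^2 k^2); the grid extends 8
    bandwidths past the sample range, so wrap-around mass is negligible
    and queries beyond the grid have (floored) zero density.
    Returns (grid origin, grid step, density values at grid points).
    """
    lo = float(x.min()) - 8.0 * h
    hi = float(x.max()) + 8.0 * h
    dx = (hi - lo) / (_GRID_SIZE - 1)
    pos = (x - lo) / dx
    i0 = pos.astype(np.int64)
    w = pos - i0
    hist = np.bincount(i0, weights=1.0 - w, minlength=_GRID_SIZE)
    hist += np.bincount(i0 + 1, weights=w, minlength=_GRID_SIZE)[:_GRID_SIZE]
    f = np.fft.rfft(hist)
    k = np.fft.rfftfreq(_GRID_SIZE, d=dx)
    f *= np.exp(-2.0 * (np.pi * h * k) ** 2)
    dens = np.fft.irfft(f, _GRID_SIZE) / (len(x) * dx)
    return lo, dx, np.maximum(dens, 0.0)


@dataclass
class DefectiveKDE:
    """Defective density over (response, rt) from simulated trials.

    ``weights[r]`` is the simulated choice probability of response ``r``
    (timeouts absorb the remaining mass, so the weights may sum to < 1);
    ``samples[r]`` are the sorted RTs and ``bandwidths[r]`` the Gaussian
    kernel bandwidth for that category.  Categories with fewer than two
    trials evaluate to the floor.
    """

    weights: dict[int, float]
    samples: dict[int, np.ndarray]
    bandwidths: dict[int, float]
    n_sim: int
    floor: float = 1e-10
    log_transform: bool = False
    eval_method: str = "grid"
    _grids: dict[int, tuple[float, float, np.ndarray]] = field(default_factory=dict)

    def _density(self, response: int, q: np.ndarray) -> np.ndarray:
        if self.eval_method == "grid":
            if response not in self._grids:
                self._grids[response] = _grid_density(
                    self.samples[response], self.bandwidths[response]
                )
            lo, dx, dens = self._grids[response]
            return np.interp((q - lo) / dx, np.arange(len(dens)), dens,
                             left=0.0, right=0.0)
        return gaussian_kde_eval(self.samples[response], self.bandwidths[response], q)

    def pdf(self, response: int, rts) -> np.ndarray:
        """Defective density (1/s), floored at ``floor``; vectorizes over rts."""
        rts = np.atleast_1d(np.asarray(rts, dtype=float))
        w = self.weights.get(int(response), 0.0)
        x = self.samples.get(int(response))
        if x is None or len(x) < 2 or w <= 0.0:
            return np.full(rts.shape, self.floor)
        if self.log_transform:
            ok = rts > 0
            dens = np.full(rts.shape, self.floor)
            if np.any(ok):
                # change of variables: f(rt) = f_log(log rt) / rt
                d = self._density(int(response), np.log(rts[ok])) / rts[ok]
                dens[ok] = np.maximum(w * d, self.floor)
            return dens
        d = self._density(int(response), rts)
        return np.maximum(w * d, self.floor)

    def logpdf(self, response: int, rts) -> np.ndarray:
        return np.log(self.pdf(response, rts))


def build_defective_kde(
    trials: Trials,
    floor: float = 1e-10,
    bandwidth_rule: str = "silverman",
    log_transform: bool = False,
    eval_method: str = "grid",
) -> DefectiveKDE:
    """Build the per-response defective KDE from simulated trials.

    Category weights are counts over the *total* number of trials
    (including timeouts); timeout trials contribute no kernel.  Raises if
    every trial timed out.
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    total = len(trials)
    weights: dict[int, float] = {}
    samples: dict[int, np.ndarray] = {}
    bandwidths: dict[int, float] = {}
    any_decided = False
    for r in (LOWER, UPPER):
        mask = trials.response == r
        cnt = int(np.sum(mask))
        weights[r] = cnt / total
        if cnt >= 2:
            any_decided = True
            x = np.sort(trials.rt[mask])
            if log_transform:
                x = np.log(x)
            samples[r] = x
            bandwidths[r] = _bandwidth(x, bandwidth_rule)
    if not any_decided:
        raise ValueError("degenerate simulation: all trials timed out")
    return DefectiveKDE(
        weights=weights,
        samples=samples,
        bandwidths=bandwidths,
        n_sim=total,
        floor=floor,
        log_transform=log_transform,
        eval_method=eval_method,
    )


def pda_log_likelihood(
    responses,
    rts,
    params,
    n_sim: int | None = None,
    cfg: LikelihoodConfig = LikelihoodConfig(),
    *,
    seed: int,
) -> float:
    """PDA log-likelihood of one participant-condition's cleaned data.

    Simulates ``n_sim`` fresh trials at ``params`` (seeded by ``seed``),
    builds the defective KDE and returns the summed floored log-density of
    the data.  Stochastic across calls with different seeds by design.
    Invalid parameters (violating the model invariants) return -inf so the
    sampler rejects them.
    """
    responses = np.asarray(responses)
    rts = np.asarray(rts, dtype=float)
    if len(responses) == 0:
        return 0.0
    n_sim = cfg.n_sim if n_sim is None else n_sim
    try:
        trials = simulate(params, n_sim, cfg.sim, seed=seed)
        kde = build_defective_kde(
            trials, floor=cfg.floor, bandwidth_rule=cfg.bandwidth_rule,
            log_transform=cfg.log_transform, eval_method=cfg.eval_method,
        )
    except ValueError:
        return -np.inf
    total = 0.0
    for r in (LOWER, UPPER):
        mask = responses == r
        if np.any(mask):
            total += float(np.sum(kde.logpdf(r, rts[mask])))
    return total


class PDALikelihood:
    """Callable log-likelihood over parameter vectors, for the sampler.

    ``log_like(theta, seed) -> float``; parameter vectors that violate the
    model's type invariants map to -inf.
    """

    def __init__(self, responses, rts, model: str, cfg: LikelihoodConfig = LikelihoodConfig()):
        if model not in PARAM_CLASSES:
            raise ValueError(f"unknown model {model!r}")
        self.responses = np.asarray(responses)
        self.rts = np.asarray(rts, dtype=float)
        self.model = model
        self.cfg = cfg
        self._cls = PARAM_CLASSES[model]
        self.param_names = self._cls.names()

    def valid(self, theta) -> bool:
        """Joint model-validity of a parameter vector (e.g. sz < A)."""
        return self._cls.is_valid_vector(np.asarray(theta, dtype=float))

    def __call__(self, theta, seed: int) -> float:
        if not self.valid(theta):
            return -np.inf
        params = self._cls.from_vector(theta)
        return pda_log_likelihood(
            self.responses, self.rts, params, cfg=self.cfg, seed=seed
        )


# ---------------------------------------------------------------------------
# analytic first-passage density of the variability-free DDM (test oracle)
# ---------------------------------------------------------------------------


def _fpt_lower_driftless(t: np.ndarray, z: float, a: float, rtol: float) -> np.ndarray:
    """Density of first passage through 0 for driftless unit-diffusion BM
    started at z in (0, a), by whichever series converges faster."""
    out = np.zeros_like(t)
    for i, ti in enumerate(t):
        if ti <= 0:
            continue
        if ti > 0.12 * a * a:  # large-time series: fast-decaying sine sum
            s = 0.0
            k = 1
            while True:
                term = k * math.sin(math.pi * k * z / a) * math.exp(
                    -(k * k) * math.pi**2 * ti / (2 * a * a)
                )
                s += term
                # alternating-ish series; stop when the envelope is tiny
                if k * math.exp(-(k * k) * math.pi**2 * ti / (2 * a * a)) < rtol * max(
                    abs(s), 1e-300
                ) and k >= 3:
                    break
                k += 1
                if k > 10000:
                    break
            out[i] = math.pi / (a * a) * s
        else:  # small-time series: sum of image charges
            s = 0.0
            for k in range(-50, 51):
                u = z + 2 * k * a
                s += u * math.exp(-(u * u) / (2 * ti))
            out[i] = s / math.sqrt(2 * math.pi * ti**3)
    return np.maximum(out, 0.0)


def analytic_wiener_density(rt, response: int, A: float, v: float, ter: float,
                            sigma: float = 0.1, rtol: float = 1e-10):
    """Exact defective first-passage density of the variability-free DDM.

    Start point fixed at A/2 (no bias); valid only for the sz=sv=ster=0
    model.  Returns the density (1/s) of responding ``response`` at total
    time ``rt``; zero for rt <= ter.  Series truncated well below 1e-8
    relative error.
    """
    rt = np.atleast_1d(np.asarray(rt, dtype=float))
    t = rt - ter
    # rescale to unit diffusion
    a = A / sigma
    z = a / 2.0
    mu = v / sigma
    if response == UPPER:
        z, mu = a - z, -mu
    elif response != LOWER:
        raise ValueError("response must be UPPER or LOWER")
    dens = np.zeros_like(t)
    pos = t > 0
    if np.any(pos):
        tp = t[pos]
        base = _fpt_lower_driftless(tp, z, a, rtol)
        dens[pos] = np.exp(-mu * z - mu * mu * tp / 2.0) * base
    return dens if dens.size > 1 else float(dens[0])


def wiener_absorption_probability(A: float, v: float, sigma: float = 0.1,
                                  z: float | None = None) -> float:
    """Closed-form probability of absorption at the upper boundary."""
    z = A / 2.0 if z is None else z
    if v == 0.0:
        return z / A
    e = 2.0 * v / (sigma * sigma)
    return float(np.expm1(-e * z) / np.expm1(-e * A))
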