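"""Distributional measures of choice-RT data and posterior-based inference
summaries.

CDFs report the RT at 17 quantile levels (10%...90% in 5% steps); CAFs
report mean RT and accuracy within 5 RT-quantile bands centred on the
10/30/50/70/90% levels.  Group summaries average participant summaries.
Credible bands propagate posterior uncertainty by recomputing the
summaries for posterior parameter draws.  Effects of condition on EAP
estimates are tested with a one-way repeated-measures ANOVA, and the
*posterior overlap indicator* checks how robust such an effect is to
posterior uncertainty: it repeats the ANOVA on small posterior-draw
averages (10 draws per cell, 1000 replicates) and reports the proportion
of significant replicates, with >= 95% read as a robust effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .model_core import UPPER, SimConfig, simulate
from .sampler import PosteriorDraws

__all__ = [
    "CDF_LEVELS",
    "CAF_LEVELS",
    "DistributionalSummary",
    "OverlapResult",
    "cdf_quantiles",
    "caf",
    "model_summary",
    "group_summary",
    "credible_band",
    "rm_anova",
    "posterior_overlap",
    "integration_time",
]

CDF_LEVELS = np.arange(0.10, 0.9001, 0.05)  # 17 levels
CAF_LEVELS = np.arange(0.10, 0.9001, 0.20)  # 5 levels


@dataclass
class DistributionalSummary:
    """CDF quantiles, CAF (rt, accuracy) pairs, and overall error rate."""

    cdf_quantile_levels: np.ndarray
    cdf_rts: np.ndarray
    caf_levels: np.ndarray
    caf_rt: np.ndarray
    caf_accuracy: np.ndarray
    error_rate: float

    def stack(self) -> np.ndarray:
        """All measure points as one vector (for banding/averaging)."""
        return np.concatenate(
            [self.cdf_rts, self.caf_rt, self.caf_accuracy, [self.error_rate]]
        )


@dataclass
class OverlapResult:
    proportion_significant: float
    n_reps: int
    n_draws_per_cell: int
    alpha: float

    @property
    def decision(self) -> bool:
        return self.proportion_significant >= 0.95


def cdf_quantiles(rts) -> np.ndarray:
    """Empirical RT quantiles at the 17 CDF levels (linear interpolation)."""
    rts = np.asarray(rts, dtype=float)
    if len(rts) < 17:
        raise ValueError(f"need >= 17 observations, got {len(rts)}")
    return np.quantile(rts, CDF_LEVELS)


def caf(rts, correct) -> tuple[np.ndarray, np.ndarray]:
    """Conditional accuracy function: (mean rt, accuracy) in 5 RT bands.

    Trials are rank-split into the quantile bands [0-20%), [20-40%), ...,
    [80-100%] whose centres are the 10...90% CAF levels; correct and error
    trials are pooled before binning.
    """
    rts = np.asarray(rts, dtype=float)
    correct = np.asarray(correct, dtype=float)
    if len(rts) < 10:
        raise ValueError(f"need >= 10 trials, got {len(rts)}")
    order = np.argsort(rts, kind="mergesort")
    bands = np.array_split(order, 5)
    mean_rt = np.array([rts[b].mean() for b in bands])
    acc = np.array([correct[b].mean() for b in bands])
    return mean_rt, acc


def summarize_trials(rts, correct) -> DistributionalSummary:
    """Distributional summary of observed or simulated trials."""
    rts = np.asarray(rts, dtype=float)
    correct = np.asarray(correct, dtype=float)
    caf_rt, caf_acc = caf(rts, correct)
    return DistributionalSummary(
        cdf_quantile_levels=CDF_LEVELS.copy(),
        cdf_rts=cdf_quantiles(rts),
        caf_levels=CAF_LEVELS.copy(),
        caf_rt=caf_rt,
        caf_accuracy=caf_acc,
        error_rate=float(1.0 - correct.mean()),
    )


def model_summary(params, n_trials: int = 2000, cfg: SimConfig = SimConfig(),
                  *, seed: int) -> DistributionalSummary:
    """Simulate ``n_trials`` at ``params`` and summarize them.

    The upper boundary codes the correct response; timeouts are dropped.
    """
    trials = simulate(params, n_trials, cfg, seed=seed).decided()
    return summarize_trials(trials.rt, trials.response == UPPER)


def group_summary(summaries: list[DistributionalSummary]) -> DistributionalSummary:
    """Average participant summaries point-wise."""
    if not summaries:
        raise ValueError("no summaries to average")
    return DistributionalSummary(
        cdf_quantile_levels=CDF_LEVELS.copy(),
        cdf_rts=np.mean([s.cdf_rts for s in summaries], axis=0),
        caf_levels=CAF_LEVELS.copy(),
        caf_rt=np.mean([s.caf_rt for s in summaries], axis=0),
        caf_accuracy=np.mean([s.caf_accuracy for s in summaries], axis=0),
        error_rate=float(np.mean([s.error_rate for s in summaries])),
    )


def credible_band(draws_per_participant: list[PosteriorDraws], model_cls,
                  n_samples: int = 1000, n_trials: int = 2000,
                  cfg: SimConfig = SimConfig(), *, seed: int,
                  prob: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Credible band over the group distributional summary.

    For each of ``n_samples`` posterior samples: draw one retained
    parameter vector per participant, compute each participant's summary,
    average across participants; the band is the central ``prob`` interval
    across samples at every measure point (stacked as in
    :meth:`DistributionalSummary.stack`).

    Each participant keeps one fixed simulation seed across posterior
    samples (common random numbers), so the band reflects parameter
    uncertainty only — a degenerate posterior yields zero-width bands.
    """
    rng = np.random.default_rng(seed)
    flats = [d.flat() for d in draws_per_participant]
    sim_seeds = [int(rng.integers(2**31)) for _ in flats]
    points = []
    for _s in range(n_samples):
        per_part = []
        for flat, sim_seed in zip(flats, sim_seeds):
            theta = flat[rng.integers(len(flat))]
            params = model_cls.from_vector(theta)
            per_part.append(model_summary(params, n_trials, cfg, seed=sim_seed))
        points.append(group_summary(per_part).stack())
    points = np.asarray(points)
    lo, hi = (1 - prob) / 2 * 100, (1 + prob) / 2 * 100
    return np.percentile(points, lo, axis=0), np.percentile(points, hi, axis=0)


def rm_anova(values: np.ndarray) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA on a participants x conditions table.

    Returns (F, df1, df2, p) with df1 = k-1 and df2 = (k-1)(n-1); no
    sphericity correction is applied.  A table with zero condition
    variance returns F = 0, p = 1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a 2-D participants x conditions table")
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 conditions and >= 3 participants")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells in the ANOVA table")
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if ss_cond <= 0:
        return 0.0, df1, df2, 1.0
    ms_err = ss_err / df2
    if ms_err <= 0:
        return float("inf"), df1, df2, 0.0
    f = (ss_cond / df1) / ms_err
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def posterior_overlap(draws: dict, *, n_draws: int = 10, n_reps: int = 1000,
                      alpha: float = 0.05, seed: int | None = None,
                      rng: np.random.Generator | None = None) -> OverlapResult:
    """Posterior overlap indicator for one parameter.

    ``draws[participant][condition]`` is a 1-D array of posterior draws of
    the parameter.  Per replicate: sample ``n_draws`` values per cell,
    average them, and run the repeated-measures ANOVA across conditions;
    the result is the proportion of replicates with p < alpha.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    participants = sorted(draws)
    conditions = sorted(draws[participants[0]])
    cells = [[np.asarray(draws[p][c], dtype=float) for c in conditions]
             for p in participants]
    n_sig = 0
    for _rep in range(n_reps):
        table = np.array(
            [[rng.choice(cell, size=n_draws).mean() for cell in row]
             for row in cells]
        )
        _f, _d1, _d2, p = rm_anova(table)
        if p < alpha:
            n_sig += 1
    return OverlapResult(
        proportion_significant=n_sig / n_reps,
        n_reps=n_reps,
        n_draws_per_cell=n_draws,
        alpha=alpha,
    )


def integration_time(beta: float, n: float, level: float = 0.97) -> float:
    """Time for the evidence growth function to reach ``level``.

    The smallest t with theta(t) >= level; computed by inverting the
    regularized incomplete gamma function (t = P^{-1}(n, level) / beta).
    """
    if not (beta > 0 and n > 0):
        raise ValueError("beta and n must be positive")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    return float(special.gammaincinv(n, level) / beta)
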