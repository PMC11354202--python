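"""Synthetic two-choice behavioral datasets with the 2 x 4 repeated-measures
structure the analysis assumes, plus the RT-cleaning and participant
exclusion filters.

The generator emulates a noise-discrimination experiment: two stimulus
identities (e.g. leftward/rightward coherent motion) crossed with four
noise levels (10/40/70/80% noise dots), 32-64 trials per noise level per
participant.  Per-condition ground-truth parameters follow the qualitative
pattern recovered from such experiments — drift rate decreasing and
boundary separation increasing with noise, non-decision time constant —
and participants differ by a truncated-normal jitter around the condition
parameters (SD = 10% of each parameter value; there is no group-level
model, the jitter only makes participants distinguishable).

The data table schema is ``participant, condition, stimulus, response,
correct, rt`` with RTs in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import (
    DDMParams,
    TVDDMParams,
    SimConfig,
    UPPER,
    simulate,
)

__all__ = [
    "DEFAULT_NOISE_LEVELS",
    "StudyDesign",
    "GroundTruth",
    "default_ground_truth",
    "generate_dataset",
    "clean_rts",
    "exclusion_screen",
    "COLUMNS",
]

DEFAULT_NOISE_LEVELS = ("10", "40", "70", "80")
COLUMNS = ("participant", "condition", "stimulus", "response", "correct", "rt")


@dataclass(frozen=True)
class StudyDesign:
    """2 x 4 repeated-measures design description.

    ``trials_per_cell`` is the number of trials per participant per noise
    level, split as evenly as possible across the two stimulus identities
    (the reference motion design uses 32, the color design 64).
    """

    n_participants: int = 46
    noise_levels: tuple[str, ...] = DEFAULT_NOISE_LEVELS
    stimuli: tuple[str, str] = ("left", "right")
    trials_per_cell: int = 32
    rt_bounds: tuple[float, float] = (0.150, 3.000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        if not self.rt_bounds[0] < self.rt_bounds[1]:
            raise ValueError("rt_bounds must be (low, high) with low < high")
        if len(self.stimuli) != 2:
            raise ValueError("exactly two stimulus identities are required")


@dataclass(frozen=True)
class GroundTruth:
    """Generative model and per-condition parameters.

    ``jitter_frac`` scales the per-participant truncated-normal jitter:
    each parameter is redrawn per participant from N(value, jitter_frac *
    value), truncated to the model's validity region.
    """

    model: str
    params: dict[str, object]  # condition label -> DDMParams | TVDDMParams
    jitter_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.model not in ("ddm", "tvddm"):
            raise ValueError(f"unknown model {self.model!r}")
        cls = DDMParams if self.model == "ddm" else TVDDMParams
        for cond, p in self.params.items():
            if not isinstance(p, cls):
                raise TypeError(f"condition {cond!r}: expected {cls.__name__}")


def default_ground_truth(model: str = "ddm",
                         noise_levels: tuple[str, ...] = DEFAULT_NOISE_LEVELS,
                         jitter_frac: float = 0.10) -> GroundTruth:
    """Ground truth encoding the qualitative noise effects: v decreasing,
    A increasing, ter (and the remaining parameters) constant in noise."""
    if len(noise_levels) != 4:
        raise ValueError("default ground truth is defined for 4 noise levels")
    if model == "ddm":
        vs = (0.40, 0.30, 0.20, 0.14)
        As = (0.14, 0.16, 0.18, 0.20)
        params = {
            lvl: DDMParams(A=a, ter=0.26, v=v, sz=0.05, sv=0.07, ster=0.28)
            for lvl, v, a in zip(noise_levels, vs, As)
        }
    elif model == "tvddm":
        vs = (0.45, 0.35, 0.27, 0.20)
        As = (0.17, 0.19, 0.21, 0.23)
        params = {
            lvl: TVDDMParams(A=a, ter=0.18, v=v, beta=25.0, n=5.0, sigma2=0.1, sv=0.25)
            for lvl, v, a in zip(noise_levels, vs, As)
        }
    else:
        raise ValueError(f"unknown model {model!r}")
    return GroundTruth(model=model, params=params, jitter_frac=jitter_frac)


def _jitter_params(params, frac: float, rng: np.random.Generator, max_redraws: int = 100):
    """Per-participant parameter jitter, redrawn until the vector is valid."""
    if frac == 0.0:
        return params
    base = params.to_vector()
    cls = type(params)
    for _ in range(max_redraws):
        theta = rng.normal(base, frac * np.abs(base))
        theta = np.abs(theta)  # reflect at zero; all parameters are non-negative
        if cls.is_valid_vector(theta):
            return cls.from_vector(theta)
    raise RuntimeError("invalid jittered parameters after 100 redraws")


def generate_dataset(design: StudyDesign, truth: GroundTruth,
                     cfg: SimConfig = SimConfig()) -> pd.DataFrame:
    """Generate the behavioral table for a full study.

    For each participant x condition the condition parameters are jittered,
    ``trials_per_cell`` trials are simulated with the generating model, and
    stimulus identities are assigned in balanced randomized order.  The
    upper boundary is the correct response: response = stimulus when the
    trial is absorbed at the upper boundary, the other identity otherwise.
    Deterministic given (design, truth).
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    n_cell = design.trials_per_cell
    half = n_cell // 2
    stim_template = np.array([0] * (n_cell - half) + [1] * half)
    for p in range(design.n_participants):
        pid = f"p{p + 1:03d}"
        p_rng = np.random.default_rng(rng.integers(2**31))
        for cond in design.noise_levels:
            params = _jitter_params(truth.params[cond], truth.jitter_frac, p_rng)
            # simulate until every trial is absorbed (timeouts are redrawn;
            # the data table must contain a decided response in every row)
            resp = np.empty(0, dtype=int)
            rt = np.empty(0)
            need = n_cell
            for _attempt in range(100):
                trials = simulate(params, need, cfg, seed=int(p_rng.integers(2**31)))
                dec = trials.decided()
                resp = np.concatenate([resp, dec.response])
                rt = np.concatenate([rt, dec.rt])
                need = n_cell - len(resp)
                if need == 0:
                    break
            else:
                raise RuntimeError(
                    f"could not obtain {n_cell} decided trials for {pid}/{cond}"
                )
            stim_idx = stim_template.copy()
            p_rng.shuffle(stim_idx)
            correct = resp == UPPER
            resp_idx = np.where(correct, stim_idx, 1 - stim_idx)
            for i in range(n_cell):
                rows.append(
                    (
                        pid,
                        cond,
                        design.stimuli[stim_idx[i]],
                        design.stimuli[resp_idx[i]],
                        bool(correct[i]),
                        float(rt[i]),
                    )
                )
    return pd.DataFrame(rows, columns=list(COLUMNS))


def clean_rts(table: pd.DataFrame,
              bounds: tuple[float, float] = (0.150, 3.000)) -> tuple[pd.DataFrame, int, float]:
    """Remove RT outliers: rows with rt < bounds[0] or rt > bounds[1].

    Boundary values are kept (the cut is strictly faster/slower than the
    thresholds).  Returns (cleaned table, n removed, fraction removed);
    raises if nothing survives.
    """
    low, high = bounds
    keep = (table["rt"] >= low) & (table["rt"] <= high)
    cleaned = table[keep].reset_index(drop=True)
    n_removed = int((~keep).sum())
    if len(cleaned) == 0:
        raise ValueError("no trials survive cleaning")
    return cleaned, n_removed, n_removed / len(table)


def exclusion_screen(table: pd.DataFrame, chance: float = 0.5) -> list[str]:
    """Participants whose overall accuracy is strictly below chance."""
    acc = table.groupby("participant")["correct"].mean()
    return sorted(acc.index[acc < chance])
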