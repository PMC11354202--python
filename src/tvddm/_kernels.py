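"""Numba-jitted inner loops: Euler-Maruyama chunk advancement and Gaussian
kernel-density evaluation.

Gaussian increments are generated in blocks by numpy's PCG64 ziggurat
sampler (fast) and consumed here in chunked lockstep: each kernel call
advances every still-running trial by up to ``chunk`` Euler steps using one
row of the pre-drawn noise matrix.  Trial status codes: RUNNING (-3) while
unabsorbed, TIMEOUT (-1) after the step cap, LOWER (0) / UPPER (1) on
absorption.
"""

from __future__ import annotations

import numpy as np
from numba import njit

UPPER = 1
LOWER = 0
TIMEOUT = -1
RUNNING = -3


@njit(cache=True, fastmath=True)
def ddm_chunk(x, vt_dt, steps, status, dec_steps, act, noise, c, A, n_steps_max):
    """Advance active DDM trials by up to one noise chunk.

    x, vt_dt, steps, status, dec_steps are per-trial state arrays of the
    current attempt cohort; ``act`` indexes the still-running trials and
    ``noise[r]`` is the standard-normal increment row for trial act[r].
    """
    chunk = noise.shape[1]
    for r in range(act.shape[0]):
        i = act[r]
        xi = x[i]
        d = vt_dt[i]
        s = steps[i]
        for k in range(chunk):
            if s >= n_steps_max:
                break
            xi += d + c * noise[r, k]
            s += 1
            if xi >= A:
                status[i] = UPPER
                dec_steps[i] = s
                break
            if xi <= 0.0:
                status[i] = LOWER
                dec_steps[i] = s
                break
        x[i] = xi
        steps[i] = s
    return


@njit(cache=True, fastmath=True)
def tvddm_chunk(x, vt, steps, status, dec_steps, act, noise, drift_dt, noise_sd, A, n_steps_max):
    """Advance active TV-DDM trials by up to one noise chunk.

    drift_dt[s] = theta(s*dt)*dt and noise_sd[s] = sqrt(sigma^2*theta(s*dt)
    + sigma2^2)*sqrt(dt) are the per-step coefficients on the Euler grid
    (left endpoint of step s+1).
    """
    chunk = noise.shape[1]
    for r in range(act.shape[0]):
        i = act[r]
        xi = x[i]
        vi = vt[i]
        s = steps[i]
        for k in range(chunk):
            if s >= n_steps_max:
                break
            xi += vi * drift_dt[s] + noise_sd[s] * noise[r, k]
            s += 1
            if xi >= A:
                status[i] = UPPER
                dec_steps[i] = s
                break
            if xi <= 0.0:
                status[i] = LOWER
                dec_steps[i] = s
                break
        x[i] = xi
        steps[i] = s
    return


@njit(cache=True, fastmath=True)
def gaussian_kde_eval(x_sorted, h, queries):
    """Mean Gaussian kernel density of sorted sample ``x_sorted`` at ``queries``.

    Kernels beyond 8 bandwidths contribute < 1e-14 relatively and are
    skipped; the sorted order allows an early break.
    """
    m = x_sorted.shape[0]
    out = np.zeros(queries.shape[0])
    inv_h = 1.0 / h
    norm = 1.0 / (np.sqrt(2.0 * np.pi) * h * m)
    for j in range(queries.shape[0]):
        q = queries[j]
        lo = np.searchsorted(x_sorted, q - 8.0 * h)
        acc = 0.0
        for k in range(lo, m):
            u = (q - x_sorted[k]) * inv_h
            if u < -8.0:
                break
            acc += np.exp(-0.5 * u * u)
        out[j] = acc * norm
    return out
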