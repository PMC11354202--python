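# tvddm

Bayesian fitting and comparison of two evidence-accumulation models of
two-choice perceptual decisions in noise: the standard drift-diffusion
model (DDM) and the time-varying drift-rate model (TV-DDM), in which a
gradual perceptual-integration stage modulates evidence accumulation.

The package is aimed at researchers modelling choice/RT data from
noise-discrimination experiments (e.g. random-dot motion or color
coherence tasks) who want to (i) fit both models per participant and
condition with simulation-based (KDE) likelihoods and DE-MCMC, (ii)
compare them with Bayes factors from thermodynamic integration (plus DIC /
BPIC), and (iii) test whether experimental manipulations selectively
influence the parameters they are supposed to influence.

## Models

DDM: dx = v dt + σ dW between absorbing boundaries 0 and A, start A/2,
non-decision time t_er, between-trial variability in start point (sz),
drift (sv) and non-decision time (st_er); σ = 0.1 fixes the evidence scale.

TV-DDM: dx = v θ(t) dt + √(σ² θ(t) + σ₂²) dW, where
θ(t) = P(n, βt) — the regularized lower incomplete gamma function — is the
fraction of the percept formed by time t (n cascaded filters with rate β),
and σ₂ is premature-sampling noise present before the percept has formed.

Likelihoods are approximated by defective kernel densities over simulated
trials (probability density approximation); parameters are estimated with
a two-stage differential-evolution MCMC (current-to-best search, then
DE-MCMC with a 30% likelihood "purification" step); convergence is gated
on split R-hat ≤ 1.1; marginal likelihoods come from thermodynamic
integration over a temperature ladder and are interpreted on the Jeffreys
evidence scale. See `docs/methods.md` for the full model and estimator
account.

## Worked example

Simulate one synthetic participant from the default study design (2
stimuli × 4 noise levels), fit the DDM to one noise level, and summarize:

```python
import numpy as np
from tvddm import (StudyDesign, default_ground_truth, generate_dataset,
                   clean_rts, fit_condition, SamplerConfig, LikelihoodConfig,
                   eap, credible_interval, integration_time)

design = StudyDesign(n_participants=1, trials_per_cell=64, seed=1)
truth = default_ground_truth("ddm", jitter_frac=0.0)
table = generate_dataset(design, truth)
table, n_removed, frac = clean_rts(table)
cell = table[table["condition"] == "40"]

draws = fit_condition(
    cell, "ddm",
    sampler_cfg=SamplerConfig(n_chains=12, stage1_iters=200,
                              stage2_iters=600, burn_in=200),
    like_cfg=LikelihoodConfig(n_sim=500),
    seed=11,
)
print("max split R-hat:", round(draws.meta["max_split_rhat"], 3))
print("EAP:", {k: round(v, 3) for k, v in eap(draws).items()})
ci = credible_interval(draws)
for k in ("A", "ter", "v"):
    print(f"95% CI {k}:", np.round(ci[k], 3))
print("97% integration time at beta=25, n=5:",
      round(integration_time(25, 5), 4), "s")
```

Output:

```
max split R-hat: 1.071
EAP: {'A': 0.169, 'ter': 0.268, 'v': 0.337, 'sz': 0.066, 'sv': 0.114, 'ster': 0.225}
95% CI A: [0.106 0.277]
95% CI ter: [0.135 0.43 ]
95% CI v: [0.188 0.552]
97% integration time at beta=25, n=5: 0.3984 s
```

The fit converged (max split R-hat below the 1.1 criterion). The "40%
noise" cell of the ground truth used A = 0.16, t_er = 0.26, v = 0.30; the
EAPs land close to all three and each lies inside its 95% credible
interval — with 64 trials the posteriors are wide, which is exactly what
the credible intervals report. The integration time is the time for θ(t)
to reach 97% at the TV-DDM prior-mean growth parameters: ~0.4 s of
perceptual integration before the percept is effectively complete.

The same stages are scriptable from the shell:

```bash
tvddm synth --seed 1 --out data.csv
tvddm fit --model ddm --data cell.csv --chains 30 --stage1 1000 \
          --stage2 3000 --burnin 500 --nsim 1000 --seed 7 --out fit.nc
tvddm compare --fit1 fit_ddm.nc --fit2 fit_tvddm.nc --data cell.csv \
              --temps 30 --gens 10000 --burnin 1500 --seed 7 --out bf.json
tvddm run-study --seed 1 --out study_out/
```

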