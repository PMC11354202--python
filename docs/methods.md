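# Methods

`tvddm` implements a Bayesian pipeline for fitting and comparing two
evidence-accumulation models of two-choice decisions under stimulus noise:
the standard drift-diffusion model (DDM) and a time-varying drift-rate
variant (TV-DDM) in which evidence accumulation is modulated by a gradual
perceptual-integration stage.

## Models

**DDM.** Evidence x(t) follows a Wiener process between absorbing
boundaries at 0 and A (start point z = A/2, unbiased),

    dx = v dt + sigma dW,

with drift v (evidence/s), diffusion coefficient sigma (fixed at 0.1 to set
the evidence scale), and non-decision time ter added to the first-passage
time. Between-trial variability: start point z ~ U(A/2 ± sz/2), drift
v_trial ~ N(v, sv), non-decision time ~ U(ter ± ster/2). Upper-boundary
absorption codes the correct response. Six free parameters:
A, ter, v, sz, sv, ster.

**TV-DDM.** The percept is not available instantaneously; its formation is
described by the growth function

    theta(t) = P(n, beta t),

the regularized lower incomplete gamma function — the response of n
cascaded linear filters with rate beta. Drift and stimulus-driven diffusion
are scaled by theta(t), while a premature-sampling noise sigma2 is present
throughout:

    dx = v theta(t) dt + sqrt(sigma^2 theta(t) + sigma2^2) dW.

theta is evaluated on the decision-stage clock (from stimulus onset,
excluding ter) at the left endpoint of each Euler step. Seven free
parameters: A, ter, v, beta, n, sigma2, sv; no start-point or ter
variability. The printed source equation for the diffusion term is
ambiguous; the reading above (stimulus diffusion grows with theta,
premature noise constant) is the natural one and is fixed throughout.

The "integration time" summary is the time at which theta reaches 97%,
computed by inverting the incomplete gamma function.

## Simulation

Both models are integrated by Euler–Maruyama with dt = 1 ms, sigma = 0.1,
times in seconds. Trials not absorbed by max_t = 10 s are redrawn up to 10
times, then recorded as timeouts (excluded from KDE construction; their
probability mass stays in the defective weights). Gaussian increments are
drawn in blocks from numpy's SFC64 generator (float32 — increment noise
needs no more precision than the Euler discretization error) and consumed
by numba-jitted kernels in chunked lockstep; one seed per simulation call
makes every trial set reproducible from (params, n_trials, config, seed).
We deliberately do not give each trial its own RNG substream: per-trial
re-seeding costs more than the simulation itself at likelihood-call sizes,
and reproducibility is defined at the call level.

Euler first-passage simulation has a known O(sqrt(dt)) boundary-overshoot
bias; at dt = 1 ms and the default parameter scale it shifts choice
probabilities by about 1.5e-3. Monte-Carlo checks against the closed-form
absorption probability are therefore run at sample sizes where 3 binomial
SEs dominate that bias.

## Likelihood (probability density approximation)

Neither model has a tractable likelihood with between-trial variability, so
the likelihood of each observed (choice, RT) pair is a defective Gaussian
KDE over n_sim freshly simulated trials: per response category, a KDE over
that category's RTs weighted by the simulated choice probability, floored
at 1e-10 so isolated observations cannot return -inf. Bandwidths follow
Silverman's rule (0.9 min(sd, IQR/1.34) m^-1/5) per category; a Scott rule
and a log-RT transform are config options (off by default). Categories
with fewer than two simulated trials evaluate to the floor; a simulation in
which every trial times out signals an invalid parameter region (-inf).

The KDE is evaluated by linear binning on a 4096-point grid followed by
Gaussian smoothing in Fourier space and linear interpolation at the data
(agreement with the exact kernel sum is ~1e-4 relative; the exact route is
kept as `eval_method="direct"` and cross-checked in tests).

Two properties of this estimator drive sampler design decisions:

- it is *noisy*: repeated calls at the same parameters differ (SD ~1.5
  nats at 64 observations and n_sim = 500);
- the *log* density is biased downward (Jensen: E[log f_hat] < log f), and
  the bias is parameter-region dependent — smoother predictive densities
  are less penalized. The bias scales like 1/n_sim.

`analytic_wiener_density` provides the exact series solution for the
first-passage density of the variability-free DDM; it is a test oracle
only, never the production likelihood.

## Sampling

Parameters are estimated per participant and condition with a two-stage
differential-evolution MCMC and truncated-normal priors TN(mu, mu, 0, inf)
whose means are A=0.17, ter=0.26, v=0.25, sz=0.05, sv=0.07, ster=0.28 (DDM)
and A=0.2, ter=0.18, v=0.3, beta=25, n=5, sigma2=0.1, sv=0.25 (TV-DDM).

- **Stage 1 (search):** current-to-best DE with greedy acceptance,
  proposal x_i + 0.5 (x_best - x_i) + 0.5 (x_r1 - x_r2) + U(±1e-4 sd_prior);
  1000 generations, 30 chains at the reference budget. The final
  population seeds stage 2.
- **Stage 2 (posterior):** DE-MCMC, proposal x_i + gamma (x_r1 - x_r2) +
  jitter with gamma = 2.38/sqrt(2d) (gamma = 1 with probability 0.1 for
  mode jumping), Metropolis acceptance on the noisy posterior ratio; 3000
  generations, 500 burn-in at the reference budget (30 x 3000 = 90,000
  generated draws; 75,000 retained).
- **Purification:** with probability 0.3 per chain per generation the
  stored log-likelihood is re-evaluated with a fresh simulation seed,
  preventing chains from sticking at lucky overestimates.
- **Initialization:** prior draws, rejection-sampled to joint model
  validity (sz < A, ster <= 2 ter). A jointly invalid chain can never be
  repaired by current-to-best pulls when its violation exceeds the best
  chain's margin, and -inf states can only enter at initialization, so
  this excludes them once and for all.
- **Migration:** with probability 0.1 per generation the states of a
  random chain subset are cyclically permuted. All chains share one
  target, so the permutation is exactly measure-preserving; it relocates
  outlier chains that the noisy likelihood would otherwise strand. At the
  reduced convergence-gate budget (12 chains, 600 generations) this is the
  difference between max split R-hat ~1.2-1.3 and ~1.05.

Convergence is assessed with split R-hat (each retained chain halved;
criterion 1.1). Posteriors are summarized by the EAP (marginal posterior
mean) and central 95% credible intervals.

## Model comparison

Marginal likelihoods are estimated by thermodynamic integration: one
DE-MCMC chain per temperature t_k = (k/(K-1))^5 (K = 30, 10,000
generations, 1500 burn-in at the reference budget) targets the power
posterior prior x likelihood^t_k; chains exchange difference vectors but
never states. The log marginal likelihood integrates the post-burn-in
mean log-likelihood over temperature with the variance-corrected
(second-order) trapezoid, using d/dt E_t[log L] = Var_t[log L]: the plain
trapezoid is biased downward by the concavity of the integrand (-0.13 nats
already at K = 10 on a conjugate toy, computable exactly), while the
corrected rule is accurate to ~0.01 nats there. Because only variance
*differences* across adjacent temperatures enter, constant PDA estimator
noise cancels.

Bayes factors are mapped to the standard Jeffreys scale (anecdotal 1-3,
moderate 3-10, strong 10-30, very strong 30-100, decisive > 100, with
reciprocal bounds; the printed source table for these categories is
internally inconsistent, so the standard bounds are used). DIC and BPIC
are computed from the posterior mean deviance (each deviance averaged over
K >= 20 likelihood re-evaluations to tame PDA noise), with
pD = Dbar - D(EAP), DIC = Dbar + pD, BPIC = Dbar + 2 pD.

## Distributional measures and inference summaries

- CDF: empirical RT quantiles at 17 levels, 10%...90% in 5% steps
  (type-7 linear interpolation; the estimator is a recorded choice).
- CAF: trials rank-split into the RT-quantile bands [0-20%), ..., [80-100%]
  whose centers are the 10/30/50/70/90% levels; per band mean RT and
  accuracy, correct and error trials pooled before binning.
- Model-based summaries simulate 2000 trials per condition at a
  participant's EAPs; group summaries average participants.
- Credible bands: 1000 posterior draws per participant; each draw's group
  summary is computed with per-participant common random numbers so the
  band reflects parameter uncertainty only (a degenerate posterior gives
  exactly zero-width bands).
- Effects of noise on EAPs: one-way repeated-measures ANOVA with
  df = (k-1, (k-1)(n-1)), no sphericity correction.
- Posterior overlap indicator: per replicate, 10 posterior draws per
  participant x condition are averaged and the ANOVA re-run; the
  indicator is the proportion of 1000 replicates with p < 0.05, with
  >= 0.95 read as an effect robust to posterior uncertainty.

## Synthetic data generator

The generator emulates a 2 x 4 repeated-measures noise-discrimination
design: two stimulus identities x four noise levels (10/40/70/80%), 32-64
trials per noise level per participant (46 participants, 32 trials/level in
the motion-task default), RT cleaning at 150 ms / 3000 ms (strict
inequalities; boundary values kept) and exclusion of participants with
below-chance accuracy. The default ground truth encodes the qualitative
pattern such experiments recover: drift rate decreasing and boundary
separation increasing with noise, non-decision time constant. Participants
are differentiated by truncated-normal jitter with SD = 10% of each
parameter value — a declared convention, not an inference target; there is
no group-level model. No contaminant/guessing process is simulated, and
the mapping from nominal noise percentage to drift is left to explicit
ground-truth tables rather than a psychophysical linking function.

Passing tests on these synthetic tables show that the pipeline recovers
what it assumes (the generating process is one of the two fitted models);
they cannot show that either model is adequate for real data, that real
between-participant variation is normal jitter, or that real contaminant
processes are absent.

## Problem sizes used in the checks

The reference budgets (30 chains, 1000 + 3000 generations, KDE from 1000
simulated trials, 30 temperatures x 10,000 generations) are configuration
defaults. The package's own validation suite runs scaled-down versions,
chosen as the smallest budgets at which each statistic is statistically
meaningful:

- convergence gate: one synthetic participant, 64 trials per condition, 12
  chains, 200 + 600 generations (200 burn-in), n_sim = 500;
- parameter recovery: 512 trials, 12 chains, 40 + 600 generations,
  5 replicate seeds per model. The KDE size is 500 for the DDM and 1000
  (the reference value) for the TV-DDM: the TV-DDM likelihood has a
  near-scale-invariant ridge (A, v, sv, sigma2 jointly scaled up with
  sigma2 swamping the fixed stimulus diffusion), and at n_sim = 500 the
  region-dependent log-KDE bias (~5 nats across the ridge at 512
  observations) is large enough to tilt the effective posterior away from
  the generating values. Non-decision time and drift recover cleanly for
  both models; the TV-DDM boundary separation does not fully (see the
  limitations below) — the suite reports this rather than hiding it.
- model recovery: Bayes-factor direction on the same datasets, TIDE with
  a reduced budget (5 temperatures x 200 generations, KDE size 500). At
  this scale the marginal-likelihood estimates are initialization-dominated
  transients (the same dataset's log marginal likelihood moves by tens of
  nats across initializations and KDE sizes), so this check documents the
  behaviour of the scaled pipeline rather than certifying discrimination;
  equilibrated estimates need the reference budget (30 temperatures x
  10,000 generations), which is hours of CPU per dataset pair.
- evidence oracle: conjugate normal-normal toy, 10 temperatures x 2000
  generations.

## Known limitations

- The PDA log-likelihood is biased (order 1/n_sim); all posterior widths
  and Bayes factors inherit some of that bias at small KDE sizes. The
  purification step controls stickiness, not bias.
- TV-DDM parameters are weakly identified at single-condition sample
  sizes; the sigma2 ridge makes the A/v/sv scale poorly constrained. In
  recovery studies at 512 trials the 95% credible interval for the TV-DDM
  boundary separation sits above the generating value for roughly half of
  the data draws, and this persists with KDE sizes up to 2000, a log-RT
  KDE, and 2000-generation chains (split R-hat 1.02) — it is a property
  of the model-plus-priors at this design size, not of the sampler.
  Joint designs (multiple noise levels with shared parameters) would
  identify the boundary better, but the pipeline deliberately fits
  conditions independently, matching its design contract.
- Bayes factors between these two models at single-condition designs are
  fragile: the TV-DDM's gamma onset plus premature-sampling noise can
  mimic the DDM's between-trial variability almost exactly, so the true
  evidence gaps are small relative to the PDA noise and bias at
  affordable KDE sizes.
- Euler integration at dt = 1 ms carries a small first-passage bias;
  halving dt is a config change away but doubles simulation cost.
- The timeout-redraw rule slightly truncates the extreme RT tail at
  pathological parameters; it exists to keep defective densities proper.
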