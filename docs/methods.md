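# Methods

`painseq` implements a complete simulation-and-inference pipeline for
studying statistical learning of noxious-input sequences: how observers
track a drifting latent pain intensity through noisy stimuli, and how much
their reported perception is pulled towards their expectation.

## Generative process of the stimulus sequences

A sequence is a concatenation of *chunks*.  Chunk means `I_k` are drawn from
U(3.5, 10.5), redrawn until consecutive means differ by at least 2 intensity
levels so transitions are perceptible.  Chunk lengths are uniform integers
on {L−a, …, L+a} with jitter a = 3; the mean length L implements volatility
(L = 15 high, L = 25 low).  Trial values are Normal(I_k, σ²), with σ²
implementing stochasticity (1.75 high, 0.25 low).  Values are rounded to
the nearest integer level; a trial whose rounded value leaves the valid
range [1, 13] is discarded and redrawn individually, preserving the chunk
structure.  Chunks are drawn until they cover the 80 trials and the final
chunk is truncated.  Centring at level 7 follows from the symmetric mean
support; no post-hoc recentring is applied.

Open choices and their resolution: the separation constraint is enforced
between consecutive chunks only (the natural reading of adjacent chunks
needing to feel different); discretisation is round-to-nearest.  Both are
recorded here because the generative recipe admits either reading.

## Observer models

All five models share the response model

    response ~ Normal(mean_t, [ξ · exp((1 − c_t)/C)]²)

where `c_t ∈ [0, 1]` is the trial's confidence rating and `C > 0` sets how
strongly low confidence inflates response noise (as C → ∞ the effect
vanishes).  Ratings live on a 0–100 scale but the Gaussian is untruncated —
a deliberate simplification; truncation would change the likelihood of
near-boundary responses.  On perception trials the mean is the modelled
percept `P_t`; on prediction trials it is the post-update expectation
`E_{t+1}`.  Beliefs update from the objective input `N_t` on every trial,
whether or not that trial's question was answered; unanswered trials simply
contribute nothing to the likelihood.

* **RL** (α, ξ, E0, C): delta rule `E_{t+1} = E_t + α(N_t − E_t)`; the
  percept is the input itself.
* **eRL** (+γ): percept `P_t = (1−γ)N_t + γE_t`; the prediction error is
  `P_t − E_t`, so expectation shapes both perception and learning.
* **KF** (s, v, ξ, E0, w0, C): the latent mean follows a Gaussian random
  walk with drift sd v, observed with noise sd s.  The tracked uncertainty
  `w_t²` yields the trial-wise gain `α_t = w²/(w² + s²)` and update
  `w²_{t+1} = w²(1−α_t) + v²`.  At v = 0 the filter reduces to conjugate
  Gaussian updating — used as an exactness oracle in the tests.
* **eKF** (+ϵ): the input is itself an imperfect cue of pain
  (`N_t ~ Normal(π_t, ϵ²)`), giving percept weight
  `γ_t = ϵ²/(ϵ² + s² + w²)` on the expectation and gain
  `α_t = w²/(ϵ² + w² + s²)`.  At ϵ = 0 it is exactly the KF.
* **random** (R, ξ, C): a constant responder; the no-learning baseline.

## Hierarchical estimation

Each native parameter is modelled non-centred:
`θ_ij = link(μ_j + τ_j η_ij)` with `μ_j ~ N(0,1)`,
`τ_j ~ half-Student-t(3,0,1)` and `η_ij ~ N(0,1)`.  Links: a logistic
approximation to the standard-Normal CDF for (0,1)-bounded parameters
(α, γ); `exp` for positive scale-like parameters (ξ, s, v, w0, ϵ, C); and
multiplication by 50 for response-scale locations (E0, R), which turns the
standard-Normal group prior into a wide N(0, 50²) on the 0–100 scale.  The
half-t prior is placed directly on τ through a log-link with its Jacobian
(equivalent to the usual gamma-mixture construction, without the auxiliary
variable).  Fits are per condition, jointly over each subject's perception
and prediction responses.

Sampling is Hamiltonian Monte Carlo on the unconstrained vector
`[μ, log τ, η]` with hand-derived analytic gradients: each model's kernel
propagates forward-mode tangents of the trial-wise response mean through
the belief recursion (compiled with numba; validated against central finite
differences at 1e-4 tolerance).  Warmup uses dual averaging of the step
size towards 0.8 acceptance and two diagonal mass-matrix re-estimations;
leapfrog steps are jittered uniformly on {1..32} to decorrelate.
Transitions with Hamiltonian error above 1000, or excursions beyond |z| >
300 on the unconstrained scale (where the links over/underflow), are
rejected as divergent.  Chains are seeded independently through
`SeedSequence` spawning, so every fit is exactly reproducible.

The default `SamplerConfig` is 4 chains × 6000 warmup + 6000 draws;
`SamplerConfig.desk_scale()` (4 × 1000/1000) is the configuration used for
all bundled studies and takes ~30 s for the 12-subject eKF benchmark.
Convergence is judged by split-R-hat < 1.1 over *every* parameter,
including the non-centred offsets, with rank-normalised bulk/tail ESS
reported alongside.

## Model comparison

ELPD is estimated by PSIS-LOO with the single trial response as the
held-out unit (matching the per-trial likelihood; the alternative — leaving
out whole participants — answers a different predictive question).
Pairwise differences to the ELPD-best model carry a standard error computed
from the paired pointwise contributions, and the *sigma effect*
|ΔELPD|/SE ≥ 2 is the significance heuristic.  LOOIC = −2·ELPD.
Observations with Pareto-k > 0.7 are counted and reported, not refit.
Between-condition parameter contrasts take the 95% highest-density interval
of the paired difference of merged-across-chains draws (differencing
interval endpoints has no probabilistic meaning); significance is
zero-exclusion.  Unequal draw counts are reconciled by seeded subsampling
of the longer set.

## Recovery studies

Parameter recovery draws individual parameters from configured group-level
distributions, simulates responses on freshly generated sequences passed
through participant-specific linear input transforms (slope/intercept
sampled from a Gaussian, negative slopes rejected), refits, and correlates
generating with estimated (posterior-mean) individual values.  Categories:
poor r < 0.5, fair to 0.75, good to 0.9, excellent above (half-open at the
boundaries, so r = 0.8 is "good").

Confidence ratings are simulated as the lag-1 autocorrelation of the
transformed inputs over a trailing 10-trial window (shorter than a chunk at
either volatility level, so confidence tracks local stability), mapped
affinely from [−1, 1] to [0, 1]; pre-window trials reuse the first complete
value and a zero-variance window maps to 0.5.  The affine map is one of
several defensible choices and is configurable.

Two group-level configurations ship with the package.
`DEFAULT_GROUP_PARAMS` spans realistic between-subject ranges on the 0–100
response scale (eKF locations s≈8, v≈3, ξ≈8, E0≈50, w0≈5, C≈2, ϵ≈6, with
scales letting s range roughly 3–20 and E0 50±15): a recovery study over a
narrow parameter range says little, so the spreads are deliberately wide.
`WELL_SEPARATED_GROUP_PARAMS`, used by model recovery, lowers response
noise and strengthens the models' distinguishing features (large γ and ϵ,
large w0 so the Kalman gain visibly decays — a signature a constant
learning rate cannot mimic).

Model recovery fits all five models to data simulated from each and
tallies the LOOIC winner into a 5×5 confusion matrix.  Because the model
family is heavily nested — RL inside eRL and (via a constant-gain
parametrisation) inside KF, both inside eKF, and even the random responder
inside eRL/eKF at γ→1/ϵ→∞ — exact LOOIC winners on restricted-model data
are coin flips decided by noise.  Candidates whose ELPD lies within two
standard errors of the winner's are therefore treated as statistical ties
and split the dataset's count equally (flagged in the report), the same
2-sigma heuristic used for comparison.  The bundled study uses 2 datasets
per generating model, 5 subjects and the desk-scale sampler at reduced
draws.

## What the synthetic data do and do not show

The synthetic generator reproduces the chunked sequence process, the
confidence-scaled Gaussian response model, autocorrelation-based confidence
and Gaussian-sampled input transforms.  It does not emulate sensitisation
or habituation across trials, boundary effects of the 0–100 scale (real
ratings pile up at bounds; the model is untruncated), response biases such
as anchoring on the previous rating, or lapses.  Passing tests therefore
demonstrate correctness of the machinery and identifiability under the
model's own assumptions, not that real participants satisfy them.

## Numerical notes and limitations

* Problem sizes for the bundled studies (12 subjects × 80 trials for the
  convergence benchmark; 8 subjects for comparison studies; 2 × 5 datasets
  for model recovery) were chosen so the full suite runs on a single CPU
  in minutes while leaving the statistics interpretable.
* Weakly identified parameters: v and w0 (and to a lesser degree s vs ϵ)
  trade off along a ridge of the Kalman likelihood; their individual-level
  recovery is honestly poor-to-fair and reported as such.
* The plain-HMC sampler (jittered leapfrog, diagonal mass) is adequate for
  these posteriors but is not NUTS: heavy funnel geometries at very small
  group scales would mix more slowly; the half-t prior and non-centring
  keep the bundled studies well-behaved.
* Degenerate inputs are rejected with messages (constant regressors, odd
  trial counts for schedules, single-chain diagnostics, <2 subjects);
  zero-variance confidence windows and LOOIC ties have documented
  conventions rather than errors.
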