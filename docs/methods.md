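# Methods

## Task model

The environment is a two-state reversal-learning task. A hidden state
`s_t ∈ {1, 2}` is constant within episodes and flips at episode
boundaries. A 72-trial block contains exactly 6 episodes ("more stable",
nominal hazard 1/12) or 12 episodes ("more volatile", nominal 1/6);
episode lengths are integers in [4, 24] drawn i.i.d. from a discrete
truncated exponential and rejected until they sum to 72. The
exponential's rate is chosen so that its truncated mean equals
`72 / n_episodes`, which makes the realized hazard match the nominal one;
the rejection step conditions on the sum without changing the shape of
the marginal beyond what that constraint forces.

Each trial shows `n ∈ {2, 4, 6, 8}` oriented stimuli (uniform over
trials). Orientations live on the π-periodic circle; category
distributions are von Mises on doubled angles with concentration
`κ = 0.5`, centered on two orthogonal means `μ_A` and `μ_B = μ_A + π/2`.
The category-A mean is redrawn uniformly on `[0, π)` every trial. The
distribution of trial-wise means is not constrained further; uniform
i.i.d. is the maximally uninformative choice and is what decorrelates
stimulus orientation from the tilt-based stimulus characteristics (see
below).

**Evidence matching.** Sequences are pre-generated as tilts `δ_i` from
the (not yet realized) drawing mean; orientations are materialized as
`θ_i = mod(δ_i + μ_t, π)` only once the drawing mean is known. In the
cue-based condition `μ_t` is a fixed function of the state; in the
outcome-based condition it also depends on the previous response, so Ob
orientations are realized lazily after simulation. In tilt space the
per-stimulus log-odds evidence is `±2κ cos(2δ_i)` in both conditions,
with the sign set by the hidden state alone — a matched pair of blocks
built from one tilt stream therefore provides identical evidence for any
response history. This identity holds to machine precision and is
asserted in the tests.

## Observer model

Log-odds beliefs update as `L_t = F(L_{t-1}) + ℒ_t` with the hazard leak
`F(L) = L + log((1-h)/h + e^{-L}) - log((1-h)/h + e^{+L})`. `F` is odd,
strictly increasing, shrinks `|L|`, and preserves the sign of `L` for
`h < 1/2`; numerically it saturates at `± log((1-h)/h)`. Beliefs are
clipped at ±50 log-odds units before exponentials; this bound is
unreachable at behavioral scales (max 8 units of evidence per trial).

Noise enters at three points:

* **Inference noise** `σ_inf`: i.i.d. `N(0, σ_inf²)` per stimulus
  update (stimulus-level scheme), whose trial-level marginal is
  `N(F(L_{t-1}) + ℒ_t, n σ_inf²)` (response-level scheme). The two
  schemes produce identical response statistics and differ only in the
  within-sequence belief trajectory.
* **Selection noise** `σ_sel`: the response is the sign of
  `N(L_t, σ_sel²)`. An exact zero decision variable is resolved by a
  fair coin from the caller's generator (probability zero under noise;
  the rule exists for reproducible edge-case behavior).
* **Lapses** `p_lapse`: the previous response is repeated blindly.
  Lapses freeze the response only; the belief still updates. Whether
  lapses should also freeze the update is not determined by the
  behavior being modeled (only the repeat probability is specified);
  response-only is the weaker assumption.

The Bayes-optimal observer is `h = 0.125`, all noise zero.

## Fitting

The response likelihood marginalizes the latent belief trajectory; a
bootstrap particle filter estimates it unbiasedly (systematic
resampling every trial; with `σ_inf = 0` all particles coincide and the
estimate is exact, which the tests exploit as a closed-form oracle). A
pseudo-marginal random-walk Metropolis chain samples the parameter
posterior on logit-transformed parameters, with truncated-normal priors
(`h`: 0.2 ± 0.1 on [0,1]; `σ_inf`, `σ_sel`: 0.5 ± 0.2 on [0,10];
`p_lapse`: 0.01 ± 0.05 on [0,1]). The proposal covariance is adapted
during a 20% burn-in and frozen afterwards, mixed with a small
fixed-scale component. Reduced model variants fix parameters to zero
via a free-parameter mask so one sampler serves model selection.
Defaults are desk-scale (hundreds of particles and iterations); the
pseudo-marginal property makes the stationary distribution independent
of the particle count, which the variance and recovery tests check.

Model evidence for Bayesian model selection is estimated by prior
importance sampling — parameters drawn from the prior, particle-filter
likelihoods averaged — which is unbiased on the likelihood scale
because the filter estimate is. Random-effects selection uses the
variational Dirichlet update over model frequencies with exceedance
probabilities by Dirichlet sampling; fixed-effects selection sums
log-evidence over participants.

## Psychometrics

Both curves are trial-level Bernoulli MLE fits (L-BFGS-B, 5 starts).
The reversal curve `p(correct at k) = p0 + (p_rev - p0)(1 - e^{-k/t_rev})`
chains episodes: `p0` is 0.5 for a block's first episode and one minus
the fitted curve's value at the last trial of the preceding episode
afterwards. Bounds: `t_rev ∈ [0.01, 100]`, `p_rev ∈ [0.5, 1]`. Below
`t_rev ≈ 0.3` the curve saturates by `k = 1` and the likelihood is flat
in `t_rev`; tests assert saturation rather than a specific bound value.
The repetition curve `p(repeat) = p_rep + (1-p_rep) σ(β ℒ_rep - β_rep)`
uses the sequence evidence signed in favor of the previous response;
the criterion `β_rep` is reported as the PSE — the magnitude of
conflicting evidence at which repeating and switching are equally
likely (positive when repetition is favored at neutral evidence).
Bounds: `β ∈ [0, 20]`, `p_rep ∈ [0, 0.5]`. Complete separation is
flagged, not raised.

## Stimulus characteristics and neural hazard

Per stimulus: orientation `(cos 2θ, sin 2θ)`; change = circular distance
to the previous stimulus on the π-periodic circle (range `[0, π/2]`;
the first stimulus of a block has none); evidence strength = distance
to the nearest category boundary (boundaries every π/2, so range
`[0, π/4]`); consistency = evidence strength signed by the agreement of
the stimulus's evidence with the current belief `L_{t,i}` (the belief
before stimulus `i` under stimulus-level inference, or the trial prior
under response-level inference). Neutral belief counts as consistent.
The two schemes' consistency variables differ exactly on stimuli where
the within-sequence belief has left the trial prior's sign.

The trial-wise axis randomization decorrelates the orientation
components from everything else (measured |r| < 0.01). It cannot
decorrelate the tilt-based characteristics from each other: consistency
is sign-carrying evidence strength, and with accurate beliefs the sign
is positive on ≈60% of stimuli, giving r(strength, consistency) ≈ 0.23;
change and strength share the current orientation within a trial
(r ≈ 0.14); orientations of successive stimuli within a trial share the
axis (r ≈ 0.06). These structural correlations are properties of the
definitions, not implementation artifacts, and the property tests
assert their measured bounds rather than a blanket zero.

The neural hazard rate `h*` of a feature set is estimated by
recomputing consistency under each hazard on a 13-point log-spaced grid
in [1/32, 1/2], decoding it with the cross-validated encoder, and
taking the vertex of a quadratic fit of precision against log-hazard,
restricted to ±3 grid points around the argmax (the tuning curve is
strongly asymmetric in log-hazard, so a global parabola biases the
vertex) and clipped to the grid hull; a concave-up fit falls back to
the grid argmax with a warning. Belief trajectories for this analysis
use the fast noise-free recursion by default; conditioning a particle
filter on responses is available through the fitting module.

## Coding-unit simulation

Populations of `n = 300` linear units code a standardized scalar
through `n_sel = 100` selective units of unit gain (`z_i = β_i x + ε`,
`ε ~ N(0, σ²)`); two conditions share a fraction `ω` of selective
units. Encoding follows sensor-style multivariate analysis: per-feature
univariate least-squares weights on 11/12 interleaved training folds
(features z-scored on training statistics), test projections pooled
across folds before one correlation, Fisher-transformed (capped at
`|r| = 1 - 1e-12`). Cross-condition generalization applies one
condition's weights to the other's test folds with matched train/test
volumes. The triple `(ω, σ_1, σ_2)` is fitted to the four precision
values by bounded least squares against an analytic matched-filter
expectation that accounts for per-unit standardization and
weight-estimation noise; the analytic model is validated against full
population simulations in the tests (ω recovered within ±0.05 across
`ω ∈ {0, …, 1}`, σ within ~15%).

## Synthetic cohorts

A cohort subject performs four matched Cb/Ob block pairs (two per
volatility). Subject-level parameters are truncated normals with the
fitted group means and between-subject SDs reconstructed as
SEM·√24 (h: 0.191 ± 0.108 Cb, 0.115 ± 0.073 Ob; σ_inf: 0.512 ± 0.118,
0.550 ± 0.162); no subject-level distributions beyond these moments are
implied by the group statistics. The two conditions' σ_inf share a
latent Gaussian factor mixed to a cross-subject correlation of 0.63 —
the simplest mechanism achieving that correlation. Simulated "MEG"
features assign each characteristic a disjoint pool of units inside one
feature array with shared background noise, and build the consistency
channel from noise-free beliefs at a configurable true hazard per
condition. These features reproduce only the statistical structure the
decoding analyses rely on — linear selective codes, condition overlap,
hazard-dependent consistency — and none of the temporal
autocorrelation, sensor covariance, or artifacts of real recordings, so
passing tests certify the analysis chain, not claims about real neural
data.

## Known limitations and open points

* **Optimal-observer accuracy.** Under the stated generative
  parameters (i.i.d. von Mises tilts at κ = 0.5, 6/12 episodes per
  block), the Bayes-optimal observer attains ≈83% accuracy, not the
  ≈88% reference value the acceptance checks compare against. The ceiling is
  structural: the within-episode asymptote is ≈92% and ≈11% of trials
  are first-after-reversal trials at ≈50% accuracy. Simulating the
  noisy observer at the fitted group-mean parameters similarly yields
  ≈78% accuracy and slightly smaller PSE/t_rev than the human fits —
  a uniform shortfall in effective evidence suggesting that reference
  stimulus sequences carried some variance reduction not derivable
  from the stated marginal distribution (a per-sequence
  stratified-quantile scheme, for comparison, yields ≈90%). All
  relative and ordinal quantities (the ≈42% prior-belief boost,
  condition orderings, recovery contracts) are insensitive to this.
* The marginal-likelihood estimator is a documented choice (prior
  importance sampling), validated on synthetic data, not a numerical
  match to any particular alternative.
* Problem sizes in tests and drivers (hundreds of particles/iterations,
  tens of sessions) are chosen for desk-scale runs; all recovery
  contracts are stated at those sizes.
* Pseudo-time latency structure of real stimulus-locked responses is
  not modeled; the feature simulator has no time axis.
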