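"""Particle-filter likelihood, particle MCMC, and Bayesian model selection.

The noisy observer's response likelihood p(r_{1:T} | stimuli, params) has
no closed form because the latent belief trajectory is integrated out. A
bootstrap particle filter provides an unbiased estimate: particles carry
latent beliefs, are propagated through the noisy update, weighted by the
response likelihood, and resampled systematically every trial. The
resulting log-likelihood estimate drives a pseudo-marginal Metropolis
sampler (particle MCMC) whose invariant distribution is the exact
parameter posterior despite the likelihood noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, psi
from scipy.stats import norm, truncnorm

from .inference import L_CLIP, ModelParams, block_evidence, leak_prior
from .task import Block

__all__ = [
    "PriorSpec",
    "ParticleFilterResult",
    "PosteriorSamples",
    "DegenerateFilterError",
    "particle_filter",
    "pmcmc_sample",
    "marginal_likelihood",
    "bms",
    "BmsResult",
]

PARAM_NAMES = ("h", "sigma_inf", "sigma_sel", "p_lapse")


class DegenerateFilterError(RuntimeError):
    """All particle weights vanished on some trial."""


@dataclass(frozen=True)
class PriorSpec:
    """Truncated-normal priors per parameter: (mean, sd, low, high)."""

    h: tuple = (0.2, 0.1, 0.0, 1.0)
    sigma_inf: tuple = (0.5, 0.2, 0.0, 10.0)
    sigma_sel: tuple = (0.5, 0.2, 0.0, 10.0)
    p_lapse: tuple = (0.01, 0.05, 0.0, 1.0)

    def spec(self, name: str) -> tuple:
        return getattr(self, name)

    def _dist(self, name: str):
        m, s, lo, hi = self.spec(name)
        return truncnorm((lo - m) / s, (hi - m) / s, loc=m, scale=s)

    def logpdf(self, name: str, value: float) -> float:
        return float(self._dist(name).logpdf(value))

    def sample(self, name: str, rng: np.random.Generator) -> float:
        return float(self._dist(name).rvs(random_state=rng))

    def bounds(self, name: str) -> tuple[float, float]:
        _, _, lo, hi = self.spec(name)
        return lo, hi


@dataclass
class ParticleFilterResult:
    loglik_hat: float
    filtered_prior: np.ndarray  # E[F(L_{t-1}) | r_{1:t-1}] per trial
    filtered_posterior: np.ndarray  # E[L_t | r_{1:t}] per trial
    ess: np.ndarray


@dataclass
class PosteriorSamples:
    draws: dict[str, np.ndarray]
    acceptance_rate: float
    burn_in: int
    log_ml: float | None = None
    loglik_trace: np.ndarray | None = None

    def mean(self, name: str) -> float:
        return float(np.mean(self.draws[name]))

    def sd(self, name: str) -> float:
        return float(np.std(self.draws[name], ddof=1))


def _response_loglik(
    L: np.ndarray, r: int, prev_r: int, params: ModelParams
) -> np.ndarray:
    """log p(r_t | L_t) for an array of particle beliefs."""
    if params.sigma_sel > 0:
        p_r = norm.cdf(r * L / params.sigma_sel)
    else:
        p_r = np.where(L * r > 0, 1.0, np.where(L == 0.0, 0.5, 0.0))
    p = (1.0 - params.p_lapse) * p_r
    if params.p_lapse > 0 and r == prev_r:
        p = p + params.p_lapse
    with np.errstate(divide="ignore"):
        return np.log(p)


def _systematic_resample(
    weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = len(weights)
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def particle_filter(
    params: ModelParams,
    block: Block,
    responses: np.ndarray,
    n_particles: int = 1000,
    rng: np.random.Generator | None = None,
) -> ParticleFilterResult:
    """Unbiased log-likelihood estimate of a block's responses.

    With ``sigma_inf == 0`` the latent trajectory is deterministic, all
    particles coincide, and the estimate equals the closed-form product
    of per-trial response probabilities exactly.
    """
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    rng = np.random.default_rng() if rng is None else rng
    totals, per_stim = block_evidence(block)
    n_per_trial = np.array([len(li) for li in per_stim])
    T = block.n_trials

    L = np.zeros(n_particles)
    loglik = 0.0
    prior_mean = np.empty(T)
    post_mean = np.empty(T)
    ess = np.empty(T)
    prev_r = block.initial_response
    for t in range(T):
        F = leak_prior(L, params.h)
        mean = F + totals[t]
        if params.sigma_inf > 0:
            L = mean + params.sigma_inf * np.sqrt(n_per_trial[t]) * rng.standard_normal(
                n_particles
            )
        else:
            L = mean
        L = np.clip(L, -L_CLIP, L_CLIP)
        logw = _response_loglik(L, int(responses[t]), prev_r, params)
        m = logw.max()
        if not np.isfinite(m):
            raise DegenerateFilterError(
                f"all particle weights are zero at trial {t} "
                f"(condition {block.condition}, pair {block.pair_id})"
            )
        w = np.exp(logw - m)
        wsum = w.sum()
        loglik += m + np.log(wsum / n_particles)
        wn = w / wsum
        ess[t] = 1.0 / np.sum(wn**2)
        prior_mean[t] = float(np.sum(wn * F))
        post_mean[t] = float(np.sum(wn * L))
        idx = _systematic_resample(wn, rng)
        L = L[idx]
        prev_r = int(responses[t])
    return ParticleFilterResult(
        loglik_hat=float(loglik),
        filtered_prior=prior_mean,
        filtered_posterior=post_mean,
        ess=ess,
    )


def dataset_loglik(
    params: ModelParams,
    blocks: list[Block],
    responses: list[np.ndarray],
    n_particles: int,
    rng: np.random.Generator,
) -> float:
    return float(
        sum(
            particle_filter(params, b, r, n_particles, rng).loglik_hat
            for b, r in zip(blocks, responses)
        )
    )


# ---------------------------------------------------------------------------
# parameter transforms (sampling space is unconstrained)
# ---------------------------------------------------------------------------


def _to_unconstrained(x: float, lo: float, hi: float) -> float:
    p = (x - lo) / (hi - lo)
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def _from_unconstrained(z: float, lo: float, hi: float) -> float:
    return float(lo + (hi - lo) / (1.0 + np.exp(-z)))


def _log_jacobian(z: float, lo: float, hi: float) -> float:
    # d x / d z for the scaled logistic transform
    s = 1.0 / (1.0 + np.exp(-z))
    return float(np.log(hi - lo) + np.log(s) + np.log1p(-s))


def pmcmc_sample(
    blocks: list[Block],
    responses: list[np.ndarray],
    prior: PriorSpec | None = None,
    n_iter: int = 2000,
    n_particles: int = 1000,
    rng: np.random.Generator | None = None,
    free_params: tuple[str, ...] = ("h", "sigma_inf"),
    burn_in_frac: float = 0.2,
    init: ModelParams | None = None,
    n_init_tries: int = 50,
) -> PosteriorSamples:
    """Pseudo-marginal Metropolis sampling of the parameter posterior.

    ``free_params`` selects the model variant: parameters not listed are
    fixed at zero (except ``h`` which is always free), implementing the
    reduced models used for model selection with one sampler. The
    random-walk proposal lives on logit-transformed parameters; its
    covariance is adapted during burn-in only and frozen afterwards, with
    a small fixed-scale mixture component to keep the chain mobile.
    """
    prior = PriorSpec() if prior is None else prior
    rng = np.random.default_rng() if rng is None else rng
    if "h" not in free_params:
        raise ValueError("the hazard rate is always a free parameter")
    d = len(free_params)
    burn_in = int(round(burn_in_frac * n_iter))

    def make_params(z: np.ndarray) -> ModelParams:
        vals = {name: 0.0 for name in PARAM_NAMES}
        for name, zi in zip(free_params, z):
            vals[name] = _from_unconstrained(zi, *prior.bounds(name))
        if vals["h"] <= 0.0 or vals["h"] >= 1.0:
            vals["h"] = min(max(vals["h"], 1e-9), 1 - 1e-9)
        return ModelParams(**vals)

    def log_prior_and_jac(z: np.ndarray) -> float:
        tot = 0.0
        for name, zi in zip(free_params, z):
            lo, hi = prior.bounds(name)
            x = _from_unconstrained(zi, lo, hi)
            tot += prior.logpdf(name, x) + _log_jacobian(zi, lo, hi)
        return tot

    # initialization: draw from the prior until the likelihood is finite
    empty = len(blocks) == 0
    z = None
    for attempt in range(n_init_tries):
        if init is not None and attempt == 0:
            cand = [getattr(init, name) for name in free_params]
        else:
            cand = [prior.sample(name, rng) for name in free_params]
        zc = np.array(
            [_to_unconstrained(x, *prior.bounds(n)) for x, n in zip(cand, free_params)]
        )
        try:
            ll = (
                0.0
                if empty
                else dataset_loglik(make_params(zc), blocks, responses, n_particles, rng)
            )
        except DegenerateFilterError:
            ll = -np.inf
        lp = log_prior_and_jac(zc)
        if np.isfinite(ll + lp):
            z, cur_ll, cur_lp = zc, ll, lp
            break
    if z is None:
        raise RuntimeError(
            "could not initialize the chain at a finite posterior density; "
            "re-seed or increase n_particles"
        )

    cov = np.eye(d) * 0.01
    scale = 2.38**2 / d
    eps = 1e-6 * np.eye(d)
    zs = np.empty((n_iter, d))
    lls = np.empty(n_iter)
    accepts = 0
    mean_z = z.copy()
    cov_z = np.eye(d) * 0.01

    for it in range(n_iter):
        if rng.random() < 0.05:
            prop = z + 0.01 * rng.standard_normal(d)
        else:
            prop = rng.multivariate_normal(z, scale * cov + eps)
        lp_prop = log_prior_and_jac(prop)
        if np.isfinite(lp_prop):
            try:
                ll_prop = (
                    0.0
                    if empty
                    else dataset_loglik(
                        make_params(prop), blocks, responses, n_particles, rng
                    )
                )
            except DegenerateFilterError:
                ll_prop = -np.inf
            log_alpha = (ll_prop + lp_prop) - (cur_ll + cur_lp)
            if np.log(rng.random()) < log_alpha:
                z, cur_ll, cur_lp = prop, ll_prop, lp_prop
                accepts += 1
        zs[it] = z
        lls[it] = cur_ll
        # adapt proposal covariance during burn-in only
        if it < burn_in:
            w = 1.0 / (it + 2)
            delta = z - mean_z
            mean_z = mean_z + w * delta
            cov_z = (1 - w) * (cov_z + w * np.outer(delta, delta))
            cov = cov_z

    draws = {}
    for j, name in enumerate(free_params):
        lo, hi = prior.bounds(name)
        draws[name] = np.array(
            [_from_unconstrained(zi, lo, hi) for zi in zs[burn_in:, j]]
        )
    return PosteriorSamples(
        draws=draws,
        acceptance_rate=accepts / n_iter,
        burn_in=burn_in,
        loglik_trace=lls[burn_in:],
    )


def marginal_likelihood(
    blocks: list[Block],
    responses: list[np.ndarray],
    prior: PriorSpec | None = None,
    n_samples: int = 200,
    n_particles: int = 1000,
    rng: np.random.Generator | None = None,
    free_params: tuple[str, ...] = ("h", "sigma_inf"),
) -> float:
    """Log marginal likelihood by prior importance sampling.

    Draws parameters from the prior and averages the particle-filter
    likelihood estimates; unbiased on the likelihood scale because the
    filter estimate is itself unbiased.
    """
    prior = PriorSpec() if prior is None else prior
    rng = np.random.default_rng() if rng is None else rng
    lls = np.full(n_samples, -np.inf)
    for i in range(n_samples):
        vals = {name: 0.0 for name in PARAM_NAMES}
        for name in free_params:
            vals[name] = prior.sample(name, rng)
        vals["h"] = min(max(vals["h"], 1e-9), 1 - 1e-9)
        try:
            lls[i] = dataset_loglik(
                ModelParams(**vals), blocks, responses, n_particles, rng
            )
        except DegenerateFilterError:
            pass
    return float(logsumexp(lls) - np.log(n_samples))


# ---------------------------------------------------------------------------
# Bayesian model selection
# ---------------------------------------------------------------------------


@dataclass
class BmsResult:
    fixed_effects: np.ndarray  # summed log-ML per model
    alpha: np.ndarray  # Dirichlet parameters of the random-effects posterior
    expected_freq: np.ndarray
    exceedance: np.ndarray
    warning: str | None = None


def bms(
    log_ml: np.ndarray,
    alpha0: float = 1.0,
    n_exceedance_samples: int = 100_000,
    rng: np.random.Generator | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> BmsResult:
    """Fixed- and random-effects model selection from a log-evidence table.

    ``log_ml`` has shape (participants, models). The random-effects step
    is the variational Dirichlet update over model frequencies; exceedance
    probabilities are estimated by sampling the fitted Dirichlet.
    """
    rng = np.random.default_rng() if rng is None else rng
    log_ml = np.asarray(log_ml, dtype=float)
    if log_ml.ndim != 2:
        raise ValueError("log_ml must be participants x models")
    if not np.all(np.isfinite(log_ml)):
        raise ValueError("log marginal likelihoods must be finite")
    n_subj, n_models = log_ml.shape
    fixed = log_ml.sum(axis=0)
    warning = None
    if n_models == 1:
        return BmsResult(
            fixed_effects=fixed,
            alpha=np.array([alpha0 + n_subj]),
            expected_freq=np.array([1.0]),
            exceedance=np.array([1.0]),
            warning="single model: model selection is degenerate",
        )

    alpha = np.full(n_models, alpha0)
    for _ in range(max_iter):
        log_u = log_ml + (psi(alpha) - psi(alpha.sum()))
        log_u = log_u - logsumexp(log_u, axis=1, keepdims=True)
        beta = np.exp(log_u).sum(axis=0)
        alpha_new = alpha0 + beta
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    samples = rng.dirichlet(alpha, size=n_exceedance_samples)
    winners = np.argmax(samples, axis=1)
    exceedance = np.bincount(winners, minlength=n_models) / n_exceedance_samples
    return BmsResult(
        fixed_effects=fixed,
        alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        exceedance=exceedance,
        warning=warning,
    )
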