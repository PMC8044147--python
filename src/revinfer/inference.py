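"""Bayes-optimal and noisy Bayesian belief updating on the task.

Beliefs are log-odds L_t = log p(s_t = +1 | evidence) / p(s_t = -1 | ...).
Between trials a fraction of the posterior is carried over through the
hazard-rate leak

    F(L) = L + log((1-h)/h + exp(-L)) - log((1-h)/h + exp(+L)),

the exact Bayesian update for a binary state with per-trial reversal
probability h. Within a trial the sequence contributes log-odds evidence
``sign(s) * sum_i 2*kappa*cos(2*delta_i)``; noisy inference corrupts each
per-stimulus update with i.i.d. Gaussian noise of SD sigma_inf, so the
trial-level posterior is L_t ~ N(F(L_{t-1}) + evidence, n*sigma_inf^2).
Responses are the sign of a decision variable N(L_t, sigma_sel^2), except
on lapse trials (probability p_lapse) where the previous response is
blindly repeated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import STATE_A, STATE_B, Block, per_stimulus_evidence

__all__ = [
    "ModelParams",
    "BeliefTrajectory",
    "leak_prior",
    "sequence_evidence",
    "block_evidence",
    "simulate_responses",
    "accuracy",
    "OPTIMAL_PARAMS",
]

#: clip beliefs to this magnitude before exponentials; unreachable at
#: behavioral scales (evidence per trial is at most 8 log-odds units).
L_CLIP = 50.0


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the noisy Bayesian observer.

    h          perceived hazard rate, in (0, 1)
    sigma_inf  SD of inference noise per stimulus update (log-odds units)
    sigma_sel  SD of selection noise on the decision variable
    p_lapse    probability of blindly repeating the previous response
    """

    h: float = 0.125
    sigma_inf: float = 0.0
    sigma_sel: float = 0.0
    p_lapse: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.h < 1.0:
            raise ValueError("h must lie in (0, 1)")
        if self.sigma_inf < 0 or self.sigma_sel < 0:
            raise ValueError("noise SDs must be nonnegative")
        if not 0.0 <= self.p_lapse <= 1.0:
            raise ValueError("p_lapse must lie in [0, 1]")


#: the Bayes-optimal observer: true hazard rate, no noise, no lapses.
OPTIMAL_PARAMS = ModelParams(h=0.125, sigma_inf=0.0, sigma_sel=0.0, p_lapse=0.0)


@dataclass
class BeliefTrajectory:
    """Per-trial prior/posterior log-odds plus within-sequence beliefs.

    ``within[t][i]`` is the belief L_{t,i} *before* processing stimulus i
    of trial t (so ``within[t][0]`` is the trial prior). Under the
    response-level scheme all within-sequence entries equal the trial
    prior (beliefs only consolidate at response time).
    """

    prior: np.ndarray
    posterior: np.ndarray
    within: list[np.ndarray] = field(default_factory=list)
    scheme: str = "stimulus_level"


def leak_prior(L, h: float):
    """Prior log-odds carried to the next trial under hazard rate h.

    Odd in L, shrinks |L| toward 0, and preserves the sign of L whenever
    h < 1/2; at h = 1/2 it collapses to 0 (total forgetting).
    """
    if not 0.0 < h < 1.0:
        raise ValueError("h must lie in (0, 1)")
    L = np.clip(L, -L_CLIP, L_CLIP)
    rho = (1.0 - h) / h
    return L + np.log(rho + np.exp(-L)) - np.log(rho + np.exp(L))


def sequence_evidence(
    tilts: np.ndarray, state: int, kappa: float
) -> tuple[float, np.ndarray]:
    """Signed sequence evidence and per-stimulus terms for one trial.

    The per-stimulus evidence toward the drawing category is
    ``2*kappa*cos(2*delta_i)``; the sign maps it onto the +1/-1 state
    convention (state +1 draws from category A in Cb, or from the
    previous response's deck in Ob - either way the tilt-space expression
    is the same).
    """
    tilts = np.asarray(tilts)
    if tilts.size == 0:
        raise ValueError("empty stimulus sequence")
    sign = 1.0 if state == STATE_A else -1.0
    li = sign * per_stimulus_evidence(tilts, kappa)
    return float(li.sum()), li


def block_evidence(block: Block) -> tuple[np.ndarray, list[np.ndarray]]:
    """Signed evidence per trial (toward state +1) for a whole block."""
    kappa = block.config.kappa
    totals = np.empty(block.n_trials)
    per_stim = []
    for t, trial in enumerate(block.trials):
        tot, li = sequence_evidence(trial.sequence.tilts, trial.state, kappa)
        totals[t] = tot
        per_stim.append(li)
    return totals, per_stim


def _select_response(
    L: float, prev: int, params: ModelParams, rng: np.random.Generator
) -> int:
    if params.p_lapse > 0 and rng.random() < params.p_lapse:
        return prev
    dv = L if params.sigma_sel == 0 else L + params.sigma_sel * rng.standard_normal()
    if dv == 0.0:
        return int(rng.choice([STATE_A, STATE_B]))  # fair coin on exact ties
    return STATE_A if dv > 0 else STATE_B


def simulate_responses(
    params: ModelParams,
    block: Block,
    rng: np.random.Generator,
    scheme: str = "stimulus_level",
) -> tuple[np.ndarray, BeliefTrajectory]:
    """Simulate the noisy Bayesian observer on one block.

    Under ``stimulus_level`` each per-stimulus update adds independent
    N(0, sigma_inf^2) noise; the trial posterior then has the marginal
    N(F(L_{t-1}) + evidence, n*sigma_inf^2) of the trial-level scheme, so
    the two schemes produce identical response statistics. Responses are
    written back onto the block's trials and the orientations are NOT
    realized here (see :func:`revinfer.task.realize_orientations`).

    Lapses freeze the response only; the belief still updates.
    """
    if scheme not in ("stimulus_level", "response_level"):
        raise ValueError(f"unknown scheme {scheme!r}")
    totals, per_stim = block_evidence(block)
    n_trials = block.n_trials
    prior = np.empty(n_trials)
    posterior = np.empty(n_trials)
    within: list[np.ndarray] = []
    responses = np.empty(n_trials, dtype=int)

    L = 0.0
    prev = block.initial_response
    for t in range(n_trials):
        F = float(leak_prior(L, params.h)) if t > 0 else 0.0
        prior[t] = F
        li = per_stim[t]
        n = len(li)
        if scheme == "stimulus_level":
            w = np.empty(n)
            cur = F
            for i in range(n):
                w[i] = cur
                cur = cur + li[i]
                if params.sigma_inf > 0:
                    cur += params.sigma_inf * rng.standard_normal()
            L = cur
        else:
            w = np.full(n, F)
            L = F + totals[t]
            if params.sigma_inf > 0:
                L += params.sigma_inf * np.sqrt(n) * rng.standard_normal()
        L = float(np.clip(L, -L_CLIP, L_CLIP))
        posterior[t] = L
        within.append(w)
        r = _select_response(L, prev, params, rng)
        responses[t] = r
        block.trials[t].response = r
        prev = r

    traj = BeliefTrajectory(prior=prior, posterior=posterior, within=within, scheme=scheme)
    return responses, traj


def accuracy(responses: np.ndarray, states: np.ndarray) -> float:
    """Fraction of trials on which the response matches the hidden state."""
    responses = np.asarray(responses)
    states = np.asarray(states)
    if responses.shape != states.shape:
        raise ValueError("responses and states differ in length")
    return float(np.mean(responses == states))
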