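"""Psychometric curve fits for reversal-learning behavior.

Two trial-level Bernoulli models are fitted by maximum likelihood:

* the reversal curve - probability of reporting the current hidden state
  as a saturating exponential of the trial's position in its episode,
  p(correct at k) = p0 + (p_rev - p0) * (1 - exp(-k / t_rev)), where p0
  is 0.5 for a block's first episode and, for later episodes, one minus
  the curve value reached on the last trial of the previous episode
  (the state flipped, so yesterday's asymptote is today's starting
  error rate);
* the repetition curve - probability of repeating the previous response
  as a sigmoid of the sequence evidence signed in favor of that
  response, p(repeat) = p_rep + (1 - p_rep) * sigmoid(beta * L - b_rep).

The repetition criterion b_rep is reported as the point of subjective
equivalence (PSE): the amount of evidence *against* the previous
response at which repeating and switching are equally likely. Larger
PSE means more conflicting evidence is needed before switching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .inference import block_evidence
from .task import Block

__all__ = [
    "ReversalFit",
    "RepetitionFit",
    "repetition_evidence",
    "reversal_dataset",
    "repetition_dataset",
    "fit_reversal_curve",
    "fit_repetition_curve",
    "reversal_curve",
    "repetition_curve",
    "pse_from_params",
]

_EPS = 1e-9

T_REV_BOUNDS = (1e-2, 1e2)
P_REV_BOUNDS = (0.5, 1.0)
BETA_BOUNDS = (0.0, 20.0)
P_REP_BOUNDS = (0.0, 0.5)
B_REP_BOUNDS = (-20.0, 20.0)


@dataclass
class ReversalFit:
    t_rev: float
    p_rev: float
    loglik: float
    n_trials: int


@dataclass
class RepetitionFit:
    beta: float
    beta_rep: float
    p_rep: float
    pse: float
    loglik: float
    n_trials: int
    separation: bool = False


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


def repetition_evidence(block: Block, responses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial evidence in favor of the previous response, and repeats.

    Trial 0 of a block is excluded (its reference is the pre-block guess,
    which carries no evidence history); with the block's initial guess as
    r_{-1} it could be included, and the first entry uses that guess.
    Returns ``(L_rep, repeated)`` for trials 1..T-1.
    """
    ev, _ = block_evidence(block)  # signed toward state +1
    responses = np.asarray(responses)
    prev = responses[:-1]
    L_rep = prev * ev[1:]
    repeated = (responses[1:] == prev).astype(float)
    return L_rep, repeated


def reversal_dataset(
    blocks: list[Block], responses_list: list[np.ndarray]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-block (episode position k, correct) sequences in trial order."""
    out = []
    for block, responses in zip(blocks, responses_list):
        st = block.states
        ep = block.episode_ids
        correct = (np.asarray(responses) == st).astype(float)
        k = np.empty(block.n_trials, dtype=int)
        c = 0
        for t in range(block.n_trials):
            if t > 0 and ep[t] != ep[t - 1]:
                c = 0
            c += 1
            k[t] = c
        out.append((k, correct))
    return out


def repetition_dataset(
    blocks: list[Block], responses_list: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    Ls, reps = [], []
    for block, responses in zip(blocks, responses_list):
        L_rep, repeated = repetition_evidence(block, responses)
        Ls.append(L_rep)
        reps.append(repeated)
    return np.concatenate(Ls), np.concatenate(reps)


# ---------------------------------------------------------------------------
# reversal curve
# ---------------------------------------------------------------------------


def reversal_curve(k: np.ndarray, t_rev: float, p_rev: float, p0: float) -> np.ndarray:
    return p0 + (p_rev - p0) * (1.0 - np.exp(-np.asarray(k, dtype=float) / t_rev))


def _reversal_nll(params, datasets):
    t_rev, p_rev = params
    nll = 0.0
    for k, correct in datasets:
        p0 = 0.5  # first episode of the block
        # episodes are contiguous runs where k resets to 1
        start = 0
        T = len(k)
        for t in range(T + 1):
            if t == T or (t > 0 and k[t] == 1):
                kk = k[start:t]
                cc = correct[start:t]
                p = np.clip(reversal_curve(kk, t_rev, p_rev, p0), _EPS, 1 - _EPS)
                nll -= np.sum(cc * np.log(p) + (1 - cc) * np.log(1 - p))
                p0 = 1.0 - p[-1]  # state flips at the episode boundary
                start = t
    return nll


def fit_reversal_curve(
    datasets: list[tuple[np.ndarray, np.ndarray]],
    n_starts: int = 5,
) -> ReversalFit:
    """MLE of (t_rev, p_rev) from per-block (position, correct) data."""
    n_episodes = sum(int(np.sum(k == 1)) for k, _ in datasets)
    if n_episodes < 2:
        raise ValueError("no reversals in the data: reversal curve undefined")
    n_trials = sum(len(k) for k, _ in datasets)
    starts = [
        (1.0, 0.9),
        (0.3, 0.8),
        (3.0, 0.95),
        (0.05, 0.99),
        (10.0, 0.7),
    ][:n_starts]
    best = None
    for x0 in starts:
        res = minimize(
            _reversal_nll,
            x0,
            args=(datasets,),
            method="L-BFGS-B",
            bounds=[T_REV_BOUNDS, P_REV_BOUNDS],
        )
        if best is None or res.fun < best.fun:
            best = res
    return ReversalFit(
        t_rev=float(best.x[0]),
        p_rev=float(best.x[1]),
        loglik=-float(best.fun),
        n_trials=n_trials,
    )


# ---------------------------------------------------------------------------
# repetition curve
# ---------------------------------------------------------------------------


def repetition_curve(L, beta: float, beta_rep: float, p_rep: float):
    return p_rep + (1.0 - p_rep) / (1.0 + np.exp(-beta * np.asarray(L) + beta_rep))


def pse_from_params(beta: float, beta_rep: float, p_rep: float) -> float:
    """Evidence against the previous response at which p(repeat) = 0.5.

    Inverts the sigmoid at 0.5 and negates: the crossing sits at negative
    signed evidence whenever repetitions are favored at neutral evidence,
    and the PSE is reported as the (positive) magnitude of conflicting
    evidence required.
    """
    if p_rep >= 0.5:
        return np.nan
    target = (0.5 - p_rep) / (1.0 - p_rep)
    crossing = (beta_rep + np.log(target / (1.0 - target))) / beta
    return float(-crossing)


def _repetition_nll(params, L, repeated):
    beta, beta_rep, p_rep = params
    p = np.clip(repetition_curve(L, beta, beta_rep, p_rep), _EPS, 1 - _EPS)
    return -np.sum(repeated * np.log(p) + (1 - repeated) * np.log(1 - p))


def fit_repetition_curve(
    L_rep: np.ndarray,
    repeated: np.ndarray,
    n_starts: int = 5,
) -> RepetitionFit:
    """MLE of (beta, beta_rep, p_rep); PSE derived from the fit."""
    L_rep = np.asarray(L_rep, dtype=float)
    repeated = np.asarray(repeated, dtype=float)
    separation = bool(np.all(repeated == 1.0) or np.all(repeated == 0.0))
    starts = [
        (2.0, -1.0, 0.03),
        (1.0, 0.0, 0.01),
        (5.0, -2.0, 0.1),
        (0.5, -0.5, 0.0),
        (3.0, -3.0, 0.05),
    ][:n_starts]
    best = None
    for x0 in starts:
        res = minimize(
            _repetition_nll,
            x0,
            args=(L_rep, repeated),
            method="L-BFGS-B",
            bounds=[BETA_BOUNDS, B_REP_BOUNDS, P_REP_BOUNDS],
        )
        if best is None or res.fun < best.fun:
            best = res
    beta, beta_rep, p_rep = best.x
    return RepetitionFit(
        beta=float(beta),
        beta_rep=float(beta_rep),
        p_rep=float(p_rep),
        pse=pse_from_params(beta, beta_rep, p_rep),
        loglik=-float(best.fun),
        n_trials=len(L_rep),
        separation=separation,
    )
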