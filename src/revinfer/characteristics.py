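"""Per-stimulus characteristics and neural-hazard-rate estimation.

Each stimulus in a sequence is described by four characteristics used as
decoding targets for neural (or simulated-neural) activity:

1. orientation, encoded as the pair (cos 2*theta, sin 2*theta);
2. change: circular distance from the preceding stimulus, |theta_i -
   theta_{i-1}| on the pi-periodic orientation circle (range [0, pi/2]);
3. evidence strength: tilt from the nearest category boundary (the
   boundaries sit +-pi/4 from the category means, so the range is
   [0, pi/4]);
4. consistency: evidence strength signed by whether the stimulus's
   evidence agrees with the current belief L_{t,i} - the "relational"
   code that flips sign when the belief flips mid-sequence.

The trial-wise randomization of the category axis decorrelates the four
characteristics from one another and across successive stimuli.

The neural hazard rate h* of a feature set is the hazard for which the
consistency variable (recomputed under that hazard) is best decoded; the
tuning curve of decoding precision over a hazard grid is smoothed by a
quadratic fit in log-hazard and its vertex reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coding import encode_cv
from .inference import BeliefTrajectory, ModelParams, leak_prior
from .task import Block, per_stimulus_evidence

__all__ = [
    "StimulusCharacteristics",
    "HazardTuningCurve",
    "compute_characteristics",
    "noise_free_beliefs",
    "consistency_under_hazard",
    "hazard_tuning",
    "default_hazard_grid",
]


@dataclass
class StimulusCharacteristics:
    """Flat per-stimulus table for one block (arrays share length)."""

    trial: np.ndarray
    stim_index: np.ndarray
    orientation_cos: np.ndarray
    orientation_sin: np.ndarray
    change: np.ndarray  # NaN for the first stimulus of a block
    evidence_strength: np.ndarray
    consistency: np.ndarray

    def as_matrix(self) -> np.ndarray:
        return np.column_stack(
            [
                self.orientation_cos,
                self.orientation_sin,
                self.change,
                self.evidence_strength,
                self.consistency,
            ]
        )


@dataclass
class HazardTuningCurve:
    grid: np.ndarray
    precision: np.ndarray  # raw Fisher-z decoding precision per hazard
    relative: np.ndarray  # fraction of the per-curve maximum
    h_star: float
    quad_coeffs: np.ndarray
    fallback: bool = False  # True when the quadratic had no interior max


def _circ_dist_pi(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance between orientations on the pi-periodic circle, in [0, pi/2]."""
    d = np.mod(a - b, np.pi)
    return np.minimum(d, np.pi - d)


def _boundary_tilt(theta: np.ndarray, mu_a: np.ndarray) -> np.ndarray:
    """Tilt from the nearest category boundary (boundaries every pi/2)."""
    phi = np.mod(theta - (mu_a + np.pi / 4.0), np.pi / 2.0)
    return np.minimum(phi, np.pi / 2.0 - phi)


def _stimulus_evidence_signed(block: Block, responses: np.ndarray) -> list[np.ndarray]:
    """Per-stimulus log-odds evidence toward state +1, from orientations.

    In Cb the reference mean for state +1 is the category-A mean; in Ob
    it follows the previous response (the block's initial guess before
    the first trial).
    """
    kappa = block.config.kappa
    out = []
    prev = block.initial_response
    for t, trial in enumerate(block.trials):
        theta = trial.sequence.orientations
        if theta is None:
            raise ValueError("orientations not realized; call realize_orientations")
        mu_a = trial.sequence.mu_a
        mu_b = (mu_a + np.pi / 2.0) % np.pi
        if block.condition == "Cb":
            ref = mu_a
        else:
            ref = mu_a if prev == 1 else mu_b
            prev = int(responses[t])
        out.append(2.0 * kappa * np.cos(2.0 * (theta - ref)))
    return out


def compute_characteristics(
    block: Block,
    responses: np.ndarray,
    beliefs: BeliefTrajectory,
    scheme: str = "stimulus_level",
) -> StimulusCharacteristics:
    """All four characteristics for every stimulus of a block.

    ``beliefs`` supplies L_{t,i}: under ``stimulus_level`` the belief
    after stimuli 1..i-1 of trial t (``beliefs.within``); under
    ``response_level`` the trial's prior, frozen across the sequence.
    When the belief is exactly zero the consistency sign defaults to the
    sign of the incoming evidence (neutral belief treated as consistent
    with what arrives).
    """
    ev_signed = _stimulus_evidence_signed(block, responses)
    trials, stim_idx = [], []
    ocos, osin, change, strength, consistency = [], [], [], [], []
    prev_theta = None
    for t, trial in enumerate(block.trials):
        theta = trial.sequence.orientations
        mu_a = np.full(len(theta), trial.sequence.mu_a)
        if scheme == "stimulus_level":
            Lti = beliefs.within[t]
        elif scheme == "response_level":
            Lti = np.full(len(theta), beliefs.prior[t])
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        s = _boundary_tilt(theta, mu_a)
        for i in range(len(theta)):
            trials.append(t)
            stim_idx.append(i)
            ocos.append(np.cos(2 * theta[i]))
            osin.append(np.sin(2 * theta[i]))
            change.append(
                np.nan if prev_theta is None else _circ_dist_pi(theta[i], prev_theta)
            )
            strength.append(s[i])
            li = ev_signed[t][i]
            L = Lti[i]
            # neutral belief counts as consistent with the incoming evidence
            sign = np.sign(li * L) if L != 0.0 else 1.0
            if sign == 0.0:
                sign = 1.0
            consistency.append(sign * s[i])
            prev_theta = theta[i]
    return StimulusCharacteristics(
        trial=np.array(trials),
        stim_index=np.array(stim_idx),
        orientation_cos=np.array(ocos),
        orientation_sin=np.array(osin),
        change=np.array(change),
        evidence_strength=np.array(strength),
        consistency=np.array(consistency),
    )


# ---------------------------------------------------------------------------
# belief recomputation under alternative hazards
# ---------------------------------------------------------------------------


def noise_free_beliefs(
    block: Block, h: float, scheme: str = "stimulus_level"
) -> BeliefTrajectory:
    """Deterministic belief trajectory under hazard ``h`` (no noise).

    The fast alternative to conditioning a particle filter on responses:
    with zero inference noise the trajectory is a deterministic function
    of the stimuli, which is exact for noise-free observers and a good
    approximation for moderately noisy ones.
    """
    from .inference import block_evidence

    totals, per_stim = block_evidence(block)
    T = block.n_trials
    prior = np.empty(T)
    posterior = np.empty(T)
    within = []
    L = 0.0
    for t in range(T):
        F = float(leak_prior(L, h))
        prior[t] = F
        li = per_stim[t]
        w = F + np.concatenate([[0.0], np.cumsum(li[:-1])])
        within.append(w)
        L = F + totals[t]
        posterior[t] = L
    return BeliefTrajectory(prior=prior, posterior=posterior, within=within, scheme=scheme)


def consistency_under_hazard(
    block: Block,
    responses: np.ndarray,
    h: float,
    scheme: str = "stimulus_level",
) -> np.ndarray:
    beliefs = noise_free_beliefs(block, h, scheme)
    chars = compute_characteristics(block, responses, beliefs, scheme)
    return chars.consistency


def default_hazard_grid(n: int = 13) -> np.ndarray:
    """Log-spaced candidate hazards spanning 1/32 to 1/2."""
    return np.exp(np.linspace(np.log(1 / 32), np.log(1 / 2), n))


def hazard_tuning(
    features: np.ndarray,
    blocks: list[Block],
    responses_list: list[np.ndarray],
    hazard_grid: np.ndarray | None = None,
    scheme: str = "stimulus_level",
    n_folds: int = 12,
    peak_window: int = 3,
) -> HazardTuningCurve:
    """Tuning curve of consistency decodability over candidate hazards.

    ``features`` is (units x stimuli) activity whose consistency channel
    was generated at some unknown true hazard. For each candidate h the
    consistency variable is recomputed from the behavioral record and
    decoded; the reported h* is the vertex of a quadratic fit to
    precision vs log-hazard, clipped to the grid hull (falling back to
    the grid argmax with a warning if the quadratic is concave-up).
    """
    grid = default_hazard_grid() if hazard_grid is None else np.asarray(hazard_grid)
    precision = np.empty(len(grid))
    for j, h in enumerate(grid):
        x = np.concatenate(
            [
                consistency_under_hazard(b, r, h, scheme)
                for b, r in zip(blocks, responses_list)
            ]
        )
        precision[j] = encode_cv(features, x, n_folds=n_folds).precision
    rel = precision / precision.max()
    logh = np.log(grid)
    # quadratic smoothing local to the peak: the tuning curve is strongly
    # asymmetric in log-hazard, so a global parabola biases the vertex
    j_max = int(np.argmax(precision))
    half = max(2, peak_window)
    lo_i, hi_i = max(0, j_max - half), min(len(grid), j_max + half + 1)
    coeffs = np.polyfit(logh[lo_i:hi_i], precision[lo_i:hi_i], 2)
    fallback = False
    if coeffs[0] >= 0:
        warnings.warn(
            "hazard tuning curve has no interior quadratic maximum; "
            "using the grid argmax",
            RuntimeWarning,
            stacklevel=2,
        )
        h_star = float(grid[np.argmax(precision)])
        fallback = True
    else:
        vertex = -coeffs[1] / (2 * coeffs[0])
        vertex = float(np.clip(vertex, logh[0], logh[-1]))
        h_star = float(np.exp(vertex))
    return HazardTuningCurve(
        grid=grid,
        precision=precision,
        relative=rel,
        h_star=h_star,
        quad_coeffs=coeffs,
        fallback=fallback,
    )
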