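"""Generative task model for the two-condition reversal-learning design.

A session is built from blocks of trials. On each trial a sequence of 2-8
oriented stimuli is drawn from one of two von Mises categories (A and B)
whose means are orthogonal on the pi-periodic orientation circle. A binary
hidden state flips occasionally (episodes of 4-24 trials drawn from a
truncated exponential), and the observer reports the state after each
sequence.

The two conditions share one generative core:

* cue-based (Cb): the drawn category is a fixed function of the hidden
  state; the observer monitors which category is being sampled.
* outcome-based (Ob): the drawn category depends on both the hidden state
  and the observer's previous response; the observer searches for the
  response that samples from a target category.

To make the evidence streams of a Cb block and an Ob block identical for
*any* response history, sequences are pre-generated as tilts ``delta_i``
from the (trial-specific) drawing mean rather than as raw orientations.
The per-stimulus log-odds evidence is then ``2*kappa*cos(2*delta_i)``
regardless of which mean was realized, so a matched pair of blocks built
from the same tilts yields the same belief trajectory in both conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TaskConfig",
    "StimulusSequence",
    "Trial",
    "Block",
    "sample_episode_lengths",
    "truncated_exp_rate",
    "generate_tilts",
    "realize_block_pair",
    "generate_block_pair",
    "realize_orientations",
    "per_stimulus_evidence",
]

#: responses / hidden states are coded as +1 ("left" key, state 1, category A)
#: and -1 ("right" key, state 2, category B).
STATE_A = 1
STATE_B = -1


@dataclass
class TaskConfig:
    """Design parameters of the reversal-learning task."""

    trials_per_block: int = 72
    sequence_lengths: tuple[int, ...] = (2, 4, 6, 8)
    kappa: float = 0.5
    episode_min: int = 4
    episode_max: int = 24
    n_episodes_stable: int = 6
    n_episodes_volatile: int = 12
    hazard_true: float = 0.125
    #: practice blocks used a higher concentration; exposed but unused here
    kappa_practice: float = 1.5
    seed: int | None = None

    def n_episodes(self, volatility: str) -> int:
        if volatility == "stable":
            return self.n_episodes_stable
        if volatility == "volatile":
            return self.n_episodes_volatile
        raise ValueError(f"unknown volatility {volatility!r}")


@dataclass
class StimulusSequence:
    """One trial's stimuli, stored both as tilts and (once realized) angles.

    ``tilts`` are offsets from the trial's realized drawing mean, in
    (-pi/2, pi/2]; ``orientations`` live on [0, pi). ``mu_a`` is the
    trial-specific category-A mean; category B sits at ``mu_a + pi/2``.
    """

    tilts: np.ndarray
    mu_a: float
    orientations: np.ndarray | None = None
    mu_drawn: float | None = None

    @property
    def n(self) -> int:
        return len(self.tilts)


@dataclass
class Trial:
    index: int
    episode_id: int
    state: int  # +1 or -1
    sequence: StimulusSequence
    category: int | None = None  # +1 (A) or -1 (B), realized
    response: int | None = None


@dataclass
class Block:
    trials: list[Trial]
    condition: str  # "Cb" or "Ob"
    volatility: str  # "stable" or "volatile"
    initial_response: int
    pair_id: int = 0
    config: TaskConfig = field(default_factory=TaskConfig)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def states(self) -> np.ndarray:
        return np.array([t.state for t in self.trials])

    @property
    def episode_ids(self) -> np.ndarray:
        return np.array([t.episode_id for t in self.trials])

    def tilt_list(self) -> list[np.ndarray]:
        return [t.sequence.tilts for t in self.trials]


# ---------------------------------------------------------------------------
# episode structure
# ---------------------------------------------------------------------------


def truncated_exp_rate(target_mean: float, lo: int, hi: int) -> float:
    """Rate of the discrete truncated exponential on {lo..hi} with given mean.

    Episode lengths are integers k in [lo, hi] with p(k) proportional to
    exp(-rate*k). The rate is chosen so the truncated mean equals the
    nominal mean episode length (block length / episode count), which makes
    the realized hazard match the nominal hazard. A negative rate (growing
    weights) is allowed for target means above the uniform mean.
    """
    ks = np.arange(lo, hi + 1, dtype=float)
    if not (lo < target_mean < hi):
        raise ValueError("target mean outside the open support interval")

    def mean_at(rate: float) -> float:
        w = np.exp(-rate * (ks - lo))  # shift for numerical stability
        return float(np.sum(ks * w) / np.sum(w))

    if np.isclose(mean_at(0.0), target_mean):
        return 0.0
    return brentq(lambda r: mean_at(r) - target_mean, -5.0, 5.0)


def sample_episode_lengths(
    n_episodes: int,
    total: int,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    max_attempts: int = 200_000,
) -> np.ndarray:
    """Draw episode lengths summing exactly to ``total``.

    Lengths are i.i.d. draws from the discrete truncated exponential whose
    mean equals ``total / n_episodes``, rejected until they sum to
    ``total``. Rejection leaves the marginal distribution of each length
    (conditioned on the sum) as close to the stated marginal as the sum
    constraint allows.
    """
    if not n_episodes * lo <= total <= n_episodes * hi:
        raise ValueError(
            f"cannot split {total} trials into {n_episodes} episodes of "
            f"{lo}-{hi} trials"
        )
    if n_episodes == 1:
        return np.array([total])
    ks = np.arange(lo, hi + 1)
    rate = truncated_exp_rate(total / n_episodes, lo, hi)
    w = np.exp(-rate * (ks - lo).astype(float))
    p = w / w.sum()
    for _ in range(max_attempts):
        lengths = rng.choice(ks, size=n_episodes, p=p)
        if lengths.sum() == total:
            return lengths
    raise RuntimeError(
        f"episode-length rejection sampler failed after {max_attempts} attempts"
    )


def episode_states(
    lengths: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Expand episode lengths into per-trial hidden states and episode ids."""
    first = rng.choice([STATE_A, STATE_B])
    states = np.concatenate(
        [np.full(int(n), first * (-1) ** i) for i, n in enumerate(lengths)]
    )
    ids = np.concatenate(
        [np.full(int(n), i) for i, n in enumerate(lengths)]
    )
    return states.astype(int), ids.astype(int)


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------


def generate_tilts(
    seq_lengths: list[int] | np.ndarray,
    kappa: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Sample per-trial tilt arrays from the category distribution.

    Orientations are pi-periodic, so the von Mises density is defined on
    the doubled angle: 2*delta ~ vonMises(0, kappa). Tilts are stored in
    (-pi/2, pi/2].
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    out = []
    for n in seq_lengths:
        doubled = rng.vonmises(0.0, kappa, size=int(n))
        delta = doubled / 2.0
        out.append(delta)
    return out


def per_stimulus_evidence(tilts: np.ndarray, kappa: float) -> np.ndarray:
    """Log-odds evidence per stimulus toward the drawing category."""
    return 2.0 * kappa * np.cos(2.0 * np.asarray(tilts))


def evidence_from_orientations(
    orientations: np.ndarray, mu: float, kappa: float
) -> np.ndarray:
    """Per-stimulus log-odds evidence toward the category with mean ``mu``."""
    return 2.0 * kappa * np.cos(2.0 * (np.asarray(orientations) - mu))


# ---------------------------------------------------------------------------
# block realization
# ---------------------------------------------------------------------------


def _build_trials(
    tilts: list[np.ndarray],
    states: np.ndarray,
    episode_ids: np.ndarray,
    mu_a: np.ndarray,
) -> list[Trial]:
    return [
        Trial(
            index=t,
            episode_id=int(episode_ids[t]),
            state=int(states[t]),
            sequence=StimulusSequence(tilts=tilts[t].copy(), mu_a=float(mu_a[t])),
        )
        for t in range(len(tilts))
    ]


def realize_block_pair(
    tilts: list[np.ndarray],
    episode_lengths: np.ndarray,
    config: TaskConfig,
    volatility: str,
    rng: np.random.Generator,
    pair_id: int = 0,
) -> tuple[Block, Block]:
    """Build a matched (Cb, Ob) pair of blocks from shared tilts.

    Both blocks share the tilt stream, hidden-state trajectory, and
    trial-wise category-A means (drawn uniformly per trial). Cb
    orientations are realized immediately (the drawing mean is a fixed
    function of the state); Ob orientations are realized lazily via
    :func:`realize_orientations` once responses are known, because the
    drawing mean at trial t depends on the response at trial t-1.
    """
    states, episode_ids = episode_states(episode_lengths, rng)
    n_trials = len(states)
    if len(tilts) != n_trials:
        raise ValueError("tilt list and episode structure disagree in length")
    mu_a = rng.uniform(0.0, np.pi, size=n_trials)
    initial_response = int(rng.choice([STATE_A, STATE_B]))

    cb = Block(
        trials=_build_trials(tilts, states, episode_ids, mu_a),
        condition="Cb",
        volatility=volatility,
        initial_response=initial_response,
        pair_id=pair_id,
        config=config,
    )
    ob = Block(
        trials=_build_trials(tilts, states, episode_ids, mu_a),
        condition="Ob",
        volatility=volatility,
        initial_response=initial_response,
        pair_id=pair_id,
        config=config,
    )
    # Cb: category is a fixed function of the state; realize now.
    responses_dummy = np.zeros(n_trials, dtype=int)  # unused for Cb
    realize_orientations(cb, responses_dummy)
    return cb, ob


def generate_block_pair(
    config: TaskConfig,
    volatility: str,
    rng: np.random.Generator,
    pair_id: int = 0,
) -> tuple[Block, Block]:
    """Sample episode structure and tilts, then realize a matched pair."""
    n_ep = config.n_episodes(volatility)
    lengths = sample_episode_lengths(
        n_ep, config.trials_per_block, config.episode_min, config.episode_max, rng
    )
    seq_lengths = rng.choice(
        np.asarray(config.sequence_lengths), size=config.trials_per_block
    )
    tilts = generate_tilts(seq_lengths, config.kappa, rng)
    return realize_block_pair(tilts, lengths, config, volatility, rng, pair_id)


def drawing_mean(trial: Trial, condition: str, prev_response: int) -> float:
    """Mean of the category the trial's stimuli were drawn from.

    Cb: state +1 draws from category A, state -1 from category B.
    Ob: state +1 means "the previous response draws from the target", so
    the drawn category follows the previous response; state -1 means it
    draws from the other category.
    """
    mu_a = trial.sequence.mu_a
    mu_b = (mu_a + np.pi / 2.0) % np.pi
    if condition == "Cb":
        return mu_a if trial.state == STATE_A else mu_b
    if condition == "Ob":
        if trial.state == STATE_A:
            return mu_a if prev_response == STATE_A else mu_b
        return mu_b if prev_response == STATE_A else mu_a
    raise ValueError(f"unknown condition {condition!r}")


def realize_orientations(block: Block, responses: np.ndarray) -> None:
    """Materialize stimulus orientations given the response history.

    For Cb blocks the responses are ignored (the drawing category never
    depends on them). For Ob blocks, trial t uses the response at t-1
    (the block's initial guess for t=0).
    """
    prev = block.initial_response
    for t, trial in enumerate(block.trials):
        mu = drawing_mean(trial, block.condition, prev)
        theta = np.mod(trial.sequence.tilts + mu, np.pi)
        trial.sequence.orientations = theta
        trial.sequence.mu_drawn = float(mu)
        trial.category = STATE_A if np.isclose(mu, trial.sequence.mu_a) else STATE_B
        if block.condition == "Ob":
            prev = int(responses[t])
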