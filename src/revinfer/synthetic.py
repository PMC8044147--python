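"""Synthetic study datasets: behavioral cohorts and simulated neural features.

A cohort emulates the study's structure: each subject performs 8 blocks
of 72 trials — four matched cue-based/outcome-based pairs, two at the
stable hazard (6 episodes) and two at the volatile hazard (12 episodes)
— with responses drawn from the noisy Bayesian observer at
subject-specific parameters. Subject-level parameters are sampled from
truncated normals whose means match the fitted group means and whose
SDs are the printed SEMs scaled by sqrt(N); the inference-noise values
of the two conditions share a latent Gaussian factor so that their
cross-subject correlation matches the observed one.

Simulated neural features stand in for sensor recordings: disjoint
subpopulations of linear coding units, one per stimulus characteristic,
summed into a single feature array with i.i.d. Gaussian background
noise. They reproduce the statistical structure the decoding analyses
rely on (selective linear codes, condition overlap, known true hazard
for the consistency channel) and nothing else about real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .characteristics import compute_characteristics
from .inference import BeliefTrajectory, ModelParams, simulate_responses
from .task import Block, TaskConfig, generate_block_pair, realize_orientations

__all__ = [
    "CohortSpec",
    "SubjectData",
    "SyntheticMEGSpec",
    "sample_subject_params",
    "generate_subject",
    "generate_cohort",
    "generate_meg_features",
]

SQRT_N = np.sqrt(24.0)


@dataclass(frozen=True)
class CohortSpec:
    """Population-level distribution of observer parameters.

    Means are the fitted group means per condition; SDs convert the
    printed standard errors to between-subject SDs (SEM * sqrt(N)).
    """

    n_subjects: int = 24
    h_cb: tuple[float, float] = (0.191, 0.022 * SQRT_N)
    h_ob: tuple[float, float] = (0.115, 0.015 * SQRT_N)
    sigma_inf_cb: tuple[float, float] = (0.512, 0.024 * SQRT_N)
    sigma_inf_ob: tuple[float, float] = (0.550, 0.033 * SQRT_N)
    sigma_inf_corr: float = 0.63
    sigma_sel: float = 0.0
    p_lapse: float = 0.0
    n_pairs_stable: int = 2
    n_pairs_volatile: int = 2


@dataclass
class SubjectData:
    subject: int
    params: dict[str, ModelParams]  # per condition
    blocks: list[Block]
    responses: list[np.ndarray]
    beliefs: list[BeliefTrajectory]


def _trunc_sample(mean, sd, lo, hi, rng):
    return float(
        truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd).rvs(
            random_state=rng
        )
    )


def sample_subject_params(
    spec: CohortSpec, rng: np.random.Generator
) -> dict[str, ModelParams]:
    """One subject's (Cb, Ob) parameter pair.

    The inference-noise values are built from a shared standard-normal
    factor plus independent residuals mixed to the target correlation,
    then mapped through each condition's mean/SD (values clipped into
    the prior support).
    """
    rho = spec.sigma_inf_corr
    shared = rng.standard_normal()
    z_cb = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal()
    z_ob = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal()
    s_cb = np.clip(spec.sigma_inf_cb[0] + spec.sigma_inf_cb[1] * z_cb, 1e-3, 10.0)
    s_ob = np.clip(spec.sigma_inf_ob[0] + spec.sigma_inf_ob[1] * z_ob, 1e-3, 10.0)
    h_cb = _trunc_sample(*spec.h_cb, 1e-3, 1 - 1e-3, rng)
    h_ob = _trunc_sample(*spec.h_ob, 1e-3, 1 - 1e-3, rng)
    return {
        "Cb": ModelParams(h=h_cb, sigma_inf=float(s_cb),
                          sigma_sel=spec.sigma_sel, p_lapse=spec.p_lapse),
        "Ob": ModelParams(h=h_ob, sigma_inf=float(s_ob),
                          sigma_sel=spec.sigma_sel, p_lapse=spec.p_lapse),
    }


def generate_subject(
    subject: int,
    params: dict[str, ModelParams],
    config: TaskConfig,
    rng: np.random.Generator,
    spec: CohortSpec | None = None,
) -> SubjectData:
    spec = spec or CohortSpec()
    blocks: list[Block] = []
    responses: list[np.ndarray] = []
    beliefs: list[BeliefTrajectory] = []
    pair_id = 0
    vols = ["stable"] * spec.n_pairs_stable + ["volatile"] * spec.n_pairs_volatile
    for vol in vols:
        cb, ob = generate_block_pair(config, vol, rng, pair_id=pair_id)
        for block in (cb, ob):
            r, traj = simulate_responses(params[block.condition], block, rng)
            realize_orientations(block, r)
            blocks.append(block)
            responses.append(r)
            beliefs.append(traj)
        pair_id += 1
    return SubjectData(
        subject=subject, params=params, blocks=blocks,
        responses=responses, beliefs=beliefs,
    )


def generate_cohort(
    spec: CohortSpec,
    config: TaskConfig,
    rng: np.random.Generator,
    params_override: dict[str, ModelParams] | None = None,
) -> list[SubjectData]:
    """Full synthetic cohort; ``params_override`` forces every subject to
    the same parameters (zero between-subject variance)."""
    cohort = []
    for s in range(spec.n_subjects):
        params = params_override or sample_subject_params(spec, rng)
        cohort.append(generate_subject(s, params, config, rng, spec))
    return cohort


# ---------------------------------------------------------------------------
# simulated neural features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticMEGSpec:
    """Layout of the simulated feature array.

    Each named characteristic owns a disjoint pool of units within the
    total of ``n``; within its pool, each condition selects ``n_sel``
    units, overlapping in a fraction ``omega``. The consistency channel
    is computed from noise-free belief trajectories at ``h_true`` (one
    value per condition).
    """

    characteristics: tuple[str, ...] = ("evidence_strength", "consistency")
    n: int = 300
    n_sel: int = 100
    sigma: float = 2.0
    omega: float = 1.0
    h_true: dict = field(default_factory=lambda: {"Cb": 0.319, "Ob": 0.216})
    scheme: str = "stimulus_level"


_CHAR_COLUMNS = {
    "orientation_cos": 0,
    "orientation_sin": 1,
    "change": 2,
    "evidence_strength": 3,
    "consistency": 4,
}


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    valid = np.isfinite(x)
    out = np.zeros_like(x)
    mu, sd = x[valid].mean(), x[valid].std()
    out[valid] = (x[valid] - mu) / sd
    return out


def characteristic_table(
    subject: SubjectData, condition: str, spec: SyntheticMEGSpec
) -> dict[str, np.ndarray]:
    """Stacked per-stimulus characteristics for one subject and condition.

    The consistency column is recomputed from noise-free beliefs at the
    spec's true hazard for that condition (the quantity the simulated
    units are meant to code), all other columns from the realized
    stimuli and the subject's own belief trajectories.
    """
    from .characteristics import consistency_under_hazard

    cols: dict[str, list[np.ndarray]] = {k: [] for k in _CHAR_COLUMNS}
    for block, resp, traj in zip(subject.blocks, subject.responses, subject.beliefs):
        if block.condition != condition:
            continue
        chars = compute_characteristics(block, resp, traj, scheme=spec.scheme)
        mat = chars.as_matrix()
        for name, j in _CHAR_COLUMNS.items():
            if name == "consistency":
                cols[name].append(
                    consistency_under_hazard(
                        block, resp, spec.h_true[condition], spec.scheme
                    )
                )
            else:
                cols[name].append(mat[:, j])
    return {k: np.concatenate(v) for k, v in cols.items()}


def generate_meg_features(
    subject: SubjectData,
    spec: SyntheticMEGSpec,
    rng: np.random.Generator,
) -> dict[str, dict]:
    """Simulated feature arrays per condition for one subject.

    Returns ``{condition: {"features": (n x stimuli), "targets": {...},
    "selective": {...}}}``. Unit pools are allocated sequentially per
    characteristic and are identical across conditions up to the
    within-pool overlap ``omega``.
    """
    n_chars = len(spec.characteristics)
    pool_size = spec.n // n_chars
    need = 2 * spec.n_sel - int(round(spec.omega * spec.n_sel))
    if pool_size < need:
        raise ValueError(
            f"unit pool of {pool_size} too small for n_sel={spec.n_sel} at "
            f"omega={spec.omega}"
        )
    # draw per-characteristic selective sets once, shared across conditions
    sel: dict[str, dict[str, np.ndarray]] = {}
    for c_idx, char in enumerate(spec.characteristics):
        offset = c_idx * pool_size
        perm = offset + rng.permutation(pool_size)
        m = int(round(spec.omega * spec.n_sel))
        sel[char] = {
            "Cb": np.concatenate([perm[:m], perm[m : spec.n_sel]]),
            "Ob": np.concatenate([perm[:m], perm[spec.n_sel : 2 * spec.n_sel - m]]),
        }
    out = {}
    for condition in ("Cb", "Ob"):
        table = characteristic_table(subject, condition, spec)
        n_stim = len(table["consistency"])
        z = spec.sigma * rng.standard_normal((spec.n, n_stim))
        targets = {}
        for char in spec.characteristics:
            x = _standardize(table[char])
            targets[char] = x
            z[sel[char][condition], :] += x[None, :]
        out[condition] = {"features": z, "targets": targets,
                          "selective": {c: sel[c][condition] for c in sel}}
    return out
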