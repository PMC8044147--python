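"""Linear coding-unit populations, cross-validated encoding, and
cross-condition code-similarity estimation.

A population of n units represents a standardized scalar variable x
through a subset of n_sel "selective" units:

    z_i = beta_i * x + eps,   beta_i = 1 (selective) or 0, eps ~ N(0, sigma^2)

Decoding proceeds as in sensor-level multivariate analyses: per-feature
univariate least-squares weights estimated on training folds, test data
projected onto the weights, and the pooled prediction-truth correlation
Fisher-transformed into a coding precision.

When the same population codes x in two conditions with selective sets
overlapping in a fraction omega of units, the four precision values
(two within-condition, two cross-condition using the other condition's
weights) jointly constrain (omega, sigma_1, sigma_2); they are recovered
by least squares against an analytic matched-filter forward model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CodingPopulation",
    "EncodingResult",
    "PrecisionScores",
    "SimilarityFit",
    "simulate_population",
    "simulate_condition_pair",
    "encode_cv",
    "generalize_and_fit",
    "expected_precisions",
]

_R_CAP = 1.0 - 1e-12


@dataclass(frozen=True)
class CodingPopulation:
    """Population layout shared by two conditions.

    ``omega`` is the coding similarity: the fraction of selective units
    shared between the two conditions' selective sets (both of size
    ``n_sel``).
    """

    n: int = 300
    n_sel: int = 100
    sigma: float = 1.0
    omega: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        if self.n_sel > self.n:
            raise ValueError("n_sel cannot exceed n")
        n_shared = self.n_shared
        if 2 * self.n_sel - n_shared > self.n:
            raise ValueError("population too small for the requested overlap")

    @property
    def n_shared(self) -> int:
        return int(round(self.omega * self.n_sel))


@dataclass
class EncodingResult:
    precision: float  # Fisher-z of pooled prediction-truth correlation
    correlation: float
    weights: np.ndarray  # per-fold weight matrix (n_folds x n_features)
    predictions: np.ndarray


@dataclass
class PrecisionScores:
    within_1: float
    within_2: float
    gen_1_to_2: float  # weights from condition 1, data from condition 2
    gen_2_to_1: float
    n_folds: int = 12

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.within_1, self.within_2, self.gen_1_to_2, self.gen_2_to_1]
        )


@dataclass
class SimilarityFit:
    omega_hat: float
    sigma_1_hat: float
    sigma_2_hat: float
    residual: float


def selective_sets(pop: CodingPopulation, rng: np.random.Generator):
    """Random selective index sets for two conditions with the given overlap."""
    perm = rng.permutation(pop.n)
    m = pop.n_shared
    shared = perm[:m]
    only1 = perm[m : pop.n_sel]
    only2 = perm[pop.n_sel : 2 * pop.n_sel - m]
    set1 = np.concatenate([shared, only1])
    set2 = np.concatenate([shared, only2])
    return set1, set2


def simulate_population(
    x: np.ndarray,
    selective: np.ndarray,
    n: int,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit activity (n x len(x)) for one condition."""
    x = np.asarray(x, dtype=float)
    beta = np.zeros(n)
    beta[selective] = 1.0
    return beta[:, None] * x[None, :] + sigma * rng.standard_normal((n, len(x)))


def simulate_condition_pair(
    x1: np.ndarray,
    x2: np.ndarray,
    pop: CodingPopulation,
    rng: np.random.Generator,
    sigma_2: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Activity matrices for two conditions with overlapping codes."""
    set1, set2 = selective_sets(pop, rng)
    z1 = simulate_population(x1, set1, pop.n, pop.sigma, rng)
    z2 = simulate_population(
        x2, set2, pop.n, pop.sigma if sigma_2 is None else sigma_2, rng
    )
    return z1, z2


# ---------------------------------------------------------------------------
# cross-validated linear encoding
# ---------------------------------------------------------------------------


def _interleaved_folds(n_samples: int, n_folds: int) -> list[np.ndarray]:
    return [np.arange(f, n_samples, n_folds) for f in range(n_folds)]


def _fit_weights(z_train: np.ndarray, x_train: np.ndarray) -> np.ndarray:
    """Per-feature univariate least-squares regression of z on x."""
    xx = float(np.dot(x_train, x_train))
    if xx == 0.0:
        return np.zeros(z_train.shape[0])
    return z_train @ x_train / xx


def encode_cv(
    features: np.ndarray,
    x: np.ndarray,
    n_folds: int = 12,
    pool: str = "concatenate",
) -> EncodingResult:
    """Cross-validated encoding precision of ``x`` from ``features``.

    ``features`` is (n_features x n_samples). Features are z-scored on
    each training fold (train statistics applied to the test fold). With
    ``pool='concatenate'`` predictions from all folds are pooled before a
    single correlation (the default); ``pool='average'`` Fisher-averages
    per-fold correlations instead.
    """
    features = np.asarray(features, dtype=float)
    x = np.asarray(x, dtype=float)
    n_feat, n_samples = features.shape
    if n_samples < n_folds:
        raise ValueError("fewer samples than folds")
    if len(x) != n_samples:
        raise ValueError("feature and target sample counts differ")
    valid = np.isfinite(x)
    folds = _interleaved_folds(n_samples, n_folds)
    predictions = np.full(n_samples, np.nan)
    weights = np.empty((n_folds, n_feat))
    per_fold_r = []
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n_samples, dtype=bool)
        train_mask[test_idx] = False
        train_mask &= valid
        test_idx = test_idx[valid[test_idx]]
        mu = features[:, train_mask].mean(axis=1, keepdims=True)
        sd = features[:, train_mask].std(axis=1, keepdims=True)
        zero_var = sd[:, 0] == 0.0
        if np.any(zero_var):
            warnings.warn(
                f"{int(zero_var.sum())} zero-variance features; weights set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            sd[zero_var, :] = 1.0
        z_train = (features[:, train_mask] - mu) / sd
        z_test = (features[:, test_idx] - mu) / sd
        w = _fit_weights(z_train, x[train_mask])
        w[zero_var] = 0.0
        weights[f] = w
        predictions[test_idx] = w @ z_test
        if len(test_idx) > 2:
            per_fold_r.append(np.corrcoef(predictions[test_idx], x[test_idx])[0, 1])
    if pool == "concatenate":
        r = float(np.corrcoef(predictions[valid], x[valid])[0, 1])
    elif pool == "average":
        r = float(np.tanh(np.mean(np.arctanh(np.clip(per_fold_r, -_R_CAP, _R_CAP)))))
    else:
        raise ValueError(f"unknown pooling {pool!r}")
    r = float(np.clip(r, -_R_CAP, _R_CAP))
    return EncodingResult(
        precision=float(np.arctanh(r)),
        correlation=r,
        weights=weights,
        predictions=predictions,
    )


def _encode_cross(
    features_train: np.ndarray,
    x_train: np.ndarray,
    features_test: np.ndarray,
    x_test: np.ndarray,
    n_folds: int,
) -> float:
    """Cross-condition precision: weights from one condition's training
    folds, predictions on the other condition's test folds (matched
    train/test volumes with the within-condition analysis)."""
    n_samples = features_train.shape[1]
    folds = _interleaved_folds(n_samples, n_folds)
    predictions = np.full(n_samples, np.nan)
    for test_idx in folds:
        train_mask = np.ones(n_samples, dtype=bool)
        train_mask[test_idx] = False
        mu = features_train[:, train_mask].mean(axis=1, keepdims=True)
        sd = features_train[:, train_mask].std(axis=1, keepdims=True)
        sd[sd == 0.0] = 1.0
        z_train = (features_train[:, train_mask] - mu) / sd
        w = _fit_weights(z_train, x_train[train_mask])
        mu2 = features_test[:, train_mask].mean(axis=1, keepdims=True)
        sd2 = features_test[:, train_mask].std(axis=1, keepdims=True)
        sd2[sd2 == 0.0] = 1.0
        z_test = (features_test[:, test_idx] - mu2) / sd2
        predictions[test_idx] = w @ z_test
    r = float(np.corrcoef(predictions, x_test)[0, 1])
    r = float(np.clip(r, -_R_CAP, _R_CAP))
    return float(np.arctanh(r))


# ---------------------------------------------------------------------------
# similarity estimation
# ---------------------------------------------------------------------------


def expected_precisions(
    omega: float,
    sigma_1: float,
    sigma_2: float,
    n: int,
    n_sel: int,
    n_train: int,
) -> np.ndarray:
    """Analytic expectation of the four precision values.

    Matched-filter argument: with unit selective gains and standardized
    x, the estimated weight of unit i is beta_i plus estimation noise of
    variance sigma^2/n_train. Projecting test activity of the (possibly
    other) condition onto these weights gives signal m (the number of
    jointly selective units between the weight and data conditions) and
    noise variance sigma_test^2 * (n_sel + n * sigma_train^2 / n_train),
    whence r = m / sqrt(m^2 + noise). Feature standardization divides
    each unit by sqrt(1[selective] + sigma^2), scaling its effective
    gain and noise alike, which the model tracks.
    """
    out = np.empty(4)
    m_between = omega * n_sel

    def prec(m, sig_w, sig_d):
        # after per-unit z-scoring a selective unit reads g*(x + sig*eps)
        # with g = 1/sqrt(1 + sig^2); a non-selective unit is unit noise.
        g_w = 1.0 / np.sqrt(1.0 + sig_w**2)
        g_d = 1.0 / np.sqrt(1.0 + sig_d**2)
        ew2 = (g_w * sig_w) ** 2 / n_train  # weight noise, selective-in-w units
        en2 = 1.0 / n_train  # weight noise, non-selective-in-w units
        signal = m * g_w * g_d
        var = m * (g_w**2 + ew2) * (g_d * sig_d) ** 2
        var += (n_sel - m) * (g_w**2 + ew2)  # selective in weights only
        var += (n_sel - m) * en2 * ((g_d * sig_d) ** 2 + g_d**2)  # in data only
        var += (n - 2 * n_sel + m) * en2  # selective in neither
        denom = np.sqrt(signal**2 + var)
        r = signal / denom if denom > 0 else 0.0
        return np.arctanh(np.clip(r, -_R_CAP, _R_CAP))

    out[0] = prec(n_sel, sigma_1, sigma_1)
    out[1] = prec(n_sel, sigma_2, sigma_2)
    out[2] = prec(m_between, sigma_1, sigma_2)
    out[3] = prec(m_between, sigma_2, sigma_1)
    return out


def generalize_and_fit(
    features_1: np.ndarray,
    features_2: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    n: int | None = None,
    n_sel: int = 100,
    n_folds: int = 12,
) -> tuple[PrecisionScores, SimilarityFit]:
    """Four-way precision scores and the (omega, sigma_1, sigma_2) fit."""
    if features_1.shape != features_2.shape:
        raise ValueError("conditions must have equal feature/sample counts")
    n = features_1.shape[0] if n is None else n
    n_samples = features_1.shape[1]
    n_train = n_samples - n_samples // n_folds
    scores = PrecisionScores(
        within_1=encode_cv(features_1, x1, n_folds).precision,
        within_2=encode_cv(features_2, x2, n_folds).precision,
        gen_1_to_2=_encode_cross(features_1, x1, features_2, x2, n_folds),
        gen_2_to_1=_encode_cross(features_2, x2, features_1, x1, n_folds),
        n_folds=n_folds,
    )
    observed = scores.as_array()

    def resid(p):
        omega, log_s1, log_s2 = p
        model = expected_precisions(
            omega, np.exp(log_s1), np.exp(log_s2), n, n_sel, n_train
        )
        return model - observed

    best = None
    for w0 in (0.0, 0.5, 1.0):
        res = least_squares(
            resid,
            x0=[w0, 0.0, 0.0],
            bounds=([0.0, -5.0, -5.0], [1.0, 5.0, 5.0]),
        )
        if best is None or res.cost < best.cost:
            best = res
    omega_hat, log_s1, log_s2 = best.x
    fit = SimilarityFit(
        omega_hat=float(omega_hat),
        sigma_1_hat=float(np.exp(log_s1)),
        sigma_2_hat=float(np.exp(log_s2)),
        residual=float(np.sqrt(2 * best.cost)),
    )
    return scores, fit
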