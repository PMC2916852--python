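"""Bayesian causal-inference model of audiovisual spatial localization.

An observer receives a noisy auditory sensation ``x_A`` and a noisy visual
sensation ``x_V`` of source locations along the azimuth, and must decide
whether the two signals share one cause (C = 1, a single audiovisual event)
or arise from two independent causes (C = 2).  Sensory noise is Gaussian
with modality-specific standard deviations ``sigma_A`` and ``sigma_V``;
locations carry a central-bias prior, Gaussian with mean 0 deg and standard
deviation ``sigma_P``; and the prior probability of a common cause is
``p_common``.

Conditional on the causal structure, the optimal location estimates are
closed-form Gaussian posteriors: reliability-weighted fusion of both cues
and the prior under C = 1, and single-cue shrinkage toward straight ahead
under C = 2.  The posterior probability of a common cause combines the two
marginal likelihoods with ``p_common`` via Bayes' rule.

Three decision strategies map the structure-conditional estimates to a
final response on each trial:

``averaging``
    posterior-weighted mixture of the two estimates (minimizes expected
    squared error of the location report),
``selection``
    commit to the more probable structure (posterior compared against a
    fixed criterion, 0.5 unless the biased variant frees it),
``matching``
    commit to the common-cause structure with probability equal to its
    posterior, realized by comparing the posterior against a fresh uniform
    draw ``xi`` on each trial.

All functions accept scalars or NumPy arrays and broadcast; likelihood
computations are done in log space to stay finite at large cue conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
from scipy.special import expit

__all__ = [
    "STRATEGIES",
    "MEAN_SUBJECT_PARAMS",
    "ModelParams",
    "Sensation",
    "StructureEstimates",
    "log_likelihood_c1",
    "log_likelihood_c2",
    "likelihood_c1",
    "likelihood_c2",
    "posterior_c1",
    "estimate_c1",
    "estimate_c2",
    "structure_estimates",
    "apply_strategy",
    "matching_expected_accuracy",
    "maximizing_expected_accuracy",
]

ArrayLike = Union[float, np.ndarray]

#: The three decision strategies compared per observer.
STRATEGIES = ("averaging", "selection", "matching")


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the causal-inference observer.

    Parameters
    ----------
    sigma_A : float
        Auditory likelihood standard deviation, degrees (> 0).
    sigma_V : float
        Visual likelihood standard deviation, degrees (> 0).
    sigma_P : float
        Standard deviation of the central spatial prior, degrees (> 0).
        The prior mean is fixed at 0 deg and is not a free parameter.
    p_common : float
        Prior probability of a common cause, in [0, 1].
    criterion : float, optional
        Posterior threshold used by the selection strategy.  0.5 gives
        standard model selection; the biased-selection variant fits it as
        a fifth free parameter.  Must lie in [0, 1].
    """

    sigma_A: float
    sigma_V: float
    sigma_P: float
    p_common: float
    criterion: float = 0.5

    def __post_init__(self) -> None:
        for name in ("sigma_A", "sigma_V", "sigma_P"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {value!r}")
        if not 0.0 <= self.p_common <= 1.0:
            raise ValueError(f"p_common must lie in [0, 1], got {self.p_common!r}")
        if not 0.0 <= self.criterion <= 1.0:
            raise ValueError(f"criterion must lie in [0, 1], got {self.criterion!r}")

    def with_criterion(self, criterion: float) -> "ModelParams":
        return replace(self, criterion=criterion)


#: Typical human-observer parameter values for this task, used as simulation
#: defaults throughout the package.
MEAN_SUBJECT_PARAMS = ModelParams(sigma_A=10.1, sigma_V=2.5, sigma_P=33.0, p_common=0.57)


@dataclass(frozen=True)
class Sensation:
    """Noisy internal measurement(s) for one trial (or a batch of trials).

    At least one modality must be present; unisensory trials carry only
    the stimulated modality.  Fields may be scalars or aligned arrays.
    """

    x_A: Optional[ArrayLike] = None
    x_V: Optional[ArrayLike] = None

    def __post_init__(self) -> None:
        if self.x_A is None and self.x_V is None:
            raise ValueError("a Sensation needs at least one of x_A, x_V")


@dataclass(frozen=True)
class StructureEstimates:
    """Structure-conditional location estimates plus the structure posterior.

    Under C = 1 the auditory and visual estimates coincide (full fusion),
    so ``s_hat_V_c1 == s_hat_A_c1`` by construction.
    """

    s_hat_A_c1: ArrayLike
    s_hat_V_c1: ArrayLike
    s_hat_A_c2: ArrayLike
    s_hat_V_c2: ArrayLike
    post_c1: ArrayLike


def _variances(params: ModelParams) -> tuple[float, float, float]:
    return params.sigma_A**2, params.sigma_V**2, params.sigma_P**2


def log_likelihood_c1(x_A: ArrayLike, x_V: ArrayLike, params: ModelParams) -> ArrayLike:
    """Log of p(x_A, x_V | C = 1).

    The common source s is integrated out analytically against the central
    prior N(0, sigma_P^2), giving a bivariate Gaussian in (x_A, x_V):

        p = exp(-0.5 * [ (x_A - x_V)^2 sP^2 + x_A^2 sV^2 + x_V^2 sA^2 ] / D)
            / (2 pi sqrt(D)),   D = sA^2 sV^2 + sA^2 sP^2 + sV^2 sP^2

    with all variances in squared degrees.
    """
    va, vv, vp = _variances(params)
    x_A = np.asarray(x_A, dtype=float)
    x_V = np.asarray(x_V, dtype=float)
    denom = va * vv + va * vp + vv * vp
    quad = ((x_A - x_V) ** 2 * vp + x_A**2 * vv + x_V**2 * va) / denom
    return -np.log(2.0 * np.pi) - 0.5 * np.log(denom) - 0.5 * quad


def log_likelihood_c2(x_A: ArrayLike, x_V: ArrayLike, params: ModelParams) -> ArrayLike:
    """Log of p(x_A, x_V | C = 2).

    Each source is drawn independently from the central prior, so the joint
    factorizes into two zero-mean Gaussian marginals with variances
    sigma_A^2 + sigma_P^2 and sigma_V^2 + sigma_P^2.
    """
    va, vv, vp = _variances(params)
    x_A = np.asarray(x_A, dtype=float)
    x_V = np.asarray(x_V, dtype=float)
    log_a = -0.5 * (np.log(2.0 * np.pi * (va + vp)) + x_A**2 / (va + vp))
    log_v = -0.5 * (np.log(2.0 * np.pi * (vv + vp)) + x_V**2 / (vv + vp))
    return log_a + log_v


def likelihood_c1(x_A: ArrayLike, x_V: ArrayLike, params: ModelParams) -> ArrayLike:
    """p(x_A, x_V | C = 1); see :func:`log_likelihood_c1`."""
    return np.exp(log_likelihood_c1(x_A, x_V, params))


def likelihood_c2(x_A: ArrayLike, x_V: ArrayLike, params: ModelParams) -> ArrayLike:
    """p(x_A, x_V | C = 2); see :func:`log_likelihood_c2`."""
    return np.exp(log_likelihood_c2(x_A, x_V, params))


def posterior_c1(x_A: ArrayLike, x_V: ArrayLike, params: ModelParams) -> ArrayLike:
    """Posterior probability of a common cause, p(C = 1 | x_A, x_V).

    Computed from the log-likelihood ratio through a logistic transform so
    the result stays in [0, 1] even when both likelihoods underflow.
    """
    pc = params.p_common
    x_A = np.asarray(x_A, dtype=float)
    x_V = np.asarray(x_V, dtype=float)
    shape = np.broadcast_shapes(x_A.shape, x_V.shape)
    if pc == 0.0:
        return np.zeros(shape) if shape else 0.0
    if pc == 1.0:
        return np.ones(shape) if shape else 1.0
    log_odds = (
        log_likelihood_c1(x_A, x_V, params)
        - log_likelihood_c2(x_A, x_V, params)
        + np.log(pc)
        - np.log1p(-pc)
    )
    post = expit(log_odds)
    return post if shape else float(post)


def estimate_c1(x_A: ArrayLike, x_V: ArrayLike, params: ModelParams) -> ArrayLike:
    """Fused location estimate under a common cause (C = 1).

    Reliability-weighted average of both sensations and the prior mean
    (0 deg); the same value serves as the auditory and visual estimate.
    """
    if x_A is None or x_V is None:
        raise ValueError("estimate_c1 requires both an auditory and a visual sensation")
    va, vv, vp = _variances(params)
    x_A = np.asarray(x_A, dtype=float)
    x_V = np.asarray(x_V, dtype=float)
    return (x_A / va + x_V / vv) / (1.0 / va + 1.0 / vv + 1.0 / vp)


def estimate_c2(x: ArrayLike, sigma: float, params: ModelParams) -> ArrayLike:
    """Single-cue location estimate under independent causes (C = 2).

    Shrinks the sensation toward the prior mean: x * sP^2 / (sP^2 + sigma^2).
    Also the response rule on unisensory trials, with the stimulated
    modality's sigma.
    """
    if x is None:
        raise ValueError("estimate_c2 requires a sensation")
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"sigma must be a positive finite number, got {sigma!r}")
    vp = params.sigma_P**2
    x = np.asarray(x, dtype=float)
    return x * vp / (vp + sigma**2)


def structure_estimates(x_A: ArrayLike, x_V: ArrayLike, params: ModelParams) -> StructureEstimates:
    """Bundle the C = 1 / C = 2 estimates and the structure posterior for a trial batch."""
    fused = estimate_c1(x_A, x_V, params)
    return StructureEstimates(
        s_hat_A_c1=fused,
        s_hat_V_c1=fused,
        s_hat_A_c2=estimate_c2(x_A, params.sigma_A, params),
        s_hat_V_c2=estimate_c2(x_V, params.sigma_V, params),
        post_c1=posterior_c1(x_A, x_V, params),
    )


def apply_strategy(
    strategy: str,
    est: StructureEstimates,
    params: ModelParams,
    xi: Optional[ArrayLike] = None,
) -> tuple[ArrayLike, ArrayLike]:
    """Map structure-conditional estimates to the trial's final (auditory, visual) report.

    ``averaging`` returns the posterior-weighted mixture; ``selection``
    commits to C = 1 iff post_c1 > params.criterion; ``matching`` commits to
    C = 1 iff post_c1 > xi, with ``xi`` a fresh Uniform(0, 1) draw per trial.
    Selection and matching use a single structure choice for both modality
    reports on a trial; ties at the threshold resolve to C = 2 (the strict
    inequality), a measure-zero convention fixed for reproducibility.
    """
    post = np.asarray(est.post_c1, dtype=float)
    a1 = np.asarray(est.s_hat_A_c1, dtype=float)
    v1 = np.asarray(est.s_hat_V_c1, dtype=float)
    a2 = np.asarray(est.s_hat_A_c2, dtype=float)
    v2 = np.asarray(est.s_hat_V_c2, dtype=float)
    if strategy == "averaging":
        return post * a1 + (1.0 - post) * a2, post * v1 + (1.0 - post) * v2
    if strategy == "selection":
        choose_c1 = post > params.criterion
    elif strategy == "matching":
        if xi is None:
            raise ValueError("the matching strategy needs a uniform draw xi")
        choose_c1 = post > np.asarray(xi, dtype=float)
    else:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    return np.where(choose_c1, a1, a2), np.where(choose_c1, v1, v2)


def matching_expected_accuracy(p: float) -> float:
    """Expected accuracy of probability matching on a binary guess.

    For an event occurring with probability ``p``, predicting it with
    probability ``p`` is correct with probability p^2 + (1 - p)^2 — e.g.
    0.58 at p = 0.70, below the 0.70 achieved by always predicting the
    more frequent outcome (:func:`maximizing_expected_accuracy`).
    """
    return p * p + (1.0 - p) * (1.0 - p)


def maximizing_expected_accuracy(p: float) -> float:
    """Expected accuracy of always predicting the more frequent binary outcome."""
    return max(p, 1.0 - p)
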