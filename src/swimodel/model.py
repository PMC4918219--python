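"""Closed-form competitive-prior model of weight-ratio perception.

The observer judges the relative weight ``w = ln(w_A/w_B)`` of two
objects (A the smaller) from a visual volume-ratio measurement ``y``
and, when lifting, a haptic weight-ratio measurement ``x``.  Density is
never sensed directly: the observer entertains three categorical
hypotheses about the density relationship,

* R1 — equal density (``d = 0``, so ``w = v`` exactly),
* R2 — the smaller object is denser (``v``–``d`` correlation < 0),
* R3 — the larger object is denser (correlation > 0),

each defining a bivariate Gaussian prior over ``(v, d)`` with zero mean
(plus an optional offset on ``d`` under R2) and covariance
``[[sv2, rho*sv*sd], [rho*sv*sd, sd2]]``.

The visual measurement is treated as the observer's belief about the
volume ratio, ``v ~ N(y, sigma_y2)``; the density relationship under
each hypothesis follows from the conditional prior ``p(d | v, R)``.
Pushing through ``w = v + d`` gives one Gaussian expectation of the
weight ratio per hypothesis.  When lifting, the haptic likelihood both
updates each expectation and arbitrates among hypotheses; the percept is
the MAP of the resulting mixture.

Two arbitration rules are provided.  ``"likelihood"`` (default) weights
the mixture by the normalized haptic predictive likelihoods
``p(x|R, y)`` — the rule that reproduces the published size-weight
illusion predictions.  ``"posterior"`` weights by the full hypothesis
posterior ``p(R|x, y) ∝ p(x|R, y) p(R)``, which is also what the exposed
:func:`hypothesis_posterior` computes.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np

from .modes import mixture_map_grid, mixture_map_newton
from .params import DensityHypothesis, GaussianBelief, ModelParams, PosteriorMixture

__all__ = [
    "Arbitration",
    "visual_log_volume_mean",
    "density_prior_covariance",
    "weight_prior_under_hypothesis",
    "posterior_w_given_hypothesis",
    "posterior_mean_w",
    "haptic_likelihood_given_hypothesis",
    "hypothesis_posterior",
    "arbitration_weights",
    "posterior_mixture",
    "map_no_lift",
    "map_lift",
    "map_lift_batch",
    "map_no_lift_batch",
    "naive_single_prior_estimate",
]

Arbitration = Literal["likelihood", "posterior"]

_H = (DensityHypothesis.R1, DensityHypothesis.R2, DensityHypothesis.R3)


def visual_log_volume_mean(V_A: float, V_B: float, params: ModelParams) -> float:
    """Mean of the visual measurement of the log volume ratio.

    Visual volume is compressed by a power law, so
    ``v* = exponent * ln(V_A/V_B)``.
    """
    if V_A <= 0 or V_B <= 0:
        raise ValueError(f"volumes must be positive, got {V_A}, {V_B}")
    return params.volume_exponent * math.log(V_A / V_B)


def density_prior_covariance(h: DensityHypothesis, params: ModelParams) -> np.ndarray:
    """2x2 prior covariance of ``(v, d)`` under hypothesis ``h``.

    For R1 the density row/column is identically zero (equal density is
    an exact 1-D model, never a near-singular 2-D Gaussian).
    """
    sd2 = params.sigma_d2_of(h)
    rho = params.rho(h)
    off = rho * math.sqrt(params.sigma_v2 * sd2)
    return np.array([[params.sigma_v2, off], [off, sd2]])


def weight_prior_under_hypothesis(h: DensityHypothesis, params: ModelParams) -> GaussianBelief:
    """Prior marginal of ``w = v + d`` under ``h`` (no sensory evidence).

    Variance is ``sv2 + sd2 + 2 rho sv sd`` (``sv2`` alone for R1); the
    mean is the R2 density offset where applicable.
    """
    sd2 = params.sigma_d2_of(h)
    rho = params.rho(h)
    var = params.sigma_v2 + sd2 + 2.0 * rho * math.sqrt(params.sigma_v2 * sd2)
    return GaussianBelief(mean=params.mu_d(h), variance=var)


def _vision_slope(h: DensityHypothesis, params: ModelParams) -> float:
    """d E[w]/d y under ``h``: 1 + rho * sd/sv (1 for R1)."""
    if h is DensityHypothesis.R1:
        return 1.0
    return 1.0 + params.rho(h) * math.sqrt(params.sigma_d2 / params.sigma_v2)


def _component_given_vision(y: float, h: DensityHypothesis, params: ModelParams) -> tuple[float, float]:
    """Mean and variance of ``p(w | R, y)`` (no haptic information)."""
    k = _vision_slope(h, params)
    mean = k * y + params.mu_d(h)
    var = k * k * params.sigma_y2
    if h is not DensityHypothesis.R1:
        var += params.sigma_d2 * (1.0 - params.rho(h) ** 2)
    return mean, var


def posterior_w_given_hypothesis(
    y: float,
    x: float | None,
    h: DensityHypothesis,
    params: ModelParams,
) -> GaussianBelief:
    """Posterior over the log weight ratio under a single hypothesis.

    Without haptic input this is the visual expectation
    ``N(k_h * y + mu_h, k_h^2 sy2 + (1-rho^2) sd2)``; with a haptic
    measurement ``x`` it is the precision-weighted product with
    ``N(x; w, sigma_x2)``.
    """
    m, s2 = _component_given_vision(y, h, params)
    if x is None:
        return GaussianBelief(mean=m, variance=s2)
    if params.sigma_x2 == 0:
        return GaussianBelief(mean=x, variance=0.0)
    prec = 1.0 / s2 + 1.0 / params.sigma_x2 if s2 > 0 else math.inf
    if s2 == 0:
        return GaussianBelief(mean=m, variance=0.0)
    mean = (m / s2 + x / params.sigma_x2) / prec
    return GaussianBelief(mean=mean, variance=1.0 / prec)


def posterior_mean_w(y: float, x: float | None, h: DensityHypothesis, params: ModelParams) -> float:
    """Posterior mean of ``w`` under ``h`` (the per-hypothesis estimate)."""
    return posterior_w_given_hypothesis(y, x, h, params).mean


def haptic_likelihood_given_hypothesis(
    x: float, y: float, h: DensityHypothesis, params: ModelParams
) -> float:
    """Predictive density ``p(x | R, y) = N(x; m_h(y), s_h^2(y) + sigma_x2)``."""
    if x is None:
        raise ValueError("haptic likelihood requires a haptic measurement x")
    m, s2 = _component_given_vision(y, h, params)
    var = s2 + params.sigma_x2
    if var <= 0:
        raise ValueError("degenerate predictive variance")
    return math.exp(-((x - m) ** 2) / (2 * var)) / math.sqrt(2 * math.pi * var)


def hypothesis_posterior(x: float, y: float, params: ModelParams) -> tuple[float, float, float]:
    """Posterior probability of each density hypothesis given ``x`` and ``y``.

    ``p(R_i | x, y) ∝ p(x | R_i, y) p(R_i)``; returns a triple summing
    to 1.
    """
    if x is None:
        raise ValueError("hypothesis_posterior requires a haptic measurement x")
    lik = [haptic_likelihood_given_hypothesis(x, y, h, params) for h in _H]
    w = [l * p for l, p in zip(lik, params.prior_R)]
    total = sum(w)
    if total <= 0 or not math.isfinite(total):
        raise FloatingPointError(
            f"all hypothesis likelihoods vanished at x={x}, y={y}; "
            "the measurements are inconsistent with every hypothesis at this precision"
        )
    return tuple(wi / total for wi in w)


def arbitration_weights(
    x: float, y: float, params: ModelParams, arbitration: Arbitration = "likelihood"
) -> tuple[float, float, float]:
    """Mixture weights used by the lifting percept."""
    if arbitration == "posterior":
        return hypothesis_posterior(x, y, params)
    if arbitration != "likelihood":
        raise ValueError(f"unknown arbitration rule: {arbitration!r}")
    lik = [haptic_likelihood_given_hypothesis(x, y, h, params) for h in _H]
    total = sum(lik)
    if total <= 0 or not math.isfinite(total):
        raise FloatingPointError(f"all hypothesis likelihoods vanished at x={x}, y={y}")
    return tuple(l / total for l in lik)


def posterior_mixture(
    y: float,
    x: float | None,
    params: ModelParams,
    arbitration: Arbitration = "likelihood",
) -> PosteriorMixture:
    """Full mixture posterior over ``w``.

    Without haptic input the components are the per-hypothesis visual
    expectations weighted by the hypothesis priors; with haptic input the
    components are haptic-updated and the weights follow the requested
    arbitration rule.
    """
    if x is None:
        weights = params.prior_R
    else:
        weights = arbitration_weights(x, y, params, arbitration)
    comps = []
    for h, wt in zip(_H, weights):
        b = posterior_w_given_hypothesis(y, x, h, params)
        comps.append(GaussianBelief(mean=b.mean, variance=b.variance, weight=min(wt, 1.0)))
    return PosteriorMixture(components=tuple(comps), hypothesis_posteriors=tuple(weights))


def _mixture_map(mix: PosteriorMixture) -> float:
    means = [c.mean for c in mix.components]
    variances = [max(c.variance, 1e-12) for c in mix.components]
    weights = [c.weight for c in mix.components]
    return mixture_map_grid(means, variances, weights)


def map_no_lift(y: float, params: ModelParams) -> float:
    """MAP percept of ``w`` with vision only (Expectation condition)."""
    return _mixture_map(posterior_mixture(y, None, params))


def map_lift(
    x: float, y: float, params: ModelParams, arbitration: Arbitration = "likelihood"
) -> float:
    """MAP percept of ``w`` when lifting (vision + haptics)."""
    if x is None:
        raise ValueError("map_lift requires a haptic measurement x; use map_no_lift")
    return _mixture_map(posterior_mixture(y, x, params, arbitration))


def naive_single_prior_estimate(x: float, y: float, params: ModelParams,
                                prior_variance: float | None = None) -> float:
    """Single-prior ("larger is heavier") baseline estimate.

    The classic formulation keeps only the equal-density expectation
    ``N(y, sigma_y2)`` as the prior over ``w`` and combines it with the
    haptic likelihood; for equally weighted objects it predicts the
    *larger* object to feel heavier — the reverse of the size-weight
    illusion.  ``prior_variance`` overrides the prior width (the flat
    limit returns ``x``).
    """
    if x is None:
        raise ValueError("the naive baseline requires a haptic measurement x")
    s2 = params.sigma_y2 if prior_variance is None else prior_variance
    if not math.isfinite(s2):
        return x
    if s2 <= 0:
        return y
    prec = 1.0 / s2 + 1.0 / params.sigma_x2
    return (y / s2 + x / params.sigma_x2) / prec


# ----------------------------------------------------------------------
# batched percepts (simulation / fitting path)
# ----------------------------------------------------------------------

def _components_batch(y: np.ndarray, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, float)
    k = np.array([_vision_slope(h, params) for h in _H])
    mu = np.array([params.mu_d(h) for h in _H])
    resid = np.array(
        [0.0 if h is DensityHypothesis.R1 else params.sigma_d2 * (1 - params.rho(h) ** 2) for h in _H]
    )
    means = y[:, None] * k[None, :] + mu[None, :]
    variances = np.broadcast_to(k ** 2 * params.sigma_y2 + resid, means.shape).copy()
    return means, variances


def map_no_lift_batch(y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Vectorized :func:`map_no_lift` over an array of visual measurements."""
    means, variances = _components_batch(y, params)
    weights = np.broadcast_to(np.asarray(params.prior_R), means.shape)
    return mixture_map_newton(means, np.maximum(variances, 1e-12), weights)


def map_lift_batch(
    x: np.ndarray, y: np.ndarray, params: ModelParams, arbitration: Arbitration = "likelihood"
) -> np.ndarray:
    """Vectorized :func:`map_lift` over paired measurement arrays."""
    x = np.asarray(x, float)
    means, variances = _components_batch(y, params)
    pred_var = variances + params.sigma_x2
    log_lik = -((x[:, None] - means) ** 2) / (2 * pred_var) - 0.5 * np.log(2 * np.pi * pred_var)
    if arbitration == "posterior":
        log_lik = log_lik + np.log(np.maximum(params.prior_R, 1e-300))
    elif arbitration != "likelihood":
        raise ValueError(f"unknown arbitration rule: {arbitration!r}")
    log_lik -= log_lik.max(axis=1, keepdims=True)
    weights = np.exp(log_lik)
    weights /= weights.sum(axis=1, keepdims=True)
    prec = 1.0 / np.maximum(variances, 1e-12) + 1.0 / params.sigma_x2
    post_mean = (means / np.maximum(variances, 1e-12) + x[:, None] / params.sigma_x2) / prec
    post_var = 1.0 / prec
    return mixture_map_newton(post_mean, post_var, weights)
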