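"""Brute-force numerical oracle for the closed-form posteriors.

Every closed form in :mod:`swimodel.model` is the result of
linear-Gaussian algebra on the generative chain

    v ~ N(y, sigma_y2)          (visual belief about the volume ratio)
    d | v, R ~ N(mu_R + rho_R (sd_R/sv) v, (1 - rho_R^2) sd_R^2)
    w = v + d
    x | w ~ N(w, sigma_x2)      (haptic measurement, when present)

This module evaluates the same chain by direct numerical integration
over ``(v, d)`` (equivalently over ``(v, w)``) on a dense grid and is
used only to validate the closed forms; the main computational path
never integrates numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import DensityHypothesis, ModelParams

__all__ = ["GridSpec", "OracleResult", "grid_posterior_oracle"]

_H = (DensityHypothesis.R1, DensityHypothesis.R2, DensityHypothesis.R3)


@dataclass(frozen=True)
class GridSpec:
    """Integration grid. Must cover at least ±6 in w, v and d."""

    half_width: float = 10.0
    step: float = 0.01
    boundary_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.half_width < 6.0:
            raise ValueError("grid must cover at least ±6 in w, v and d")

    def axis(self) -> np.ndarray:
        n = int(round(2 * self.half_width / self.step)) + 1
        return np.linspace(-self.half_width, self.half_width, n)


@dataclass(frozen=True)
class OracleResult:
    """Discretized mixture posterior over w."""

    w: np.ndarray                       # grid over w
    component_density: np.ndarray       # (3, n) normalized p(w | R_i, [x,] y)
    likelihoods: np.ndarray             # (3,) integral p(x | R_i, y) (ones if x absent)
    weights: np.ndarray                 # (3,) mixture weights used
    density: np.ndarray                 # (n,) normalized mixture posterior

    @property
    def map_estimate(self) -> float:
        dens = self.density
        best = dens.max()
        tied = np.flatnonzero(dens >= best * (1 - 1e-12))
        return float(self.w[tied[np.argmin(np.abs(self.w[tied]))]])

    def component_moments(self, h: DensityHypothesis) -> tuple[float, float]:
        p = self.component_density[h.index]
        dw = self.w[1] - self.w[0]
        mass = np.sum(p) * dw
        mean = np.sum(self.w * p) * dw / mass
        var = np.sum((self.w - mean) ** 2 * p) * dw / mass
        return float(mean), float(var)

    @property
    def mass(self) -> float:
        dw = self.w[1] - self.w[0]
        return float(np.sum(self.density) * dw)


def _gauss(z: np.ndarray, mean, var) -> np.ndarray:
    return np.exp(-((z - mean) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)


def grid_posterior_oracle(
    y: float,
    x: float | None,
    params: ModelParams,
    grid: GridSpec | None = None,
    weight_mode: str = "prior",
) -> OracleResult:
    """Numerically integrated mixture posterior over ``w``.

    ``weight_mode`` selects the mixture weights: ``"prior"`` (hypothesis
    priors; the no-lift rule — also used with ``x`` for the
    posterior-arbitration variant, where the likelihood integrals supply
    the evidence) or ``"likelihood"`` (normalized likelihoods only).
    """
    grid = grid or GridSpec()
    w_axis = grid.axis()
    v_axis = w_axis  # same coverage for the latent volume ratio
    dw = w_axis[1] - w_axis[0]

    comp = np.zeros((3, w_axis.size))
    lik = np.ones(3)
    for h in _H:
        if h is DensityHypothesis.R1:
            # w = v exactly: 1-D in v
            dens = _gauss(w_axis, y, params.sigma_y2)
        else:
            rho = params.rho(h)
            beta = rho * math.sqrt(params.sigma_d2 / params.sigma_v2)
            resid = params.sigma_d2 * (1 - rho ** 2)
            mu = params.mu_d(h)
            # p(w|R,y) = ∫ N(v; y, sy2) N(w - v; mu + beta v, resid) dv
            pv = _gauss(v_axis, y, params.sigma_y2)                    # (nv,)
            d_mean = mu + beta * v_axis                                # (nv,)
            if resid <= 0:
                # degenerate conditional: d deterministic given v
                w_det = v_axis + d_mean
                dens = np.zeros_like(w_axis)
                idx = np.clip(np.round((w_det - w_axis[0]) / dw).astype(int), 0, w_axis.size - 1)
                np.add.at(dens, idx, pv)
            else:
                pd = _gauss(w_axis[:, None] - v_axis[None, :], d_mean[None, :], resid)
                dens = pd @ pv * dw
        if x is not None:
            dens = dens * _gauss(w_axis, x, params.sigma_x2)
            lik[h.index] = float(np.sum(dens) * dw)
        mass = np.sum(dens) * dw
        if mass <= 0:
            raise FloatingPointError(f"zero posterior mass under {h}")
        edge = (dens[0] + dens[-1]) * dw / mass
        if edge > grid.boundary_tol:
            raise ValueError(
                f"grid too coarse/narrow: boundary mass {edge:.2e} under {h}"
            )
        comp[h.index] = dens / mass

    if x is None or weight_mode == "prior":
        weights = np.array(params.prior_R, float)
        if x is not None:
            weights = weights * lik
    elif weight_mode == "likelihood":
        weights = lik.copy()
    else:
        raise ValueError(f"unknown weight_mode: {weight_mode!r}")
    weights = weights / weights.sum()

    density = (weights[:, None] * comp).sum(axis=0)
    density = density / (np.sum(density) * dw)
    return OracleResult(w=w_axis, component_density=comp, likelihoods=lik,
                        weights=weights, density=density)
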