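"""Maximum-likelihood parameter recovery from trial tables.

The predictive density of a canonical log report under candidate
parameters is approximated by Monte Carlo: sensory measurements are
sampled per condition, pushed through the percept model, and the
log-normal report stage closes the likelihood in closed form:

    p(ln r | condition) ≈ mean_k N(ln r; w_k, report_noise_sd^2)

Common random numbers across candidates keep the likelihood surface
smooth, and the search is a two-stage grid (coarse, then refined around
the best cell) over the requested free parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from . import model
from .analysis import _canonical_log
from .params import ModelParams
from .stimuli import VOLUMES_CM3

__all__ = ["FitSpec", "FitResult", "fit_observer", "FREE_PARAMS"]

FREE_PARAMS = ("sigma_x2", "prior_R2", "mu_d_R2", "report_noise_sd")

_DEFAULT_RANGES = {
    "sigma_x2": (0.05, 1.5),
    "prior_R2": (0.01, 0.6),
    "mu_d_R2": (0.0, 3.0),
    "report_noise_sd": (0.05, 0.6),
}

#: profile log-likelihood range below which a parameter is reported
#: non-identifiable
_FLAT_PROFILE_TOL = 0.5


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``free`` names the parameters to estimate (subset of
    :data:`FREE_PARAMS`); the rest are fixed at ``base``'s values.
    """

    free: tuple[str, ...]
    base: ModelParams = field(default_factory=ModelParams)
    report_noise_sd: float = 0.21
    arbitration: model.Arbitration = "likelihood"
    observer_model: Literal["competitive", "naive"] = "competitive"
    n_draws: int = 160
    n_grid: int = 13
    n_stages: int = 2
    seed: int = 0
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.free) - set(FREE_PARAMS)
        if unknown:
            raise ValueError(f"cannot fit parameter(s) {sorted(unknown)}; "
                             f"free parameters are {FREE_PARAMS}")
        if not self.free:
            raise ValueError("fit_spec must name at least one free parameter")

    def range_of(self, name: str) -> tuple[float, float]:
        return self.ranges.get(name, _DEFAULT_RANGES[name])


@dataclass(frozen=True)
class FitResult:
    estimates: dict[str, float]
    log_likelihood: float
    profiles: dict[str, pd.DataFrame]
    non_identifiable: tuple[str, ...]

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


def _apply_candidate(base: ModelParams, values: dict[str, float]) -> tuple[ModelParams, float]:
    noise = values.get("report_noise_sd")
    p = base
    if "sigma_x2" in values:
        p = replace(p, sigma_x2=values["sigma_x2"])
    if "mu_d_R2" in values:
        p = replace(p, mu_d_R2=values["mu_d_R2"])
    if "prior_R2" in values:
        p = p.with_prior_R2(values["prior_R2"])
    return p, noise if noise is not None else math.nan


def _condition_table(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials[trials["ordering"] != "I-S"].copy()
    t["ln_report"] = _canonical_log(t)
    t["condition"] = t["session"] + "/" + t["pair"]
    return t


def _percepts_for(params: ModelParams, session: str, vstar: float,
                  z_y: np.ndarray, z_x: np.ndarray,
                  spec: FitSpec) -> np.ndarray:
    """Percept samples for one condition under candidate params."""
    y = vstar + z_y * math.sqrt(params.sigma_y2)
    if spec.observer_model == "naive":
        if session == "Expectation":
            return y
        x = z_x * math.sqrt(params.sigma_x2)
        return np.array([model.naive_single_prior_estimate(float(xi), float(yi), params)
                         for xi, yi in zip(x, y)])
    if session == "Expectation":
        return model.map_no_lift_batch(y, params)
    x = z_x * math.sqrt(params.sigma_x2)  # true log weight ratio is 0 in these designs
    return model.map_lift_batch(x, y, params, spec.arbitration)


def fit_observer(trials: pd.DataFrame, fit_spec: FitSpec) -> FitResult:
    """Grid/profile maximum-likelihood fit of a trial table.

    Accepts cohort tables from :func:`swimodel.simulate.simulate_cohort`
    (or any table with the same columns).  All subjects are pooled: the
    harness recovers the shared generating parameters.
    """
    t = _condition_table(trials)
    conditions = sorted(t["condition"].unique())
    vstars = {}
    base = fit_spec.base
    for c in conditions:
        session, pair = c.split("/")
        a, b = pair.split(":")
        vstars[c] = model.visual_log_volume_mean(VOLUMES_CM3[a], VOLUMES_CM3[b], base)
    ln_by_cond = {c: grp["ln_report"].to_numpy(float)
                  for c, grp in t.groupby("condition")}

    rng = np.random.default_rng(np.random.SeedSequence((fit_spec.seed, 271828)))
    z_y = {c: rng.standard_normal(fit_spec.n_draws) for c in conditions}
    z_x = {c: rng.standard_normal(fit_spec.n_draws) for c in conditions}

    def loglik(values: dict[str, float]) -> float:
        params, noise = _apply_candidate(base, values)
        noise_sd = fit_spec.report_noise_sd if math.isnan(noise) else noise
        total = 0.0
        for c in conditions:
            session = c.split("/")[0]
            w = _percepts_for(params, session, vstars[c], z_y[c], z_x[c], fit_spec)
            lnr = ln_by_cond[c]
            z = (lnr[:, None] - w[None, :]) / noise_sd
            log_terms = -0.5 * z * z - math.log(noise_sd) - 0.5 * math.log(2 * math.pi)
            m = log_terms.max(axis=1)
            total += float(np.sum(m + np.log(np.mean(np.exp(log_terms - m[:, None]), axis=1))))
        return total

    grids = {name: np.linspace(*fit_spec.range_of(name), fit_spec.n_grid)
             for name in fit_spec.free}
    best_vals: dict[str, float] = {}
    best_ll = -math.inf
    ll_table: dict[tuple, float] = {}
    for stage in range(fit_spec.n_stages):
        mesh = np.meshgrid(*[grids[n] for n in fit_spec.free], indexing="ij")
        flat = np.stack([m.ravel() for m in mesh], axis=-1)
        for row in flat:
            values = {n: float(v) for n, v in zip(fit_spec.free, row)}
            key = tuple(round(v, 10) for v in row)
            if key in ll_table:
                continue
            ll_table[key] = loglik(values)
            if ll_table[key] > best_ll:
                best_ll, best_vals = ll_table[key], values
        if stage + 1 < fit_spec.n_stages:
            new_grids = {}
            for n in fit_spec.free:
                g = grids[n]
                span = (g[-1] - g[0]) / (fit_spec.n_grid - 1)
                lo = max(fit_spec.range_of(n)[0], best_vals[n] - 1.5 * span)
                hi = min(fit_spec.range_of(n)[1], best_vals[n] + 1.5 * span)
                new_grids[n] = np.linspace(lo, hi, fit_spec.n_grid)
            grids = new_grids

    profiles = {}
    flat_params = []
    keys = np.array(sorted(ll_table))
    lls = np.array([ll_table[tuple(k)] for k in keys])
    for i, name in enumerate(fit_spec.free):
        df = (pd.DataFrame({name: keys[:, i], "log_likelihood": lls})
              .groupby(name, as_index=False)["log_likelihood"].max())
        profiles[name] = df
        if df["log_likelihood"].max() - df["log_likelihood"].min() < _FLAT_PROFILE_TOL:
            flat_params.append(name)

    return FitResult(estimates=best_vals, log_likelihood=best_ll,
                     profiles=profiles, non_identifiable=tuple(flat_params))
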