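"""Robustness sweeps: does the illusion survive parameter perturbations?

A sweep varies one model parameter over a list of values and evaluates,
for each of the six cube pairs, whether the deterministic lifting
percept at equal true weights stays positive (illusion present).  The
pseudo-parameter ``"rho"`` varies the magnitude of both correlations
jointly (rho2 = -rho, rho3 = +rho).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from . import model
from .params import ModelParams
from .stimuli import SIZE_PAIRS, VOLUMES_CM3

__all__ = ["SweepSpec", "run_sweep", "SWEEPABLE"]

SWEEPABLE = ("sigma_y2", "sigma_x2", "sigma_v2", "sigma_d2", "rho2", "rho3", "rho",
             "mu_d_R2", "volume_exponent")

_BOUNDS = {
    "sigma_y2": (0.0, None), "sigma_x2": (0.0, None),
    "sigma_v2": (0.0, None), "sigma_d2": (0.0, None),
    "rho2": (-1.0, 1.0), "rho3": (-1.0, 1.0), "rho": (0.0, 1.0),
    "mu_d_R2": (None, None), "volume_exponent": (0.0, None),
}


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep over the six cube pairs."""

    parameter: str
    values: tuple[float, ...]
    pairs: tuple[str, ...] = tuple(f"{a}:{b}" for a, b in SIZE_PAIRS)

    def __post_init__(self) -> None:
        if self.parameter not in SWEEPABLE:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; one of {SWEEPABLE}"
            )
        if not self.values:
            raise ValueError("sweep needs at least one value")


def _apply(base: ModelParams, name: str, value: float) -> ModelParams:
    if name == "rho":
        return replace(base, rho2=-value, rho3=value)
    return replace(base, **{name: value})


def run_sweep(
    spec: SweepSpec,
    base_params: ModelParams | None = None,
    arbitration: model.Arbitration = "likelihood",
) -> pd.DataFrame:
    """Boolean illusion table plus percept magnitudes per (value, pair).

    Out-of-bounds values are flagged per cell (``error`` column) and the
    sweep continues.
    """
    base = base_params or ModelParams()
    lo, hi = _BOUNDS[spec.parameter]
    rows = []
    for val in spec.values:
        out_of_bounds = (lo is not None and val < lo) or (hi is not None and val > hi)
        for pair in spec.pairs:
            row = {"parameter": spec.parameter, "value": float(val), "pair": pair}
            if out_of_bounds:
                row |= {"map_lift": float("nan"), "illusion": False,
                        "error": "value out of physical bounds"}
            else:
                try:
                    p = _apply(base, spec.parameter, float(val))
                    a, b = pair.split(":")
                    vstar = model.visual_log_volume_mean(VOLUMES_CM3[a], VOLUMES_CM3[b], p)
                    w = model.map_lift(0.0, vstar, p, arbitration)
                    row |= {"map_lift": w, "illusion": bool(w > 0), "error": ""}
                except (ValueError, FloatingPointError) as exc:
                    row |= {"map_lift": float("nan"), "illusion": False, "error": str(exc)}
            rows.append(row)
    return pd.DataFrame(rows)
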