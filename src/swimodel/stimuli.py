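"""Cube stimulus set, pair designs, and model prediction tables.

Four cube sizes (5.08, 7.62, 10.16 and 15.24 cm on a side; volumes
131.10, 442.45, 1048.77 and 3539.61 cm³, labelled A–D) in three weight
classes (Light 150 g, Medium 350 g, Heavy 550 g).  Within a weight class
all cubes weigh the same, so the true log weight ratio of any test pair
is 0 and any felt difference is illusory.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from . import model
from .params import ModelParams

__all__ = [
    "CubeSpec",
    "PairCondition",
    "SIZE_LABELS",
    "WEIGHT_CLASSES",
    "VOLUMES_CM3",
    "SIDES_CM",
    "MASSES_G",
    "SIZE_PAIRS",
    "build_cube_sets",
    "enumerate_pairs",
    "pair_volume_ratio",
    "predict_pair",
    "prediction_table",
]

SIZE_LABELS = ("A", "B", "C", "D")
WEIGHT_CLASSES = ("L", "M", "H")
#: printed volumes (kept verbatim rather than recomputed from the sides,
#: which match to well under 0.5%)
VOLUMES_CM3 = {"A": 131.10, "B": 442.45, "C": 1048.77, "D": 3539.61}
SIDES_CM = {"A": 5.08, "B": 7.62, "C": 10.16, "D": 15.24}
MASSES_G = {"L": 150.0, "M": 350.0, "H": 550.0}

#: the six size pairs in canonical (smaller, larger) order
SIZE_PAIRS = (("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D"))

Ordering = Literal["S-B", "B-S", "I-S"]
Session = Literal["Expectation", "Lifting"]


@dataclass(frozen=True)
class CubeSpec:
    """One physical cube: size label, weight class, geometry and mass."""

    label: str
    weight_class: str
    side_cm: float
    volume_cm3: float
    mass_g: float

    def __post_init__(self) -> None:
        if abs(self.side_cm ** 3 - self.volume_cm3) / self.volume_cm3 > 0.005:
            raise ValueError(
                f"volume {self.volume_cm3} inconsistent with side {self.side_cm} (>0.5%)"
            )
        if self.mass_g not in MASSES_G.values():
            raise ValueError(f"mass must be one of {sorted(MASSES_G.values())}, got {self.mass_g}")


@dataclass(frozen=True)
class PairCondition:
    """One presented pair: left and right cubes plus session metadata."""

    left: CubeSpec
    right: CubeSpec
    ordering: Ordering
    session: Session

    def __post_init__(self) -> None:
        if self.ordering == "I-S":
            if self.session != "Expectation":
                raise ValueError("identical-size pairs occur only in Expectation sessions")
            if self.left.label != self.right.label:
                raise ValueError("I-S ordering requires identical sizes")
        if self.session == "Lifting" and self.left.weight_class != self.right.weight_class:
            raise ValueError("Lifting pairs always share a weight class")

    @property
    def pair_id(self) -> str:
        """Canonical pair name, smaller cube first (e.g. 'A:D')."""
        a, b = sorted((self.left.label, self.right.label))
        return f"{a}:{b}"

    @property
    def smaller_label(self) -> str:
        return min(self.left.label, self.right.label)

    def canonical_log_ratios(self, params: ModelParams) -> tuple[float, float]:
        """(v*, true w) in the canonical smaller/larger convention."""
        a, b = sorted((self.left.label, self.right.label))
        if a == b:
            return 0.0, 0.0
        vstar = model.visual_log_volume_mean(VOLUMES_CM3[a], VOLUMES_CM3[b], params)
        w_true = math.log(self.left.mass_g / self.right.mass_g)
        # same weight class in all designs used here -> 0; keep general:
        if self.left.label != a:
            w_true = -w_true
        return vstar, w_true


def build_cube_sets() -> list[CubeSpec]:
    """All 12 cubes: 4 sizes x 3 weight classes."""
    return [
        CubeSpec(label=s, weight_class=wc, side_cm=SIDES_CM[s],
                 volume_cm3=VOLUMES_CM3[s], mass_g=MASSES_G[wc])
        for wc in WEIGHT_CLASSES
        for s in SIZE_LABELS
    ]


def _cube(label: str, wc: str) -> CubeSpec:
    return CubeSpec(label=label, weight_class=wc, side_cm=SIDES_CM[label],
                    volume_cm3=VOLUMES_CM3[label], mass_g=MASSES_G[wc])


def enumerate_pairs(session: Session) -> list[PairCondition]:
    """Full factorial trial list for one session.

    Lifting: 12 ordered size pairs x 3 weight classes x 4 repeats = 144.
    Expectation: 12 ordered pairs x 8 + 4 identical-size pairs x 8 = 128
    (weight class is immaterial without lifting; the Medium set is used).
    """
    trials: list[PairCondition] = []
    if session == "Lifting":
        for wc in WEIGHT_CLASSES:
            for a, b in SIZE_PAIRS:
                for left, right, ordering in ((a, b, "S-B"), (b, a, "B-S")):
                    for _ in range(4):
                        trials.append(PairCondition(_cube(left, wc), _cube(right, wc),
                                                    ordering, "Lifting"))
    elif session == "Expectation":
        for a, b in SIZE_PAIRS:
            for left, right, ordering in ((a, b, "S-B"), (b, a, "B-S")):
                for _ in range(8):
                    trials.append(PairCondition(_cube(left, "M"), _cube(right, "M"),
                                                ordering, "Expectation"))
        for s in SIZE_LABELS:
            for _ in range(8):
                trials.append(PairCondition(_cube(s, "M"), _cube(s, "M"), "I-S", "Expectation"))
    else:
        raise ValueError(f"unknown session: {session!r}")
    return trials


def pair_volume_ratio(pair_id: str) -> float:
    """Large/small volume ratio of a canonical pair id like 'A:D'."""
    a, b = pair_id.split(":")
    return VOLUMES_CM3[b] / VOLUMES_CM3[a]


def predict_pair(
    pair: PairCondition,
    params: ModelParams,
    mode: Literal["deterministic", "stochastic"] = "deterministic",
    rng: np.random.Generator | None = None,
    arbitration: model.Arbitration = "likelihood",
) -> dict[str, float]:
    """Model prediction for one presented pair.

    Deterministic mode evaluates the percept at the noiseless sensory
    means (y = v*, x = true log weight ratio); stochastic mode samples
    both measurements.  Returns the canonical log percept and its ratio
    form, plus the value mapped to the presentation order.
    """
    vstar, w_true = pair.canonical_log_ratios(params)
    if mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        y = rng.normal(vstar, math.sqrt(params.sigma_y2))
        x = rng.normal(w_true, math.sqrt(params.sigma_x2))
    elif mode == "deterministic":
        y, x = vstar, w_true
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    if pair.session == "Expectation":
        w_map = model.map_no_lift(y, params)
    else:
        w_map = model.map_lift(x, y, params, arbitration)

    # map canonical (smaller/larger) percept to the presented right/left ratio
    sign = 0.0 if pair.ordering == "I-S" else (1.0 if pair.right.label == pair.smaller_label else -1.0)
    w_presented = sign * w_map
    return {
        "v_star": vstar,
        "y": y,
        "x": x if pair.session == "Lifting" else float("nan"),
        "w_map_log": w_map,
        "w_map_ratio": math.exp(w_map),
        "w_presented_log": w_presented,
        "report_ratio_mean": math.exp(w_presented),
    }


def prediction_table(
    params: ModelParams | None = None,
    arbitration: model.Arbitration = "likelihood",
) -> pd.DataFrame:
    """Deterministic model predictions for every pair/session/weight class.

    One row per (pair, session, weight class); Expectation rows carry a
    single collapsed weight-class entry because the percept does not
    depend on absolute mass.  Columns follow the external CSV interface.
    """
    params = params or ModelParams()
    rows = []
    combos: list[tuple[str, str]] = [("Lifting", wc) for wc in WEIGHT_CLASSES]
    combos.append(("Expectation", "collapsed"))
    for session, wc in combos:
        for a, b in SIZE_PAIRS:
            use_wc = wc if wc != "collapsed" else "M"
            pair = PairCondition(_cube(a, use_wc), _cube(b, use_wc), "S-B", session)
            pred = predict_pair(pair, params, "deterministic", arbitration=arbitration)
            vstar = pred["v_star"]
            if session == "Lifting":
                post = model.arbitration_weights(0.0, vstar, params, arbitration)
                w_hat_means = [model.posterior_mean_w(vstar, 0.0, h, params)
                               for h in model._H]
            else:
                post = params.prior_R
                w_hat_means = [model.posterior_mean_w(vstar, None, h, params)
                               for h in model._H]
            rows.append({
                "pair": f"{a}:{b}",
                "ordering": "S-B",
                "session": session,
                "weight_class": wc,
                "v_star": vstar,
                "p_R1": post[0],
                "p_R2": post[1],
                "p_R3": post[2],
                "w_map_log": pred["w_map_log"],
                "w_map_ratio": pred["w_map_ratio"],
                "w_mean_R1": w_hat_means[0],
                "w_mean_R2": w_hat_means[1],
                "w_mean_R3": w_hat_means[2],
            })
    return pd.DataFrame(rows)


def prediction_table_csv(params: ModelParams | None = None) -> str:
    """Byte-stable CSV rendering of :func:`prediction_table`."""
    df = prediction_table(params)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.6f", lineterminator="\n")
    return buf.getvalue()
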