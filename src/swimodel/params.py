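"""Model parameters and elementary belief containers.

All quantities live in log-ratio space: for two objects A and B (A the
smaller one in the canonical convention), ``v = ln(V_A/V_B)``,
``d = ln(d_A/d_B)`` and ``w = ln(w_A/w_B)``, with the deterministic
constraint ``w = v + d``.  Variances are therefore dimensionless.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "DensityHypothesis",
    "ModelParams",
    "GaussianBelief",
    "PosteriorMixture",
    "PARAM_KEYS",
]

#: Flat configuration keys, in canonical order (external interface).
PARAM_KEYS = (
    "sigma_y2",
    "sigma_x2",
    "sigma_v2",
    "sigma_d2",
    "rho2",
    "rho3",
    "prior_R1",
    "prior_R2",
    "prior_R3",
    "volume_exponent",
    "mu_d_R2",
)

_PRIOR_TOL = 1e-12


class DensityHypothesis(enum.Enum):
    """Categorical hypothesis about two objects' relative densities.

    With A the smaller object: R1 — equal density; R2 — the smaller
    object is denser; R3 — the larger object is denser.
    """

    R1 = 1
    R2 = 2
    R3 = 3

    @property
    def index(self) -> int:
        return self.value - 1

    @property
    def swapped(self) -> "DensityHypothesis":
        """Role of this hypothesis after exchanging objects A and B."""
        if self is DensityHypothesis.R1:
            return DensityHypothesis.R1
        return DensityHypothesis.R3 if self is DensityHypothesis.R2 else DensityHypothesis.R2


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the competitive-prior observer.

    Parameters
    ----------
    sigma_y2
        Visual measurement variance of the log volume ratio.
    sigma_x2
        Haptic measurement variance of the log weight ratio.  The
        Expectation (no-lift) condition is expressed by *omitting* the
        haptic observation in the relevant operations, not by making
        this infinite.
    sigma_v2
        Prior variance of the log volume ratio ``v``.
    sigma_d2
        Prior variance of the log density ratio ``d`` under R2 and R3
        (under R1, ``sigma_d`` is identically zero).
    rho2, rho3
        Prior correlation between ``v`` and ``d`` under R2 (negative:
        smaller objects denser) and R3 (positive).
    prior_R
        A-priori probabilities of the three hypotheses, summing to 1.
    volume_exponent
        Power-law compression of visual volume estimates (0.704).
    mu_d_R2
        Mean offset of ``d`` under R2; zero by default, raised to
        ln 10 … ln 100 to emulate inverted-density training.
    """

    sigma_y2: float = 0.10
    sigma_x2: float = 0.50
    sigma_v2: float = 0.85
    sigma_d2: float = 1.2
    rho2: float = -0.95
    rho3: float = 0.95
    prior_R: tuple[float, float, float] = (0.8, 0.15, 0.05)
    volume_exponent: float = 0.704
    mu_d_R2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_y2", "sigma_x2", "sigma_v2", "sigma_d2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.sigma_v2 == 0:
            raise ValueError("sigma_v2 must be positive")
        for name in ("rho2", "rho3"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {getattr(self, name)}")
        if len(self.prior_R) != 3:
            raise ValueError("prior_R must have exactly three entries")
        if any(p < 0 for p in self.prior_R):
            raise ValueError(f"prior_R entries must be >= 0, got {self.prior_R}")
        if abs(sum(self.prior_R) - 1.0) > _PRIOR_TOL:
            raise ValueError(f"prior_R must sum to 1 within {_PRIOR_TOL}, got {sum(self.prior_R)}")

    # -- hypothesis-level accessors -------------------------------------
    def rho(self, h: DensityHypothesis) -> float:
        return {DensityHypothesis.R1: 0.0, DensityHypothesis.R2: self.rho2,
                DensityHypothesis.R3: self.rho3}[h]

    def sigma_d2_of(self, h: DensityHypothesis) -> float:
        """sigma_d² under hypothesis ``h`` (0 for R1)."""
        return 0.0 if h is DensityHypothesis.R1 else self.sigma_d2

    def mu_d(self, h: DensityHypothesis) -> float:
        return self.mu_d_R2 if h is DensityHypothesis.R2 else 0.0

    def swapped(self) -> "ModelParams":
        """Parameters after relabelling the objects (A<->B).

        R2 and R3 exchange roles; the R2 mean offset changes sign and
        moves with its hypothesis.
        """
        if self.mu_d_R2 != 0:
            # the swapped model would need the offset on R3, which
            # ModelParams does not represent
            raise ValueError("object swap is only defined for mu_d_R2 == 0")
        return replace(
            self,
            rho2=self.rho3,
            rho3=self.rho2,
            prior_R=(self.prior_R[0], self.prior_R[2], self.prior_R[1]),
        )

    # -- flat-dict external interface -----------------------------------
    def to_dict(self) -> dict[str, float]:
        return {
            "sigma_y2": self.sigma_y2,
            "sigma_x2": self.sigma_x2,
            "sigma_v2": self.sigma_v2,
            "sigma_d2": self.sigma_d2,
            "rho2": self.rho2,
            "rho3": self.rho3,
            "prior_R1": self.prior_R[0],
            "prior_R2": self.prior_R[1],
            "prior_R3": self.prior_R[2],
            "volume_exponent": self.volume_exponent,
            "mu_d_R2": self.mu_d_R2,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ModelParams":
        unknown = set(data) - set(PARAM_KEYS)
        if unknown:
            raise KeyError(f"unknown parameter key(s): {sorted(unknown)}")
        base = cls().to_dict()
        base.update(data)
        return cls(
            sigma_y2=float(base["sigma_y2"]),
            sigma_x2=float(base["sigma_x2"]),
            sigma_v2=float(base["sigma_v2"]),
            sigma_d2=float(base["sigma_d2"]),
            rho2=float(base["rho2"]),
            rho3=float(base["rho3"]),
            prior_R=(float(base["prior_R1"]), float(base["prior_R2"]), float(base["prior_R3"])),
            volume_exponent=float(base["volume_exponent"]),
            mu_d_R2=float(base["mu_d_R2"]),
        )

    def with_prior_R2(self, p2: float) -> "ModelParams":
        """Set p(R2) to ``p2``, rescaling p(R1), p(R3) proportionally."""
        p1, _, p3 = self.prior_R
        rest = p1 + p3
        if rest <= 0:
            raise ValueError("cannot rescale: p(R1)+p(R3) is zero")
        scale = (1.0 - p2) / rest
        return replace(self, prior_R=(p1 * scale, p2, p3 * scale))


@dataclass(frozen=True)
class GaussianBelief:
    """A 1-D Gaussian belief over the log weight ratio, with a mixture weight."""

    mean: float
    variance: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"variance must be >= 0, got {self.variance}")
        if not 0.0 <= self.weight <= 1.0 + 1e-12:
            raise ValueError(f"weight must lie in [0, 1], got {self.weight}")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class PosteriorMixture:
    """Mixture posterior over w: one Gaussian per hypothesis plus arbitration weights."""

    components: tuple[GaussianBelief, GaussianBelief, GaussianBelief]
    hypothesis_posteriors: tuple[float, float, float] = field(default=(1 / 3, 1 / 3, 1 / 3))

    def __post_init__(self) -> None:
        s = sum(self.hypothesis_posteriors)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"hypothesis posteriors must sum to 1 within 1e-9, got {s}")

    def component(self, h: DensityHypothesis) -> GaussianBelief:
        return self.components[h.index]
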