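"""Synthetic observers: trial simulation, cohorts, and the two model experiments.

An observer is the competitive-prior model plus a log-normal report
stage: on each trial the sensory measurements are sampled, the MAP
percept is computed, and the verbal ratio report is
``exp(percept + eps)`` with ``eps ~ N(0, report_noise_sd^2)``.  The
default report noise (0.21) matches typical within-subject variability
of log ratio reports in this task.

Individual differences in density expectations are carried by
``mu_d_R2`` — how much denser the observer believes a smaller object to
be — optionally together with an elevated ``prior_R2``.  The Day-1
instruction of the individual-differences experiment ("the smaller one
is denser") is modelled as raising ``prior_R2`` for the Expectation
session only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import model
from .params import ModelParams
from .stimuli import PairCondition, enumerate_pairs

__all__ = [
    "ObserverProfile",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "inverted_training_curve",
    "individual_differences_experiment",
    "DEFAULT_REPORT_NOISE_SD",
    "INSTRUCTED_PRIOR_R2",
]

DEFAULT_REPORT_NOISE_SD = 0.21
#: Day-1 "smaller is denser" instruction, expressed as p(R2)
INSTRUCTED_PRIOR_R2 = 0.9

TRIAL_COLUMNS = [
    "subject_id", "session", "day", "pair", "ordering", "weight_class",
    "trial_index", "report_ratio",
]


@dataclass(frozen=True)
class ObserverProfile:
    """One simulated observer.

    ``density_asymmetry`` is the observer's ``mu_d_R2`` (log units; 0 =
    textbook everyday expectations, ln 2 ≈ believes a smaller object
    twice as dense).  It is applied on top of ``params``.
    """

    params: ModelParams = field(default_factory=ModelParams)
    report_noise_sd: float = DEFAULT_REPORT_NOISE_SD
    density_asymmetry: float = 0.0
    arbitration: model.Arbitration = "likelihood"

    def __post_init__(self) -> None:
        if self.report_noise_sd < 0:
            raise ValueError("report_noise_sd must be >= 0")

    def effective_params(self, session: str, instructed: bool = False) -> ModelParams:
        p = replace(self.params, mu_d_R2=self.params.mu_d_R2 + self.density_asymmetry)
        if instructed and session == "Expectation":
            p = p.with_prior_R2(INSTRUCTED_PRIOR_R2)
        return p


def simulate_trial(
    pair: PairCondition,
    profile: ObserverProfile,
    rng: np.random.Generator,
    mode: Literal["deterministic", "stochastic"] = "deterministic",
    instructed: bool = False,
) -> float:
    """Simulate one ratio report (right cube relative to left).

    Returns the dimensionless report ratio (> 0); multiply by 10 for the
    experimental 10-unit response scale.
    """
    p = profile.effective_params(pair.session, instructed)
    vstar, w_true = pair.canonical_log_ratios(p)
    if mode == "stochastic":
        y = rng.normal(vstar, math.sqrt(p.sigma_y2))
        x = rng.normal(w_true, math.sqrt(p.sigma_x2))
    else:
        y, x = vstar, w_true
    if pair.session == "Expectation":
        w_map = model.map_no_lift(y, p)
    else:
        w_map = model.map_lift(x, y, p, profile.arbitration)
    sign = 0.0 if pair.ordering == "I-S" else (1.0 if pair.right.label == pair.smaller_label else -1.0)
    eps = rng.normal(0.0, profile.report_noise_sd) if profile.report_noise_sd > 0 else 0.0
    return math.exp(sign * w_map + eps)


def _session_frame(
    trials: Sequence[PairCondition],
    profile: ObserverProfile,
    rng: np.random.Generator,
    subject_id: int,
    day: int,
    mode: str,
    instructed: bool,
) -> pd.DataFrame:
    """Vectorized session simulation (batched percepts)."""
    session = trials[0].session
    p = profile.effective_params(session, instructed)
    n = len(trials)
    vstar = np.empty(n)
    w_true = np.empty(n)
    sign = np.empty(n)
    for i, t in enumerate(trials):
        vstar[i], w_true[i] = t.canonical_log_ratios(p)
        sign[i] = 0.0 if t.ordering == "I-S" else (1.0 if t.right.label == t.smaller_label else -1.0)
    if mode == "stochastic":
        y = rng.normal(vstar, math.sqrt(p.sigma_y2))
        x = rng.normal(w_true, math.sqrt(p.sigma_x2))
    else:
        y, x = vstar, w_true
    if session == "Expectation":
        w_map = model.map_no_lift_batch(y, p)
    else:
        w_map = model.map_lift_batch(x, y, p, profile.arbitration)
    eps = (rng.normal(0.0, profile.report_noise_sd, size=n)
           if profile.report_noise_sd > 0 else np.zeros(n))
    report = np.exp(sign * w_map + eps)
    return pd.DataFrame({
        "subject_id": subject_id,
        "session": session,
        "day": day,
        "pair": [t.pair_id for t in trials],
        "ordering": [t.ordering for t in trials],
        "weight_class": [t.left.weight_class for t in trials],
        "trial_index": np.arange(n),
        "report_ratio": report,
    })


def simulate_session(
    profile: ObserverProfile,
    session: str,
    rng: np.random.Generator,
    subject_id: int = 0,
    day: int = 1,
    mode: str = "deterministic",
    instructed: bool = False,
) -> pd.DataFrame:
    return _session_frame(enumerate_pairs(session), profile, rng, subject_id, day,
                          mode, instructed)


def _subject_rng(master_seed: int, subject_id: int) -> np.random.Generator:
    """Per-subject stream: reproducible under cohort resizing."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, subject_id)))


def simulate_cohort(
    n_subjects: int,
    profiles: ObserverProfile | Sequence[ObserverProfile],
    design: Iterable[str] = ("Expectation", "Lifting"),
    master_seed: int = 0,
    mode: str = "deterministic",
    instructed: bool = False,
) -> pd.DataFrame:
    """Two-session synthetic data set (Expectation Day 1, Lifting Day 2).

    ``profiles`` is a single shared profile or one per subject.
    Deterministic for a given master seed; per-subject streams are
    derived from ``(master_seed, subject_id)``.
    """
    if isinstance(profiles, ObserverProfile):
        profiles = [profiles] * n_subjects
    if len(profiles) != n_subjects:
        raise ValueError("need one profile per subject")
    frames = []
    for s in range(n_subjects):
        rng = _subject_rng(master_seed, s)
        for day, session in enumerate(design, start=1):
            frames.append(_session_frame(enumerate_pairs(session), profiles[s], rng,
                                         s, day, mode, instructed))
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def inverted_training_curve(
    offsets: Sequence[float],
    params: ModelParams | None = None,
    arbitration: model.Arbitration = "likelihood",
) -> pd.DataFrame:
    """Deterministic illusion magnitude per pair as training shifts R2.

    ``offsets`` are values of ``mu_d_R2``: 0 is the everyday prior;
    ln 10 and ln 100 emulate training with a smaller object 10x / 100x
    denser.  As the R2 expectation drifts away from the haptic evidence
    the equal-density and larger-denser hypotheses take over and the
    illusion attenuates, then reverses.
    """
    from .stimuli import SIZE_PAIRS, VOLUMES_CM3

    params = params or ModelParams()
    rows = []
    for off in offsets:
        p = replace(params, mu_d_R2=float(off))
        for a, b in SIZE_PAIRS:
            vstar = model.visual_log_volume_mean(VOLUMES_CM3[a], VOLUMES_CM3[b], p)
            rows.append({
                "mu_d_R2": float(off),
                "pair": f"{a}:{b}",
                "map_lift": model.map_lift(0.0, vstar, p, arbitration),
            })
    return pd.DataFrame(rows)


def sample_asymmetry_profiles(
    n_subjects: int,
    asymmetry_spread: float,
    rng: np.random.Generator,
    base: ObserverProfile | None = None,
) -> list[ObserverProfile]:
    """Observers with heterogeneous density-asymmetry beliefs.

    ``mu_d_R2 ~ Uniform(0, asymmetry_spread)``: beliefs range from "no
    asymmetry" to "smaller denser by exp(spread)".
    """
    base = base or ObserverProfile()
    mus = rng.uniform(0.0, asymmetry_spread, size=n_subjects)
    return [replace(base, density_asymmetry=float(m)) for m in mus]


#: default belief spread: from "no asymmetry" up to "twice as dense" —
#: the lower half of the everyday two-to-three-fold density asymmetry
#: that the R2 prior correlation itself encodes.  Stronger beliefs push
#: the closest pairs past the turning point where the R2 expectation
#: becomes too incongruent with the haptic evidence, outside the rising
#: regime that the expectation-illusion relationship concerns.
DEFAULT_ASYMMETRY_SPREAD = math.log(2.0)


def individual_differences_experiment(
    n_subjects: int = 30,
    asymmetry_spread: float = DEFAULT_ASYMMETRY_SPREAD,
    seed: int = 0,
    base: ObserverProfile | None = None,
) -> pd.DataFrame:
    """Simulated two-day experiment relating expectations to illusion size.

    Day 1: Expectation session under the "smaller is denser" instruction
    (elevated ``prior_R2``), giving Expected Weight (EW) reports.
    Day 2: Lifting session with the observer's unmodified profile,
    giving Perceived Weight (PW) reports.  Returns the per-pair Pearson
    correlation of subject-mean ln(EW) with ln(PW).
    """
    from .analysis import ew_pw_correlation, log_collapse

    if asymmetry_spread <= 0:
        raise ValueError(
            "asymmetry_spread must be > 0: identical observers make the "
            "EW-PW correlation undefined"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 987654321)))
    profiles = sample_asymmetry_profiles(n_subjects, asymmetry_spread, rng)
    frames = []
    for s, prof in enumerate(profiles):
        srng = _subject_rng(seed, s)
        frames.append(simulate_session(prof, "Expectation", srng, s, day=1,
                                       mode="stochastic", instructed=True))
        frames.append(simulate_session(prof, "Lifting", srng, s, day=2,
                                       mode="stochastic"))
    trials = pd.concat(frames, ignore_index=True)
    ew = log_collapse(trials[trials.session == "Expectation"], collapse_weight_class=True)
    pw = log_collapse(trials[trials.session == "Lifting"], collapse_weight_class=True)
    return ew_pw_correlation(ew, pw)
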