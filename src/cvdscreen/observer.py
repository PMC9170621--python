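"""Synthetic observers and cohort simulation.

An observer detects each displayed target independently with a
Weibull-style probability ``p = 1 - exp(-(s / sigma)**beta)`` (zero for
an infinite sigma), taps uniformly among the detected targets, and taps
uniformly among all 11 items when nothing is detected.  A lapse rate
models stimulus-independent errors - attention or motivation failures -
as a uniform tap over the 11 items, depressing performance on all axes
equally, which is exactly the non-visual factor the threshold-ratio
metric is designed to cancel.

Observer classes follow the congenital red-green CVD taxonomy: normal
trichromats (one sensitivity scale shared by all three axes), anomalous
trichromats (affected red-green axis strongly impaired, the neighboring
red-green axis moderately so - the two confusion lines are close in
color space), and dichromats (affected axis blind, neighbor strongly
impaired).  Tritan sensitivity is left intact for every red-green class;
congenital tritan deficiency is rare enough to neglect.

Parameter defaults are engineering choices for pipeline validation, not
estimates of human values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .colorimetry import Axis
from .config import EngineConfig
from .errors import NonterminatingSessionError
from .staircase import Session, apply_tap, init_session
from .stimulus import TrialStimulus, make_trial

__all__ = [
    "ObserverModel",
    "Participant",
    "SimulatedCohort",
    "DEFAULT_TYPE_MIX",
    "tap_choice",
    "run_session",
    "simulate_cohort",
    "simulate_groups",
    "expected_cvd_count",
    "lapse_invariance_check",
]

#: CVD type mix echoing the deutan predominance of congenital red-green CVD.
DEFAULT_TYPE_MIX = {
    "deuteranomalous": 0.50,
    "protanomalous": 0.25,
    "deuteranope": 0.15,
    "protanope": 0.10,
}

_CVD_KINDS = tuple(DEFAULT_TYPE_MIX)

#: Detection slope used for generated cohort observers.  Steep enough that
#: simulated psychometric functions rise sharply from the guessing floor to
#: saturation within about an octave, as the fitted example curves the
#: analysis is designed around do; shallower slopes leave the own-tap
#: probability hovering at the threshold level over a wide saturation band,
#: which makes the 0.21 crossing ill-defined for any estimator.
COHORT_DETECTION_SLOPE = 4.0


@dataclass(frozen=True)
class ObserverModel:
    """Parametric response model.

    ``sigma`` maps each axis to its sensitivity scale in saturation
    units (math.inf = blind to that axis); ``beta`` is the detection
    slope; ``lapse`` the stimulus-independent error rate.
    """

    kind: str = "normal"
    sigma: dict[Axis, float] = field(
        default_factory=lambda: {a: 0.05 for a in Axis}
    )
    beta: float = 2.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError(f"lapse must be in [0, 0.5), got {self.lapse}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        object.__setattr__(
            self, "sigma", {Axis(a): float(s) for a, s in self.sigma.items()}
        )
        # Congenital tritan deficiency is rare; the red-green classes this
        # package models never lose tritan discrimination entirely.
        if self.kind in ("normal", *_CVD_KINDS) and not math.isfinite(
            self.sigma[Axis.TRITAN]
        ):
            raise ValueError(
                f"tritan sigma must be finite for observer kind {self.kind!r}"
            )

    def detection_prob(self, axis: Axis, saturation: float) -> float:
        s = self.sigma[Axis(axis)]
        if math.isinf(s):
            return 0.0
        return 1.0 - math.exp(-((saturation / s) ** self.beta))


def tap_choice(
    trial: TrialStimulus, obs: ObserverModel, rng: np.random.Generator
) -> str:
    """Simulate one tap; returns the tapped item's role.

    With probability ``lapse`` an item is tapped uniformly at random.
    Otherwise each target is detected independently; one detected target
    is tapped uniformly, and if none is detected the tap falls uniformly
    on one of the 11 items (which may still be a target by chance).
    """
    items = trial.items
    if obs.lapse > 0.0 and rng.random() < obs.lapse:
        return items[rng.integers(len(items))].role
    detected = []
    for it in sorted(trial.targets(), key=lambda t: t.role):
        if rng.random() < obs.detection_prob(Axis(it.role), it.saturation):
            detected.append(it.role)
    if detected:
        return detected[rng.integers(len(detected))] if len(detected) > 1 else detected[0]
    return items[rng.integers(len(items))].role


def run_session(
    obs: ObserverModel,
    seed: int | None,
    config: EngineConfig | None = None,
    profile=None,
) -> Session:
    """Drive a full two-set session with a simulated observer.

    Deterministic given the seed: trial noise and tap choices share one
    generator, so identical seeds replay identical sessions.
    """
    config = config or EngineConfig()
    rng = np.random.default_rng(seed)
    session = init_session(seed=seed, config=config)
    noise = config.noise()
    while not session.complete:
        trial = make_trial(session.active_saturations(), noise, rng, profile=profile)
        apply_tap(session, tap_choice(trial, obs, rng))
        if session.trial_count > config.max_trials:
            raise NonterminatingSessionError(
                f"session exceeded {config.max_trials} trials"
            )
    return session


def expected_cvd_count(n: int, prevalence: float = 0.08) -> int:
    """Expected number of CVD cases in a sample of n (rounded)."""
    return round(n * prevalence)


def _draw_observer(kind: str, rng: np.random.Generator) -> ObserverModel:
    """Draw one observer of the given class from the default parameter ranges.

    The base sensitivity scale is shared by all three axes (normal
    discrimination is comparably good along every confusion line);
    deficits multiply the affected axes.
    """
    base = rng.uniform(0.03, 0.08)
    lapse = rng.uniform(0.0, 0.1)
    sigma = {a: base for a in Axis}
    if kind == "normal":
        pass
    elif kind == "deuteranomalous":
        sigma[Axis.DEUTAN] = base * rng.uniform(5.0, 20.0)
        sigma[Axis.PROTAN] = base * rng.uniform(2.0, 6.0)
    elif kind == "protanomalous":
        sigma[Axis.PROTAN] = base * rng.uniform(5.0, 20.0)
        sigma[Axis.DEUTAN] = base * rng.uniform(2.0, 6.0)
    elif kind == "deuteranope":
        sigma[Axis.DEUTAN] = math.inf
        sigma[Axis.PROTAN] = base * rng.uniform(8.0, 30.0)
    elif kind == "protanope":
        sigma[Axis.PROTAN] = math.inf
        sigma[Axis.DEUTAN] = base * rng.uniform(8.0, 30.0)
    else:
        raise ValueError(f"unknown observer kind {kind!r}")
    return ObserverModel(
        kind=kind, sigma=sigma, beta=COHORT_DETECTION_SLOPE, lapse=lapse
    )


@dataclass(frozen=True)
class Participant:
    participant_id: str
    observer: ObserverModel
    truth: str                 # "CVD" or "normal" (simulation ground truth)
    ishihara_errors: int       # emulated reference-test error count
    session_seed: int


@dataclass(frozen=True)
class SimulatedCohort:
    participants: tuple[Participant, ...]
    prevalence: float
    seed: int | None

    def __iter__(self):
        return iter(self.participants)

    def __len__(self):
        return len(self.participants)


def _make_participant(idx: int, kind: str, rng: np.random.Generator) -> Participant:
    obs = _draw_observer(kind, rng)
    truth = "normal" if kind == "normal" else "CVD"
    # Reference-test emulation: normals make no errors; CVD observers at
    # least three (out of five test plates).
    errors = 0 if truth == "normal" else int(rng.integers(3, 6))
    return Participant(
        participant_id=f"sim-{idx:04d}",
        observer=obs,
        truth=truth,
        ishihara_errors=errors,
        session_seed=int(rng.integers(2**31)),
    )


def simulate_cohort(
    n: int,
    prevalence: float = 0.08,
    type_mix: dict[str, float] | None = None,
    seed: int | None = None,
) -> SimulatedCohort:
    """Cohort with CVD membership drawn at the given prevalence."""
    if n <= 0:
        raise ValueError("n must be positive")
    mix = type_mix or DEFAULT_TYPE_MIX
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("type mix must sum to 1")
    rng = np.random.default_rng(seed)
    kinds, probs = zip(*sorted(mix.items()))
    participants = []
    for i in range(n):
        if rng.random() < prevalence:
            kind = kinds[rng.choice(len(kinds), p=probs)]
        else:
            kind = "normal"
        participants.append(_make_participant(i, kind, rng))
    return SimulatedCohort(tuple(participants), prevalence, seed)


def simulate_groups(
    n_cvd: int,
    n_control: int,
    type_mix: dict[str, float] | None = None,
    seed: int | None = None,
) -> SimulatedCohort:
    """Case-control cohort with fixed group sizes (validation-style design)."""
    mix = type_mix or DEFAULT_TYPE_MIX
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("type mix must sum to 1")
    rng = np.random.default_rng(seed)
    kinds, probs = zip(*sorted(mix.items()))
    participants = []
    for i in range(n_cvd):
        kind = kinds[rng.choice(len(kinds), p=probs)]
        participants.append(_make_participant(i, kind, rng))
    for j in range(n_control):
        participants.append(_make_participant(n_cvd + j, "normal", rng))
    return SimulatedCohort(tuple(participants), n_cvd / (n_cvd + n_control), seed)


def lapse_invariance_check(
    obs: ObserverModel,
    lapse_values,
    seed: int | None = None,
    n_seeds: int = 10,
    config: EngineConfig | None = None,
):
    """Full-pipeline lapse-robustness report.

    Runs the simulate -> fit -> ratio pipeline for the same sensitivity
    profile at several lapse rates and ``n_seeds`` replicate sessions
    each, returning one row per (lapse, seed) with the threshold triple
    and ratio.  Supports the design claim that lapses move raw
    thresholds but leave the ratio comparatively stable.
    """
    from . import pipeline  # lazy: pipeline imports this module

    config = config or EngineConfig()
    for lv in lapse_values:
        if not 0.0 <= lv < 0.5:
            raise ValueError(f"lapse must be in [0, 0.5), got {lv}")
    ss = np.random.SeedSequence(seed)
    session_seeds = [int(s) for s in ss.generate_state(n_seeds) % 2**31]
    rows = []
    for lv in lapse_values:
        variant = replace(obs, lapse=float(lv))
        for s in session_seeds:
            session = run_session(variant, s, config)
            triple = pipeline.thresholds_from_session(session, config)
            from .classify import threshold_ratio

            rows.append(
                {
                    "lapse": float(lv),
                    "seed": s,
                    "t_protan": triple.protan.effective(),
                    "t_deutan": triple.deutan.effective(),
                    "t_tritan": triple.tritan.effective(),
                    "ratio": threshold_ratio(triple),
                }
            )
    return rows
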