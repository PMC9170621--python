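"""End-to-end harness: session -> thresholds -> ratio -> label -> metrics."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import (
    ConfusionResult,
    ThresholdTriple,
    classify,
    confusion_metrics,
    threshold_ratio,
)
from .colorimetry import Axis
from .config import EngineConfig
from .errors import UnfittableDataError
from .observer import Participant, SimulatedCohort, run_session
from .psychometric import FitParams, ThresholdEstimate, fit_modelfree, threshold_at
from .staircase import Session, pool_observations

__all__ = [
    "thresholds_from_session",
    "session_fits",
    "participant_result",
    "evaluate_cohort",
    "CohortEvaluation",
]


def _single_level_threshold(obs, level: float) -> ThresholdEstimate:
    """Fallback when an axis was only ever tested at one saturation.

    This happens for severely impaired axes whose staircase never left
    the ceiling.  The level itself tells the story: performance below
    the threshold level means the threshold lies beyond the tested range
    (unresolved at the 0.9 ceiling); performance above it means the
    threshold lies below the only tested level (floor).
    """
    (sat, k, n) = obs[0]
    if k / n < level:
        return ThresholdEstimate(0.9, "unresolved")
    return ThresholdEstimate(float(sat), "floor")


def session_fits(session: Session, params: FitParams | None = None) -> dict[Axis, object]:
    """Model-free fit per axis from a session's pooled observations."""
    params = params or session.config.fit_params()
    return {
        a: fit_modelfree(pool_observations(session, a), params, axis=a) for a in Axis
    }


def thresholds_from_session(
    session: Session, config: EngineConfig | None = None, params: FitParams | None = None
) -> ThresholdTriple:
    """Per-axis thresholds, with the single-level fallback applied."""
    config = config or session.config
    params = params or config.fit_params()
    estimates = {}
    for a in Axis:
        obs = pool_observations(session, a)
        try:
            fit = fit_modelfree(obs, params, axis=a)
            estimates[a] = threshold_at(fit, params.level)
        except UnfittableDataError:
            estimates[a] = _single_level_threshold(obs, params.level)
    return ThresholdTriple(estimates[Axis.PROTAN], estimates[Axis.DEUTAN], estimates[Axis.TRITAN])


def participant_result(
    p: Participant, config: EngineConfig | None = None, profile=None
) -> dict:
    """Simulate one participant's session and classify it."""
    config = config or EngineConfig()
    session = run_session(p.observer, p.session_seed, config, profile=profile)
    triple = thresholds_from_session(session, config)
    ratio = threshold_ratio(triple)
    return {
        "participant_id": p.participant_id,
        "truth": p.truth,
        "kind": p.observer.kind,
        "ishihara_errors": p.ishihara_errors,
        "t_protan": triple.protan.effective(),
        "t_deutan": triple.deutan.effective(),
        "t_tritan": triple.tritan.effective(),
        "flags": "/".join(
            t.flag for t in (triple.protan, triple.deutan, triple.tritan)
        ),
        "ratio": ratio,
        "label": classify(ratio, config.criterion),
        "n_trials": session.trial_count,
    }


@dataclass(frozen=True)
class CohortEvaluation:
    results: pd.DataFrame
    metrics: ConfusionResult


def evaluate_cohort(
    cohort: SimulatedCohort, config: EngineConfig | None = None, profile=None
) -> CohortEvaluation:
    """Run every participant through the full pipeline.

    Sensitivity/specificity are computed against the simulation ground
    truth (every simulated participant has a conclusive truth label).
    """
    config = config or EngineConfig()
    rows = [participant_result(p, config, profile=profile) for p in cohort]
    df = pd.DataFrame(rows)
    metrics = confusion_metrics(df["label"], df["truth"])
    return CohortEvaluation(df, metrics)
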