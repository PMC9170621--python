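"""Threshold-ratio metric, CVD classification, and diagnostic accuracy.

Raw discrimination thresholds confound a red-green deficit with
non-visual factors (attention, motivation) that depress performance on
every axis equally.  The ratio

    r = min(t_tritan / t_protan, t_tritan / t_deutan)

factors those out: it is invariant under a common scaling of all three
thresholds, and because congenital tritan deficiency is vanishingly
rare, a small r specifically indicates a red-green deficit.  An observer
is labelled CVD when r falls strictly below the criterion (default
0.59, the midpoint between the group extremes of a discovery cohort).

The reference test groups participants by error count: 0 errors ->
control, 1-2 -> inconclusive, >=3 -> CVD.  Sensitivity and specificity
are computed against the conclusive reference groups only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidCountError, InvalidThresholdError, UndefinedMetricError
from .psychometric import ThresholdEstimate

__all__ = [
    "ThresholdTriple",
    "RatioClassification",
    "ConfusionResult",
    "threshold_ratio",
    "classify",
    "derive_criterion",
    "ishihara_group",
    "confusion_metrics",
    "power_bootstrap",
]

CVD = "CVD"
NORMAL = "normal"
DEFAULT_CRITERION = 0.59
CEILING = 0.9


def _as_estimate(t) -> ThresholdEstimate:
    return t if isinstance(t, ThresholdEstimate) else ThresholdEstimate(float(t))


@dataclass(frozen=True)
class ThresholdTriple:
    """Per-axis thresholds; entries may carry ceiling/floor flags."""

    protan: ThresholdEstimate
    deutan: ThresholdEstimate
    tritan: ThresholdEstimate

    def __post_init__(self) -> None:
        for name in ("protan", "deutan", "tritan"):
            object.__setattr__(self, name, _as_estimate(getattr(self, name)))


@dataclass(frozen=True)
class RatioClassification:
    ratio: float
    criterion: float
    label: str


def threshold_ratio(t: ThresholdTriple, ceiling: float = CEILING) -> float:
    """min(tritan:protan, tritan:deutan) threshold ratio.

    Unresolved (ceiling-flagged) thresholds enter at the display ceiling
    0.9 - conservative and finite, and still far below the criterion
    whenever tritan performance is normal.
    """
    tp = t.protan.effective(ceiling)
    td = t.deutan.effective(ceiling)
    tt = t.tritan.effective(ceiling)
    if min(tp, td, tt) <= 0.0:
        raise InvalidThresholdError(f"thresholds must be positive, got {(tp, td, tt)}")
    return min(tt / tp, tt / td)


def classify(r: float, criterion: float = DEFAULT_CRITERION) -> str:
    """CVD iff the ratio is strictly below the criterion (tie -> normal)."""
    if r <= 0.0 or criterion <= 0.0:
        raise InvalidThresholdError("ratio and criterion must be positive")
    return CVD if r < criterion else NORMAL


def derive_criterion(cvd_ratios, control_ratios) -> float:
    """Midpoint between the CVD maximum and the control minimum ratio.

    Warns (and still returns the midpoint) when the groups overlap.
    """
    cvd_ratios, control_ratios = list(cvd_ratios), list(control_ratios)
    if not cvd_ratios or not control_ratios:
        raise ValueError("both ratio lists must be non-empty")
    hi_cvd, lo_ctrl = max(cvd_ratios), min(control_ratios)
    if hi_cvd >= lo_ctrl:
        warnings.warn(
            f"groups overlap: max CVD ratio {hi_cvd:.3g} >= min control ratio {lo_ctrl:.3g}",
            stacklevel=2,
        )
    return 0.5 * (hi_cvd + lo_ctrl)


def ishihara_group(errors: int) -> str:
    """Reference-test grouping: 0 -> control, 1-2 -> inconclusive, >=3 -> CVD."""
    if errors < 0:
        raise InvalidCountError(f"error count must be nonnegative, got {errors}")
    if errors == 0:
        return "control"
    if errors <= 2:
        return "inconclusive"
    return CVD


@dataclass(frozen=True)
class ConfusionResult:
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    n_inconclusive: int


def confusion_metrics(predicted, reference) -> ConfusionResult:
    """Sensitivity/specificity of predictions against conclusive references.

    ``reference`` entries equal to ``inconclusive`` are excluded (their
    count is reported).  Raises :class:`UndefinedMetricError` when the
    reference contains no positives (sensitivity) or no negatives
    (specificity).
    """
    predicted, reference = list(predicted), list(reference)
    if len(predicted) != len(reference):
        raise ValueError("predicted and reference must have equal length")
    tp = fp = tn = fn = inc = 0
    for pred, ref in zip(predicted, reference):
        if ref == "inconclusive":
            inc += 1
        elif ref == CVD:
            tp += pred == CVD
            fn += pred != CVD
        elif ref in (NORMAL, "control"):
            tn += pred != CVD
            fp += pred == CVD
        else:
            raise ValueError(f"unknown reference label {ref!r}")
    if tp + fn == 0:
        raise UndefinedMetricError("no positive references; sensitivity undefined")
    if tn + fp == 0:
        raise UndefinedMetricError("no negative references; specificity undefined")
    return ConfusionResult(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        tp=tp, fp=fp, tn=tn, fn=fn, n_inconclusive=inc,
    )


def power_bootstrap(
    n_cvd: int,
    n_control: int,
    true_sens: float,
    true_spec: float,
    half_range_sens: float,
    half_range_spec: float,
    reps: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Simulation-based power for the planned sample sizes.

    Each replicate draws binomial test outcomes at the true rates; power
    is the fraction of replicates whose estimated rate lies within the
    stated half-range of the truth.  This is an interpretation of a
    sample-size bootstrap in terms of estimate proximity, not a unique
    reconstruction of any particular study's procedure.
    """
    if n_cvd <= 0 or n_control <= 0:
        raise ValueError("sample sizes must be positive")
    for p in (true_sens, true_spec):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"rates must be in (0, 1], got {p}")
    rng = np.random.default_rng(seed)
    sens_hat = rng.binomial(n_cvd, true_sens, size=reps) / n_cvd
    spec_hat = rng.binomial(n_control, true_spec, size=reps) / n_control
    power_sens = float(np.mean(np.abs(sens_hat - true_sens) <= half_range_sens + 1e-12))
    power_spec = float(np.mean(np.abs(spec_hat - true_spec) <= half_range_spec + 1e-12))
    return power_sens, power_spec
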