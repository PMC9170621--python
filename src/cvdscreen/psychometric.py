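"""Model-free psychometric-function estimation and threshold extraction.

The performance curve is estimated by local-linear logistic regression:
at each evaluation point x0 on the log10-saturation axis, a degree-1
polynomial on the logit scale is fitted by maximizing the
Gaussian-kernel-weighted binomial log-likelihood

    sum_i  K((x_i - x0)/h) * [k_i log p_i + (n_i - k_i) log(1 - p_i)],
    logit(p_i) = a + b (x_i - x0),

and the fitted probability at x0 is expit(a).  The fit is performed on
log10(saturation) because the staircase levels are geometric (spacing
0.301 log units per halving), so the default bandwidth h = 0.70 smooths
over roughly two to three adjacent levels; on the raw scale it would
span the entire stimulus range.

The threshold at performance level pi (default 0.21, above the 1/11
chance rate of the 11-alternative task) is the largest grid saturation
where the fitted curve crosses pi from below.  Curves that never reach
pi are flagged ``unresolved`` and assigned the 0.9 display ceiling;
curves already above pi at the lowest tested level are flagged
``floor``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .colorimetry import Axis
from .errors import EmptyDataError, InvalidLevelError, UnfittableDataError

__all__ = [
    "FitParams",
    "PsychometricFit",
    "ThresholdEstimate",
    "fit_modelfree",
    "threshold_at",
    "optimize_fit_params",
    "separation_objective",
]

logger = logging.getLogger(__name__)

_P_CLAMP = 1e-6          # likelihood clamp for degenerate neighborhoods
_A_CAP = math.log((1 - _P_CLAMP) / _P_CLAMP)   # |intercept| at the clamp
_B_CAP = 300.0
_STEP_CAP = 4.0
_MAX_ITER = 200


@dataclass(frozen=True)
class FitParams:
    """Smoothing and threshold parameters.

    ``bandwidth``: Gaussian kernel bandwidth in log10-saturation units.
    ``level``: raw performance level defining the threshold.
    """

    bandwidth: float = 0.70
    level: float = 0.21
    link: str = "logit"
    grid_size: int = 201

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError(f"bandwidth must be positive, got {self.bandwidth}")
        if not 0.0 < self.level < 1.0:
            raise InvalidLevelError(f"level must be in (0, 1), got {self.level}")
        if self.link != "logit":
            raise ValueError(f"unsupported link {self.link!r}")


@dataclass(frozen=True)
class ThresholdEstimate:
    """Threshold saturation with a resolution flag.

    flag: ``ok`` (interpolated crossing), ``unresolved`` (curve never
    reaches the level; value is the display ceiling), or ``floor``
    (curve already above the level at the lowest tested saturation).
    """

    value: float
    flag: str = "ok"

    def effective(self, ceiling: float = 0.9) -> float:
        return ceiling if self.flag == "unresolved" else self.value


@dataclass(frozen=True)
class PsychometricFit:
    axis: Axis | None
    bandwidth: float
    grid: np.ndarray = field(repr=False)       # saturations
    log_grid: np.ndarray = field(repr=False)   # log10(saturations)
    p_hat: np.ndarray = field(repr=False)
    data: tuple[tuple[float, int, int], ...] = field(repr=False)

    def to_dict(self, level: float | None = None) -> dict:
        d = {
            "axis": self.axis.value if self.axis else None,
            "bandwidth": self.bandwidth,
            "grid": self.grid.tolist(),
            "p_hat": self.p_hat.tolist(),
        }
        if level is not None:
            t = threshold_at(self, level)
            d.update(level=level, threshold=t.value, flag=t.flag)
        return d


def _local_logistic(
    x: np.ndarray, k: np.ndarray, n: np.ndarray, grid_x: np.ndarray, h: float
) -> np.ndarray:
    """Fitted probabilities at every grid point (damped Newton, vectorized).

    The weighted binomial log-likelihood is concave in (a, b); Newton
    steps are capped in norm and the intercept is clamped so degenerate
    all-success / all-failure neighborhoods saturate at the clamp
    probabilities instead of diverging.
    """
    dx = x[None, :] - grid_x[:, None]                      # (G, m)
    w = np.exp(-0.5 * (dx / h) ** 2)
    p_bar = min(max(k.sum() / n.sum(), 1e-3), 1 - 1e-3)
    a = np.full(grid_x.shape, logit(p_bar))
    b = np.zeros_like(a)
    ridge = 1e-9
    for _ in range(_MAX_ITER):
        p = expit(a[:, None] + b[:, None] * dx)
        r = w * (k[None, :] - n[None, :] * p)
        u1 = r.sum(axis=1)
        u2 = (r * dx).sum(axis=1)
        v = w * n[None, :] * p * (1.0 - p)
        h11 = v.sum(axis=1) + ridge
        h12 = (v * dx).sum(axis=1)
        h22 = (v * dx * dx).sum(axis=1) + ridge
        det = h11 * h22 - h12 * h12
        da = (h22 * u1 - h12 * u2) / det
        db = (h11 * u2 - h12 * u1) / det
        norm = np.hypot(da, db)
        scale = np.minimum(1.0, _STEP_CAP / np.maximum(norm, 1e-300))
        a = np.clip(a + scale * da, -_A_CAP, _A_CAP)
        b = np.clip(b + scale * db, -_B_CAP, _B_CAP)
        if norm.max() < 1e-11:
            break
    return expit(a)


def fit_modelfree(
    data: Iterable[tuple[float, int, int]],
    params: FitParams | None = None,
    axis: Axis | None = None,
) -> PsychometricFit:
    """Fit the model-free psychometric curve to pooled observations.

    ``data`` rows are ``(saturation, successes, trials)``.  At least two
    distinct saturation levels with trials are required.  The evaluation
    grid is ``params.grid_size`` points evenly spaced in log10 saturation
    from the lowest tested level to 0.9 (or the highest tested level if
    larger).
    """
    params = params or FitParams()
    agg: dict[float, list[int]] = {}
    for sat, k, n in data:
        if n <= 0:
            continue
        if sat <= 0:
            raise ValueError(f"saturations must be positive, got {sat}")
        row = agg.setdefault(float(sat), [0, 0])
        row[0] += int(k)
        row[1] += int(n)
    if not agg:
        raise EmptyDataError("no observations with trials > 0")
    if len(agg) < 2:
        raise UnfittableDataError(
            f"need >= 2 distinct saturation levels, got {len(agg)}"
        )
    sats = np.array(sorted(agg))
    k = np.array([agg[s][0] for s in sats], dtype=float)
    n = np.array([agg[s][1] for s in sats], dtype=float)
    x = np.log10(sats)
    hi = math.log10(max(0.9, sats[-1]))
    log_grid = np.linspace(x[0], hi, params.grid_size)
    p_hat = _local_logistic(x, k, n, log_grid, params.bandwidth)
    return PsychometricFit(
        axis=axis,
        bandwidth=params.bandwidth,
        grid=10.0 ** log_grid,
        log_grid=log_grid,
        p_hat=p_hat,
        data=tuple((float(s), int(agg[s][0]), int(agg[s][1])) for s in sats),
    )


def threshold_at(fit: PsychometricFit, level: float) -> ThresholdEstimate:
    """Threshold saturation where the fitted curve crosses ``level``.

    Takes the largest upward crossing, linearly interpolated on the
    log10 grid.  See module docstring for the ``unresolved`` and
    ``floor`` flags.
    """
    if not 0.0 < level < 1.0:
        raise InvalidLevelError(f"level must be in (0, 1), got {level}")
    p = fit.p_hat
    xg = fit.log_grid
    below = p[:-1] < level
    above = p[1:] >= level
    idx = np.nonzero(below & above)[0]
    if idx.size:
        i = idx[-1]
        frac = (level - p[i]) / (p[i + 1] - p[i])
        return ThresholdEstimate(float(10.0 ** (xg[i] + frac * (xg[i + 1] - xg[i]))))
    if p.max() < level:
        return ThresholdEstimate(0.9, "unresolved")
    return ThresholdEstimate(float(fit.grid[0]), "floor")


def separation_objective(
    cvd_ratios: Sequence[float], control_ratios: Sequence[float]
) -> float:
    """Gap between the worst-separated members of the two groups."""
    return min(control_ratios) - max(cvd_ratios)


def optimize_fit_params(
    fit_fn: Callable[[object, float], Mapping[Axis, PsychometricFit]],
    cvd_ids: Sequence,
    control_ids: Sequence,
    bandwidth_grid: Sequence[float] | None = None,
    level_grid: Sequence[float] | None = None,
) -> FitParams:
    """Grid-search the (bandwidth, level) pair maximizing group separation.

    ``fit_fn(participant_id, bandwidth)`` must return per-axis fits for
    that participant.  For each candidate pair every participant's
    threshold ratio is computed and the objective is
    ``min(control ratios) - max(CVD ratios)``; the argmax pair is
    returned, ties broken toward smaller bandwidth then lower level.
    Participants unfittable at some bandwidth make every pair at that
    bandwidth score -inf (logged), they do not raise.
    """
    from .classify import threshold_ratio, ThresholdTriple  # avoid cycle

    if not cvd_ids or not control_ids:
        raise ValueError("both groups must be non-empty")
    if bandwidth_grid is None:
        bandwidth_grid = np.round(np.arange(0.10, 2.0001, 0.05), 10)
    if level_grid is None:
        level_grid = np.round(np.arange(0.05, 0.5001, 0.01), 10)

    best: tuple[float, float, float] | None = None  # (objective, h, level)
    for h in sorted(bandwidth_grid):
        fits: dict[object, Mapping[Axis, PsychometricFit]] = {}
        failed = False
        for pid in [*cvd_ids, *control_ids]:
            try:
                fits[pid] = fit_fn(pid, float(h))
            except (UnfittableDataError, EmptyDataError) as exc:
                logger.warning("participant %r unfittable at h=%.3g: %s", pid, h, exc)
                failed = True
                break
        for level in sorted(level_grid):
            if failed:
                obj = -math.inf
            else:
                ratios = {}
                for pid, axfits in fits.items():
                    triple = ThresholdTriple(
                        *(threshold_at(axfits[a], float(level)) for a in Axis)
                    )
                    ratios[pid] = threshold_ratio(triple)
                obj = separation_objective(
                    [ratios[p] for p in cvd_ids], [ratios[p] for p in control_ids]
                )
            if best is None or obj > best[0]:
                best = (obj, float(h), float(level))
    assert best is not None
    logger.info("optimal params h=%.3g level=%.3g (objective %.4g)", best[1], best[2], best[0])
    return FitParams(bandwidth=best[1], level=best[2])
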