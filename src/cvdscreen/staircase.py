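"""Three-axis adaptive session controller.

Each confusion axis runs its own staircase starting at saturation 0.9
(the greatest tested multiple of the maximum in-gamut saturation).
Tapping a target halves that axis's saturation; tapping a distractor
multiplies every active axis's saturation by 1.5, capped at 0.9.  Both
events count as an *update* for the staircases involved.  A staircase
that accumulates 35 updates within the current set deactivates - its
target is replaced by a distractor - and once all three are done the
second set begins with counts reset and saturations carried over.  The
session is complete when the second set's quotas are met.

For threshold fitting, every update event contributes one Bernoulli
observation at the saturation that axis presented on that trial: a
success if its own target was tapped, a failure if a distractor was
tapped.  Trials resolved by tapping a *different* axis's target say
nothing about this axis and contribute no observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .colorimetry import Axis
from .config import EngineConfig
from .errors import InsufficientDataError, ProtocolViolationError

__all__ = [
    "StaircaseState",
    "TrialRecord",
    "Session",
    "init_session",
    "apply_tap",
    "pool_observations",
]

DISTRACTOR = "distractor"


@dataclass
class StaircaseState:
    axis: Axis
    saturation: float
    update_count: int = 0
    set_index: int = 1
    active: bool = True


@dataclass
class TrialRecord:
    trial_index: int                 # 1-based, consecutive
    set_index: int
    saturations: dict[Axis, float]   # axes shown on this trial
    tapped: str                      # axis value or "distractor"


@dataclass
class Session:
    """Mutable session state doubling as the session record."""

    seed: int | None = None
    config: EngineConfig = field(default_factory=EngineConfig)
    staircases: dict[Axis, StaircaseState] = field(init=False)
    trials: list[TrialRecord] = field(default_factory=list)
    set_index: int = 1
    complete: bool = False

    def __post_init__(self) -> None:
        self.staircases = {
            a: StaircaseState(a, self.config.start_saturation) for a in Axis
        }

    def active_saturations(self) -> dict[Axis, float]:
        return {
            a: st.saturation for a, st in self.staircases.items() if st.active
        }

    @property
    def trial_count(self) -> int:
        return len(self.trials)

    @property
    def valid(self) -> bool:
        """Whether the session meets the minimum-trial validity floor."""
        return self.trial_count >= self.config.min_valid_trials


def init_session(seed: int | None = None, config: EngineConfig | None = None) -> Session:
    """Fresh session: all three staircases active at 0.9, set 1."""
    return Session(seed=seed, config=config or EngineConfig())


def apply_tap(session: Session, tapped: str) -> Session:
    """Record one trial outcome and advance the staircases in place."""
    if session.complete:
        raise ProtocolViolationError("tap applied to a completed session")
    cfg = session.config
    shown = session.active_saturations()
    if tapped != DISTRACTOR and not session.staircases[Axis(tapped)].active:
        raise ProtocolViolationError(f"tap on inactive axis {tapped!r}")
    session.trials.append(
        TrialRecord(session.trial_count + 1, session.set_index, dict(shown), str(tapped))
    )

    if tapped == DISTRACTOR:
        updated = [st for st in session.staircases.values() if st.active]
        for st in updated:
            st.saturation = min(st.saturation * cfg.gain_up, cfg.start_saturation)
    else:
        st = session.staircases[Axis(tapped)]
        st.saturation *= cfg.gain_down
        updated = [st]
    for st in updated:
        st.update_count += 1
        if st.update_count >= cfg.set_quota:
            st.active = False

    if all(st.update_count >= cfg.set_quota for st in session.staircases.values()):
        if session.set_index < cfg.n_sets:
            session.set_index += 1
            for st in session.staircases.values():
                st.update_count = 0
                st.set_index = session.set_index
                st.active = True  # saturations carry over between sets
        else:
            session.complete = True
    return session


def update_events(trial: TrialRecord) -> dict[Axis, bool]:
    """Axes updated by a trial, mapped to success (own target tapped)."""
    if trial.tapped == DISTRACTOR:
        return {a: False for a in trial.saturations}
    return {Axis(trial.tapped): True}


def pool_observations(
    session: Session, axis: Axis, min_trials: int | None = None
) -> list[tuple[float, int, int]]:
    """Bernoulli observations for one axis, pooled across both sets.

    Returns ``(saturation, successes, trials)`` rows aggregated per
    distinct saturation level.  Sessions below the validity floor
    (default: the config's ``min_valid_trials``) are refused.
    """
    axis = Axis(axis)
    floor = session.config.min_valid_trials if min_trials is None else min_trials
    if session.trial_count < floor:
        raise InsufficientDataError(
            f"session has {session.trial_count} trials; minimum is {floor}"
        )
    counts: dict[float, list[int]] = {}
    for tr in session.trials:
        events = update_events(tr)
        if axis not in events:
            continue
        sat = tr.saturations[axis]
        row = counts.setdefault(sat, [0, 0])
        row[0] += int(events[axis])
        row[1] += 1
    return sorted((sat, k, n) for sat, (k, n) in counts.items())
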