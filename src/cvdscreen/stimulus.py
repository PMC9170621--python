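"""Trial assembly: confusion-line targets, distractors, and masking noise.

A trial shows 11 items: one target per active confusion axis plus enough
achromatic distractors to fill the display (an inactive axis contributes
an extra distractor).  Two noise sources mask residual cues available to
observers whose spectral sensitivities differ from the calibration
assumptions:

* item luminance is drawn uniformly from +-20% of the background
  luminance, swamping the <=~10% luminance contrast a dichromat can
  extract from the red-green targets;
* each item's s coordinate is shifted by a binary +-16% of the
  background s, swamping the ~8% tritan leakage expected from
  individual differences in cone fundamentals or calibration error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .colorimetry import (
    Axis,
    ChromaticityMB,
    DeviceProfile,
    cones_from_mb,
    dichromat_luminance_signal,
    target_chromaticity,
)
from .errors import SaturationOverflowError

__all__ = ["NoiseConfig", "TrialItem", "TrialStimulus", "make_trial", "dichromat_visible_cue"]

N_ITEMS = 11
_AXIS_ORDER = (Axis.PROTAN, Axis.DEUTAN, Axis.TRITAN)
_GAMUT_TOL = 1e-9
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class NoiseConfig:
    """Masking-noise amplitudes.

    ``lum_half_range``: half-width of the uniform luminance noise as a
    fraction of the background luminance (default 0.20).
    ``tritan_amplitude``: magnitude of the binary s shift as a fraction
    of the background s (default 0.16).
    """

    lum_half_range: float = 0.20
    tritan_amplitude: float = 0.16

    def __post_init__(self) -> None:
        for name in ("lum_half_range", "tritan_amplitude"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class TrialItem:
    role: str                    # axis value or "distractor"
    saturation: float | None     # None for distractors
    chromaticity: ChromaticityMB  # nominal (pre-noise)
    lum_factor: float            # multiple of the background luminance
    tritan_sign: int             # +-1
    position: int                # display slot 0..10
    clipped: bool = False        # noise pushed the item out of gamut


@dataclass
class TrialStimulus:
    items: list[TrialItem]
    target_saturations: dict[Axis, float] = field(default_factory=dict)

    def targets(self) -> list[TrialItem]:
        return [it for it in self.items if it.role != "distractor"]


def _effective_chromaticity(
    nominal: ChromaticityMB, lum_factor: float, sign: int, cfg: NoiseConfig, white: ChromaticityMB
) -> ChromaticityMB:
    s = max(nominal.s + sign * cfg.tritan_amplitude * white.s, 0.0)
    return ChromaticityMB(nominal.l, s, white.lum * lum_factor)


def _in_gamut(chrom: ChromaticityMB, profile: DeviceProfile) -> bool:
    linear = profile.lms_to_rgb @ cones_from_mb(chrom).as_array()
    return bool(np.all(linear >= -_GAMUT_TOL) and np.all(linear <= 1.0 + _GAMUT_TOL))


def make_trial(
    saturations: dict[Axis, float],
    cfg: NoiseConfig,
    rng: np.random.Generator,
    profile: DeviceProfile | None = None,
    active: dict[Axis, bool] | None = None,
) -> TrialStimulus:
    """Assemble one 11-item trial.

    ``saturations`` maps each active axis to its current staircase
    saturation in (0, 0.9]; axes that are absent (or flagged inactive in
    ``active``) are replaced by distractors.  Luminance factors are drawn
    uniformly from ``[1 - r, 1 + r]``; each item independently receives an
    equiprobable binary s shift; positions are a uniform random
    permutation of the 11 slots.  Noise draws that leave the device gamut
    are redrawn up to 100 times, then clipped with a warning.
    """
    if profile is None:
        profile = DeviceProfile.default()
    shown = {
        Axis(a): s
        for a, s in saturations.items()
        if active is None or active.get(Axis(a), True)
    }
    for a, s in shown.items():
        if s > 0.9:
            raise SaturationOverflowError(f"{a.value} saturation {s} above ceiling 0.9")
        if s <= 0.0:
            raise ValueError(f"{a.value} saturation must be positive, got {s}")

    white = profile.white
    roles: list[tuple[str, float | None, ChromaticityMB]] = []
    for a in _AXIS_ORDER:
        if a in shown:
            roles.append((a.value, shown[a], target_chromaticity(a, shown[a], profile)))
    while len(roles) < N_ITEMS:
        roles.append(("distractor", None, white))

    positions = rng.permutation(N_ITEMS)
    items: list[TrialItem] = []
    for idx, (role, sat, chrom) in enumerate(roles):
        lum_f = 0.0
        sign = 0
        clipped = False
        for attempt in range(_MAX_REDRAWS):
            lum_f = rng.uniform(1.0 - cfg.lum_half_range, 1.0 + cfg.lum_half_range)
            sign = 1 if rng.random() < 0.5 else -1
            if _in_gamut(_effective_chromaticity(chrom, lum_f, sign, cfg, white), profile):
                break
        else:
            clipped = True
            warnings.warn(
                f"item {role!r} out of gamut after {_MAX_REDRAWS} redraws; clipping",
                stacklevel=2,
            )
        items.append(
            TrialItem(role, sat, chrom, lum_f, sign, int(positions[idx]), clipped)
        )
    return TrialStimulus(items, dict(shown))


def dichromat_visible_cue(
    trial: TrialStimulus, observer_type: str, profile: DeviceProfile | None = None
) -> list[dict]:
    """Per-item residual cue summary for a dichromat.

    For each item: the chromatic luminance signal its nominal
    chromaticity carries for the given dichromat type, the luminance
    noise factor, and the total relative luminance the item presents
    (``(1 + chromatic) * lum_factor - 1``).  Targets are only detectable
    to the dichromat if their total cue escapes the noise band.
    """
    if profile is None:
        profile = DeviceProfile.default()
    rows = []
    for it in trial.items:
        if it.role == "distractor" or it.role == Axis.TRITAN.value:
            chromatic = 0.0
        else:
            chromatic = dichromat_luminance_signal(
                Axis(it.role), it.saturation, profile, observer_type
            )
        rows.append(
            {
                "role": it.role,
                "chromatic_cue": chromatic,
                "lum_factor": it.lum_factor,
                "total_cue": (1.0 + chromatic) * it.lum_factor - 1.0,
            }
        )
    return rows
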