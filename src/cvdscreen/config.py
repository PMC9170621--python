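"""Engine configuration: every protocol constant, overridable, serializable."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields

from .psychometric import FitParams
from .stimulus import NoiseConfig

__all__ = ["EngineConfig", "ENGINE_VERSION"]

ENGINE_VERSION = "0.1.0"


@dataclass(frozen=True)
class EngineConfig:
    """Protocol defaults.

    Staircase: start at saturation 0.9, halve on a target tap, multiply
    by 1.5 (capped at 0.9) on a distractor tap, 35 updates per staircase
    per set, two sets, 40-trial validity floor.  Display: 11 items (3
    targets + 8 distractors).  Noise: +-20% luminance, +-16% binary
    tritan.  Fitting: bandwidth 0.70 (log10 units), threshold level 0.21.
    Classification: ratio criterion 0.59.  Population: 8% CVD prevalence
    among males.
    """

    start_saturation: float = 0.9
    gain_down: float = 0.5
    gain_up: float = 1.5
    set_quota: int = 35
    n_sets: int = 2
    min_valid_trials: int = 40
    n_distractors: int = 8
    lum_half_range: float = 0.20
    tritan_amplitude: float = 0.16
    bandwidth: float = 0.70
    level: float = 0.21
    criterion: float = 0.59
    prevalence: float = 0.08
    max_trials: int = 10000

    def noise(self) -> NoiseConfig:
        return NoiseConfig(self.lum_half_range, self.tritan_amplitude)

    def fit_params(self) -> FitParams:
        return FitParams(bandwidth=self.bandwidth, level=self.level)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EngineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "EngineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
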