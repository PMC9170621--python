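"""Session CSV and fit JSON serialization.

Trial-level data go to CSV (human-inspectable long tables); profiles,
fits and configs go to JSON (nested parameters).  Session CSVs carry a
versioned comment header with the seed so replays are traceable.
"""

from __future__ import annotations

import json
import math

import pandas as pd

from .colorimetry import Axis
from .config import ENGINE_VERSION, EngineConfig
from .errors import FormatError
from .staircase import Session, TrialRecord

__all__ = ["write_session_csv", "read_session_csv", "write_fit_json"]

_COLUMNS = [
    "trial_index",
    "set_index",
    "sat_protan",
    "sat_deutan",
    "sat_tritan",
    "tapped",
]
_VALID_TAPS = {a.value for a in Axis} | {"distractor"}


def write_session_csv(session: Session, path) -> None:
    def fmt(v: float | None) -> str:
        return "" if v is None else repr(v)  # repr round-trips float64 exactly

    with open(path, "w") as fh:
        fh.write(f"# cvdscreen session v{ENGINE_VERSION}\n")
        fh.write(f"# seed={session.seed} complete={session.complete}\n")
        fh.write(",".join(_COLUMNS) + "\n")
        for tr in session.trials:
            fh.write(
                f"{tr.trial_index},{tr.set_index},"
                f"{fmt(tr.saturations.get(Axis.PROTAN))},"
                f"{fmt(tr.saturations.get(Axis.DEUTAN))},"
                f"{fmt(tr.saturations.get(Axis.TRITAN))},"
                f"{tr.tapped}\n"
            )


def read_session_csv(path, config: EngineConfig | None = None) -> Session:
    """Load a session log for pooling/fitting (staircase state not rebuilt)."""
    config = config or EngineConfig()
    seed = None
    complete = False
    with open(path) as fh:
        header = [fh.readline(), fh.readline()]
    for line in header:
        if line.startswith("# seed="):
            for tok in line[2:].split():
                key, _, val = tok.partition("=")
                if key == "seed":
                    seed = None if val == "None" else int(val)
                elif key == "complete":
                    complete = val == "True"
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: cannot parse session CSV: {exc}") from exc
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    session = Session(seed=seed, config=config)
    session.complete = complete
    expected = 1
    for row in df.itertuples(index=False):
        if int(row.trial_index) != expected:
            raise FormatError(
                f"{path}: trial_index {row.trial_index} out of order (expected {expected})"
            )
        expected += 1
        sats = {}
        for a in Axis:
            v = getattr(row, f"sat_{a.value}")
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                sats[a] = float(v)
        if row.tapped not in _VALID_TAPS:
            raise FormatError(f"{path}: unknown tapped value {row.tapped!r}")
        if row.tapped != "distractor" and Axis(row.tapped) not in sats:
            raise FormatError(
                f"{path}: trial {row.trial_index} taps inactive axis {row.tapped!r}"
            )
        session.trials.append(
            TrialRecord(int(row.trial_index), int(row.set_index), sats, str(row.tapped))
        )
    return session


def write_fit_json(fits: dict, level: float, path) -> None:
    payload = {
        "engine_version": ENGINE_VERSION,
        "fits": [fit.to_dict(level=level) for fit in fits.values()],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
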