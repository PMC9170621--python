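"""Cone-space colorimetry for confusion-line stimulus generation.

Chromaticities live in the MacLeod-Boynton (MB) diagram: ``l = L/(L+M)``
and ``s = S/(L+M)`` at luminance ``L+M``, where L, M, S are the long-,
medium- and short-wavelength cone excitations.  In this space:

* protanope luminance is carried by M alone, so protan confusion lines
  converge at the L-cone corner ``(l, s) = (1, 0)``;
* deuteranope luminance is carried by L alone, so deutan confusion lines
  converge at ``(0, 0)``;
* tritan confusion lines are vertical (constant ``l``).

A :class:`DeviceProfile` holds everything display-specific: the linear
RGB -> LMS matrix, per-channel gamma exponents, the background (white)
chromaticity and the chromaticity of each confusion axis at maximum
in-gamut saturation.  The engine never hard-codes a set of cone
fundamentals; the profile's coordinates fully determine the geometry.
The s axis carries no normalization convention - only ratios of s to the
background s enter any computation downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping

import numpy as np

from .errors import (
    GamutViolationError,
    InvalidConeExcitationError,
    InvalidProfileError,
    InvalidSaturationError,
    UnderdeterminedConversionError,
)

__all__ = [
    "Axis",
    "ChromaticityMB",
    "ConeExcitation",
    "DeviceProfile",
    "CalibrationAudit",
    "mb_from_cones",
    "cones_from_mb",
    "rgb_from_cones",
    "cones_from_rgb",
    "target_chromaticity",
    "max_in_gamut_saturation",
    "dichromat_luminance_signal",
    "audit_calibration_error",
    "infer_white_s",
]

_GAMUT_TOL = 1e-9


class Axis(str, Enum):
    """Dichromatic confusion axis (deficiency class)."""

    PROTAN = "protan"
    DEUTAN = "deutan"
    TRITAN = "tritan"


RED_GREEN_AXES = (Axis.PROTAN, Axis.DEUTAN)


@dataclass(frozen=True)
class ChromaticityMB:
    """MacLeod-Boynton chromaticity, optionally with a luminance."""

    l: float
    s: float
    lum: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.l < 1.0:
            raise ValueError(f"l must be in (0, 1), got {self.l}")
        if self.s < 0.0:
            raise ValueError(f"s must be nonnegative, got {self.s}")
        if self.lum is not None and self.lum <= 0.0:
            raise ValueError(f"lum must be positive, got {self.lum}")

    def with_lum(self, lum: float) -> "ChromaticityMB":
        return ChromaticityMB(self.l, self.s, lum)


@dataclass(frozen=True)
class ConeExcitation:
    """L, M, S cone excitations in arbitrary linear units."""

    L: float
    M: float
    S: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.M, self.S], dtype=float)


def mb_from_cones(c: ConeExcitation) -> ChromaticityMB:
    """Project cone excitations to MB chromaticity (keeping luminance)."""
    lum = c.L + c.M
    if lum <= 0.0:
        raise InvalidConeExcitationError(f"L+M must be positive, got {lum}")
    return ChromaticityMB(c.L / lum, c.S / lum, lum)


def cones_from_mb(x: ChromaticityMB) -> ConeExcitation:
    """Lift an MB chromaticity with luminance back to cone excitations."""
    if x.lum is None:
        raise UnderdeterminedConversionError(
            "chromaticity has no luminance; conversion to cones is underdetermined"
        )
    return ConeExcitation(x.l * x.lum, (1.0 - x.l) * x.lum, x.s * x.lum)


def infer_white_s(protan_ep: ChromaticityMB, deutan_ep: ChromaticityMB) -> float:
    """Background s implied by the red-green endpoints.

    The protan endpoint lies on a confusion line through the protan
    copunctal point (1, 0); the deutan endpoint on a line through (0, 0).
    Both lines pass through the background chromaticity, so their
    intersection recovers the background s when a profile omits it.
    """
    slope_p = protan_ep.s / (1.0 - protan_ep.l)  # s(l) = slope_p * (1 - l)
    slope_d = deutan_ep.s / deutan_ep.l          # s(l) = slope_d * l
    l_star = slope_p / (slope_p + slope_d)
    return slope_d * l_star


@dataclass(frozen=True)
class DeviceProfile:
    """Display calibration state.

    ``rgb_to_lms`` columns are the cone excitations of the three primaries
    at full drive; ``gamma`` holds the per-channel encoding exponents.
    ``axis_endpoints`` are the chromaticities at saturation 1.0 on each
    confusion axis.  The tritan endpoint must share the background l
    (tritan confusion lines are vertical in MB space).
    """

    model_id: str
    rgb_to_lms: np.ndarray
    gamma: np.ndarray
    white: ChromaticityMB
    axis_endpoints: Mapping[Axis, ChromaticityMB]
    lms_to_rgb: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.rgb_to_lms, dtype=float)
        g = np.asarray(self.gamma, dtype=float)
        object.__setattr__(self, "rgb_to_lms", m)
        object.__setattr__(self, "gamma", g)
        if m.shape != (3, 3):
            raise InvalidProfileError("rgb_to_lms must be 3x3")
        if abs(np.linalg.det(m)) < 1e-15:
            raise InvalidProfileError("rgb_to_lms is singular")
        object.__setattr__(self, "lms_to_rgb", np.linalg.inv(m))
        if g.shape != (3,) or np.any(g <= 0.5) or np.any(g >= 5.0):
            raise InvalidProfileError("gamma exponents must be in (0.5, 5)")
        if self.white.lum is None:
            raise InvalidProfileError("white point must carry a luminance")
        missing = [a for a in Axis if a not in self.axis_endpoints]
        if missing:
            raise InvalidProfileError(f"missing endpoints: {missing}")
        if abs(self.axis_endpoints[Axis.TRITAN].l - self.white.l) > 1e-9:
            raise InvalidProfileError(
                "tritan endpoint l must equal the background l "
                "(tritan confusion lines are vertical)"
            )

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceProfile":
        eps = {
            Axis(name): ChromaticityMB(ep["l"], ep["s"])
            for name, ep in d["endpoints"].items()
        }
        w = d["white"]
        s_white = w.get("s")
        if s_white is None:
            s_white = infer_white_s(eps[Axis.PROTAN], eps[Axis.DEUTAN])
        white = ChromaticityMB(w["l"], s_white, w.get("lum", 1.0))
        return cls(
            model_id=d["model_id"],
            rgb_to_lms=np.array(d["rgb_to_lms"], dtype=float),
            gamma=np.array(d["gamma"], dtype=float),
            white=white,
            axis_endpoints=eps,
        )

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "rgb_to_lms": self.rgb_to_lms.tolist(),
            "gamma": self.gamma.tolist(),
            "white": {"l": self.white.l, "s": self.white.s, "lum": self.white.lum},
            "endpoints": {
                a.value: {"l": ep.l, "s": ep.s}
                for a, ep in self.axis_endpoints.items()
            },
        }

    @classmethod
    def from_json(cls, path) -> "DeviceProfile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def default(cls) -> "DeviceProfile":
        """Packaged default profile.

        Endpoint and background chromaticities are published tablet
        calibration values; the RGB->LMS matrix and gamma are a synthetic
        stand-in consistent with that geometry (no physical display was
        measured for this package).
        """
        ref = resources.files("cvdscreen.data") / "synthetic_default_profile.json"
        return cls.from_dict(json.loads(ref.read_text()))


def rgb_from_cones(
    c: ConeExcitation, p: DeviceProfile, clip: bool = False
) -> np.ndarray:
    """Gamma-encoded RGB triple displaying the given cone excitations.

    Raises :class:`GamutViolationError` when the linear RGB leaves
    ``[0, 1]^3`` (tolerance 1e-9) unless ``clip`` is set.
    """
    linear = p.lms_to_rgb @ c.as_array()
    if np.any(linear < -_GAMUT_TOL) or np.any(linear > 1.0 + _GAMUT_TOL):
        if not clip:
            raise GamutViolationError(f"linear RGB out of gamut: {linear}")
    linear = np.clip(linear, 0.0, 1.0)
    return linear ** (1.0 / p.gamma)


def cones_from_rgb(rgb, p: DeviceProfile) -> ConeExcitation:
    """Decode gamma-encoded RGB and map to cone excitations."""
    linear = np.asarray(rgb, dtype=float) ** p.gamma
    L, M, S = p.rgb_to_lms @ linear
    return ConeExcitation(L, M, S)


def _chromaticity_on_axis(axis: Axis, t: float, p: DeviceProfile) -> ChromaticityMB:
    # No [0, 1] check: used internally for the gamut search (t may exceed 1).
    w, ep = p.white, p.axis_endpoints[axis]
    return ChromaticityMB(
        w.l + t * (ep.l - w.l), max(w.s + t * (ep.s - w.s), 0.0), w.lum
    )


def target_chromaticity(
    axis: Axis, saturation: float, p: DeviceProfile
) -> ChromaticityMB:
    """Chromaticity of a confusion-line target.

    ``saturation`` is the fractional distance from the background toward
    the axis endpoint (the maximum in-gamut chromaticity on that axis).
    """
    if not 0.0 <= saturation <= 1.0:
        raise InvalidSaturationError(f"saturation must be in [0, 1], got {saturation}")
    return _chromaticity_on_axis(Axis(axis), saturation, p)


def max_in_gamut_saturation(
    axis: Axis, p: DeviceProfile, lum: float, tol: float = 1e-6
) -> float:
    """Largest multiple of the axis direction displayable at ``lum``.

    The linear RGB of a point on the axis is affine in the saturation
    multiplier at fixed luminance, so the in-gamut set is an interval and
    bisection is exact to ``tol``.
    """
    axis = Axis(axis)

    def in_gamut(t: float) -> bool:
        chrom = _chromaticity_on_axis(axis, t, p).with_lum(lum)
        linear = p.lms_to_rgb @ cones_from_mb(chrom).as_array()
        return bool(np.all(linear >= -_GAMUT_TOL) and np.all(linear <= 1 + _GAMUT_TOL))

    if not in_gamut(0.0):
        raise InvalidProfileError("background itself is out of gamut at this luminance")
    lo, hi = 0.0, 1.0
    doublings = 0
    while in_gamut(hi):
        lo, hi = hi, hi * 2.0
        doublings += 1
        if doublings > 60:  # direction never leaves the cube (degenerate)
            return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if in_gamut(mid):
            lo = mid
        else:
            hi = mid
    return lo


def dichromat_luminance_signal(
    axis: Axis, saturation: float, p: DeviceProfile, observer_type: str
) -> float:
    """Relative luminance change of a target as seen by a dichromat.

    At fixed L+M a protanope's luminance is proportional to M and a
    deuteranope's to L, so a target at MB coordinate ``l_t`` against a
    background at ``l_w`` carries a residual luminance contrast of
    ``(l_w - l_t)/(1 - l_w)`` (protanope) or ``(l_t - l_w)/l_w``
    (deuteranope).  Tritan targets share the background l, so the signal
    is zero by construction.
    """
    axis = Axis(axis)
    if observer_type not in ("protanope", "deuteranope"):
        raise ValueError(f"unknown dichromat type {observer_type!r}")
    l_t = target_chromaticity(axis, saturation, p).l
    l_w = p.white.l
    if observer_type == "protanope":
        return (l_w - l_t) / (1.0 - l_w)
    return (l_t - l_w) / l_w


@dataclass(frozen=True)
class CalibrationAudit:
    """Residual cues from rendering with one profile, displaying with another.

    ``lum_excess_*`` is the dichromat luminance contrast beyond the one
    intended by the nominal profile; ``tritan_fraction`` is the excess
    s contrast relative to the displayed background s.  Both are zero
    when the profiles coincide.
    """

    lum_excess_protanope: float
    lum_excess_deuteranope: float
    tritan_fraction: float


def _displayed(chrom: ChromaticityMB, render: DeviceProfile, display: DeviceProfile) -> ConeExcitation:
    rgb = rgb_from_cones(cones_from_mb(chrom), render, clip=True)
    return cones_from_rgb(rgb, display)


def audit_calibration_error(
    p_nominal: DeviceProfile,
    p_perturbed: DeviceProfile,
    axis: Axis,
    saturation: float,
) -> CalibrationAudit:
    """Residual dichromat and tritan cues from calibration error.

    A target and the background are rendered with ``p_nominal`` but
    physically displayed according to ``p_perturbed``; the audit reports
    how much extra luminance signal (per dichromat type) and tritan
    signal (fraction of the displayed background s) the miscalibration
    introduces, for comparison against the masking-noise amplitudes.
    """
    tgt_chrom = target_chromaticity(Axis(axis), saturation, p_nominal)
    wht_chrom = p_nominal.white

    tgt_int = cones_from_mb(tgt_chrom)
    wht_int = cones_from_mb(wht_chrom)
    tgt_act = _displayed(tgt_chrom, p_nominal, p_perturbed)
    wht_act = _displayed(wht_chrom, p_nominal, p_perturbed)

    def contrast(t, w, attr):
        return (getattr(t, attr) - getattr(w, attr)) / getattr(w, attr)

    lum_p = contrast(tgt_act, wht_act, "M") - contrast(tgt_int, wht_int, "M")
    lum_d = contrast(tgt_act, wht_act, "L") - contrast(tgt_int, wht_int, "L")

    s_act_t, s_act_w = mb_from_cones(tgt_act).s, mb_from_cones(wht_act).s
    s_int_t, s_int_w = mb_from_cones(tgt_int).s, mb_from_cones(wht_int).s
    tritan = (s_act_t - s_act_w) / s_act_w - (s_int_t - s_int_w) / s_int_w
    return CalibrationAudit(lum_p, lum_d, tritan)
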