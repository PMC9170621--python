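import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvdscreen import (
    Axis,
    ChromaticityMB,
    ConeExcitation,
    DeviceProfile,
    audit_calibration_error,
    cones_from_mb,
    cones_from_rgb,
    dichromat_luminance_signal,
    max_in_gamut_saturation,
    mb_from_cones,
    rgb_from_cones,
    target_chromaticity,
)
from cvdscreen.colorimetry import infer_white_s
from cvdscreen.errors import (
    GamutViolationError,
    InvalidConeExcitationError,
    InvalidProfileError,
    InvalidSaturationError,
    UnderdeterminedConversionError,
)

PRINTED_ENDPOINTS = {
    Axis.PROTAN: (0.6160, 0.0186),
    Axis.DEUTAN: (0.6160, 0.0157),
    Axis.TRITAN: (0.6553, 0.0033),
}


class TestChromaticityConversions:
    @pytest.mark.parametrize(
        "cones, expected",
        [
            ((2.0, 1.0, 0.03), (2 / 3, 0.01, 3.0)),
            ((0.5, 0.5, 0.0), (0.5, 0.0, 1.0)),
        ],
    )
    def test_mb_from_cones_ratios(self, cones, expected):
        mb = mb_from_cones(ConeExcitation(*cones))
        assert (mb.l, mb.s, mb.lum) == pytest.approx(expected)

    def test_cones_from_mb_direct(self):
        c = cones_from_mb(ChromaticityMB(0.6553, 0.0, lum=1.0))
        assert (c.L, c.M, c.S) == pytest.approx((0.6553, 0.3447, 0.0))

    def test_zero_luminance_rejected(self):
        with pytest.raises(InvalidConeExcitationError):
            mb_from_cones(ConeExcitation(0.0, 0.0, 0.5))

    def test_missing_luminance_rejected(self):
        with pytest.raises(UnderdeterminedConversionError):
            cones_from_mb(ChromaticityMB(0.5, 0.1))

    @given(
        l=st.floats(0.01, 0.99),
        s=st.floats(0.0, 2.0),
        lum=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_mb_cones_roundtrip(self, l, s, lum):
        x = ChromaticityMB(l, s, lum)
        y = mb_from_cones(cones_from_mb(x))
        assert math.isclose(y.l, x.l, rel_tol=0, abs_tol=1e-10)
        assert math.isclose(y.s, x.s, rel_tol=1e-10, abs_tol=1e-10)
        assert math.isclose(y.lum, x.lum, rel_tol=1e-10)


class TestDeviceTransforms:
    def test_identity_profile_passthrough(self):
        p = DeviceProfile(
            model_id="identity",
            rgb_to_lms=np.eye(3),
            gamma=np.ones(3),
            white=ChromaticityMB(0.5, 0.2, 0.5),
            axis_endpoints={
                Axis.PROTAN: ChromaticityMB(0.4, 0.25),
                Axis.DEUTAN: ChromaticityMB(0.45, 0.22),
                Axis.TRITAN: ChromaticityMB(0.5, 0.05),
            },
        )
        rgb = rgb_from_cones(ConeExcitation(0.2, 0.3, 0.1), p)
        assert rgb == pytest.approx([0.2, 0.3, 0.1])

    def test_gamma_square_root_law(self, simple_profile):
        import dataclasses

        p = dataclasses.replace(simple_profile, gamma=np.array([2.0, 2.0, 2.0]))
        lms = p.rgb_to_lms @ np.array([0.25, 0.25, 0.25])
        rgb = rgb_from_cones(ConeExcitation(*lms), p)
        assert rgb == pytest.approx([0.5, 0.5, 0.5])

    def test_encode_decode_roundtrip(self, default_profile):
        for v in np.linspace(0.05, 0.95, 7):
            c = cones_from_rgb([v, v, v], default_profile)
            rgb = rgb_from_cones(c, default_profile)
            assert rgb == pytest.approx([v, v, v], abs=1e-12)

    def test_out_of_gamut_raises_and_clips(self, default_profile):
        c = cones_from_mb(ChromaticityMB(0.9, 0.0, lum=0.6))
        with pytest.raises(GamutViolationError):
            rgb_from_cones(c, default_profile)
        clipped = rgb_from_cones(c, default_profile, clip=True)
        assert np.all(clipped >= 0.0) and np.all(clipped <= 1.0)


class TestTargetGeometry:
    def test_zero_saturation_is_white(self, default_profile):
        for axis in Axis:
            chrom = target_chromaticity(axis, 0.0, default_profile)
            assert chrom.l == pytest.approx(default_profile.white.l)
            assert chrom.s == pytest.approx(default_profile.white.s)

    def test_full_saturation_hits_printed_endpoints(self, default_profile):
        for axis, (l, s) in PRINTED_ENDPOINTS.items():
            chrom = target_chromaticity(axis, 1.0, default_profile)
            assert (chrom.l, chrom.s) == pytest.approx((l, s), abs=1e-12)

    def test_tritan_axis_is_vertical(self, default_profile):
        w = default_profile.white
        chrom = target_chromaticity(Axis.TRITAN, 0.5, default_profile)
        assert chrom.l == w.l
        assert chrom.s == pytest.approx(0.5 * (w.s + 0.0033))

    def test_affine_in_saturation(self, default_profile):
        w = default_profile.white
        full = target_chromaticity(Axis.PROTAN, 1.0, default_profile)
        for t in (0.1, 0.37, 0.9):
            chrom = target_chromaticity(Axis.PROTAN, t, default_profile)
            assert chrom.l - w.l == pytest.approx(t * (full.l - w.l), abs=1e-15)
            assert chrom.s - w.s == pytest.approx(t * (full.s - w.s), abs=1e-15)

    def test_saturation_bounds_enforced(self, default_profile):
        with pytest.raises(InvalidSaturationError):
            target_chromaticity(Axis.PROTAN, 1.2, default_profile)
        with pytest.raises(InvalidSaturationError):
            target_chromaticity(Axis.PROTAN, -0.1, default_profile)


class TestGamutSearch:
    def brute_force(self, axis, profile, lum, step=1e-5, t_max=20.0):
        # vectorized grid scan: linear RGB is affine in t, so build the
        # whole ray at once and take the last in-gamut point before the
        # first violation
        w, ep = profile.white, profile.axis_endpoints[axis]
        t = np.arange(0.0, t_max, step)
        l = w.l + t * (ep.l - w.l)
        s = np.maximum(w.s + t * (ep.s - w.s), 0.0)
        lms = np.stack([l * lum, (1 - l) * lum, s * lum])
        linear = profile.lms_to_rgb @ lms
        ok = np.all((linear >= -1e-9) & (linear <= 1 + 1e-9), axis=0)
        first_bad = np.argmin(ok)  # ok[0] is True (white in gamut)
        assert not ok[first_bad]
        return t[first_bad - 1]

    @pytest.mark.parametrize("axis", list(Axis))
    def test_matches_brute_force_scan(self, axis, simple_profile):
        lum = simple_profile.white.lum
        fast = max_in_gamut_saturation(axis, simple_profile, lum)
        slow = self.brute_force(axis, simple_profile, lum)
        assert fast == pytest.approx(slow, abs=1e-4)

    def test_monotone_in_luminance_near_ceiling(self, simple_profile):
        lums = [0.5, 0.7, 0.9]
        vals = [
            max_in_gamut_saturation(Axis.PROTAN, simple_profile, lum)
            for lum in lums
        ]
        assert vals[0] >= vals[1] >= vals[2]

    def test_background_out_of_gamut_rejected(self, simple_profile):
        with pytest.raises(InvalidProfileError):
            max_in_gamut_saturation(Axis.PROTAN, simple_profile, lum=50.0)


class TestDichromatLuminanceSignal:
    def test_tritan_targets_carry_no_signal(self, default_profile):
        for t in ("protanope", "deuteranope"):
            assert dichromat_luminance_signal(Axis.TRITAN, 0.9, default_profile, t) == 0.0

    def test_protanope_signal_closed_form(self, default_profile):
        # 0.9 * (0.6553 - 0.6160) / (1 - 0.6553)
        got = dichromat_luminance_signal(Axis.PROTAN, 0.9, default_profile, "protanope")
        assert got == pytest.approx(0.9 * 0.0393 / 0.3447, rel=1e-6)

    def test_deuteranope_signal_closed_form(self, default_profile):
        got = dichromat_luminance_signal(Axis.PROTAN, 0.9, default_profile, "deuteranope")
        assert got == pytest.approx(-0.9 * 0.0393 / 0.6553, rel=1e-6)

    def test_linear_in_saturation_and_zero_at_zero(self, default_profile):
        base = dichromat_luminance_signal(Axis.DEUTAN, 0.5, default_profile, "protanope")
        assert dichromat_luminance_signal(Axis.DEUTAN, 0.0, default_profile, "protanope") == 0.0
        assert dichromat_luminance_signal(
            Axis.DEUTAN, 1.0, default_profile, "protanope"
        ) == pytest.approx(2 * base)


class TestCalibrationAudit:
    def test_identity_profiles_give_zero_residuals(self, default_profile):
        audit = audit_calibration_error(default_profile, default_profile, Axis.PROTAN, 0.9)
        assert audit.lum_excess_protanope == pytest.approx(0.0, abs=1e-9)
        assert audit.lum_excess_deuteranope == pytest.approx(0.0, abs=1e-9)
        assert audit.tritan_fraction == pytest.approx(0.0, abs=1e-9)

    def test_matrix_perturbation_matches_two_path_recomputation(self, default_profile):
        import dataclasses

        rng = np.random.default_rng(7)
        perturbed = dataclasses.replace(
            default_profile,
            rgb_to_lms=default_profile.rgb_to_lms
            * (1 + 0.01 * rng.standard_normal((3, 3))),
        )
        audit = audit_calibration_error(default_profile, perturbed, Axis.DEUTAN, 0.9)

        # independent recomputation straight through both device models
        def displayed(chrom):
            rgb = rgb_from_cones(cones_from_mb(chrom), default_profile, clip=True)
            return cones_from_rgb(rgb, perturbed)

        tgt_n = cones_from_mb(target_chromaticity(Axis.DEUTAN, 0.9, default_profile))
        wht_n = cones_from_mb(default_profile.white)
        tgt_a = displayed(target_chromaticity(Axis.DEUTAN, 0.9, default_profile))
        wht_a = displayed(default_profile.white)
        lum_p = (tgt_a.M - wht_a.M) / wht_a.M - (tgt_n.M - wht_n.M) / wht_n.M
        assert audit.lum_excess_protanope == pytest.approx(lum_p, rel=1e-12)
        s_a = tgt_a.S / (tgt_a.L + tgt_a.M) / (wht_a.S / (wht_a.L + wht_a.M)) - 1
        s_n = tgt_n.S / (tgt_n.L + tgt_n.M) / (wht_n.S / (wht_n.L + wht_n.M)) - 1
        assert audit.tritan_fraction == pytest.approx(s_a - s_n, rel=1e-9, abs=1e-12)


class TestDeviceProfileIO:
    def test_json_roundtrip(self, default_profile, tmp_path):
        path = tmp_path / "profile.json"
        default_profile.to_json(path)
        again = DeviceProfile.from_json(path)
        assert np.allclose(again.rgb_to_lms, default_profile.rgb_to_lms)
        assert again.white == default_profile.white
        assert again.axis_endpoints == default_profile.axis_endpoints

    def test_white_s_inferred_from_red_green_endpoints(self):
        # the two confusion lines through the printed endpoints meet at the
        # background; their copunctal points are (1, 0) and (0, 0)
        s = infer_white_s(
            ChromaticityMB(*PRINTED_ENDPOINTS[Axis.PROTAN]),
            ChromaticityMB(*PRINTED_ENDPOINTS[Axis.DEUTAN]),
        )
        assert s == pytest.approx(0.016700, abs=5e-6)

    def test_default_profile_white_uses_inferred_s(self, default_profile):
        assert default_profile.white.l == pytest.approx(0.6553)
        assert default_profile.white.s == pytest.approx(0.016700, abs=5e-6)

    def test_tilted_tritan_endpoint_rejected(self, default_profile):
        d = default_profile.to_dict()
        d["endpoints"]["tritan"]["l"] = 0.60
        with pytest.raises(InvalidProfileError):
            DeviceProfile.from_dict(d)
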