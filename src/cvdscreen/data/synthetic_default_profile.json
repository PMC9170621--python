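{
  "model_id": "synthetic-default-tablet",
  "comment": "Synthetic stand-in profile. Endpoint chromaticities and the background l are published tablet calibration values; the background s is recomputed at load from the red-green endpoints; the RGB->LMS matrix and gamma exponents are constructed (not measured) so that full drive of all three primaries reproduces the background chromaticity at luminance 1.0 and the default background (lum 0.6) plus masking noise stays in gamut except for the unavoidable high-saturation tritan corner.",
  "rgb_to_lms": [
    [0.1869, 0.4355, 0.0329],
    [0.0231, 0.2845, 0.0371],
    [0.000147, 0.001728, 0.014824835300576443]
  ],
  "gamma": [2.2, 2.2, 2.2],
  "white": {"l": 0.6553, "s": null, "lum": 0.6},
  "endpoints": {
    "protan": {"l": 0.616, "s": 0.0186},
    "deutan": {"l": 0.616, "s": 0.0157},
    "tritan": {"l": 0.6553, "s": 0.0033}
  }
}
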