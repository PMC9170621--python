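# cvdscreen

A desk-scale engine for gamified screening of congenital red-green color
vision deficiency (CVD) in young children. It reimplements the
computational core of a tablet-based tap-the-odd-spot test: calibrated
confusion-line stimulus generation with masking noise, a three-axis
adaptive staircase, model-free psychometric threshold estimation, and a
threshold-ratio classifier — validated end to end against simulated
observers. It is aimed at vision scientists who want to study, stress or
extend the method without a tablet, a clinic, or children.

## The method

Stimuli live in the MacLeod–Boynton chromaticity diagram
(l = L/(L+M), s = S/(L+M) at constant luminance L+M). Each trial shows
11 items: one colored target on each of the protan, deutan and tritan
dichromatic confusion lines, plus eight achromatic distractors. Item
luminance is drawn uniformly within ±20% of the background and every
item's s coordinate is shifted by a binary ±16% of the background s —
masking the residual luminance cue available to dichromats (at most
≈10% of background, computed from the calibrated endpoint
chromaticities) and the ≈8% tritan leakage expected from individual
differences in cone fundamentals or calibration error.

Each axis runs an adaptive staircase from saturation 0.9 (relative to
the maximum in-gamut saturation): tapping a target halves that axis's
saturation, tapping a distractor multiplies all active axes by 1.5
(capped at 0.9). A staircase retires after 35 update events per set;
two sets give 70 Bernoulli observations per axis. Performance curves
are estimated by model-free local-linear logistic regression on
log10 saturation (Gaussian kernel, bandwidth h = 0.70) and the
threshold is the largest saturation where the fitted curve crosses the
π = 0.21 performance level.

The classifier uses

    r = min(t_tritan / t_protan, t_tritan / t_deutan)

which cancels non-visual factors (attention, motivation) that depress
performance on all three axes equally; congenital tritan deficits are
rare, so a small r specifically flags a red-green deficit. An observer
is labelled CVD when r < 0.59, the midpoint between the group extremes
of a discovery cohort.

## Worked example

Simulate a deuteranope's full session, fit it, and classify:

```
$ cvdscreen simulate-session --observer deuteranope --seed 7 --out session.csv
wrote 124 trials to session.csv

$ cvdscreen fit session.csv --out fits.json
protan: threshold=0.2518 flag=ok
deutan: threshold=0.9000 flag=unresolved
tritan: threshold=0.0199 flag=ok
ratio: 0.0221
wrote fits to fits.json
```

The deutan staircase never left the 0.9 ceiling (the observer is blind
along that confusion line), the protan threshold is strongly elevated,
and tritan discrimination is normal — so the tritan:red-green ratio
0.022 falls far below the 0.59 criterion:

```
$ cvdscreen classify --protan 0.9 --deutan 0.9 --tritan 0.0241
ratio=0.0268 criterion=0.59 label=CVD
```

Cohort-level validation against simulation ground truth:

```
$ cvdscreen validate --n-cvd 37 --n-control 117 --seed 1 --report report.md
```

Other subcommands: `simulate-cohort` (writes per-participant session
CSVs plus ground truth), `optimize-params` (grid search of bandwidth
and level maximizing group separation), `derive-criterion`,
`audit-calibration`. All accept `--seed`, `--config` (engine constants
as JSON) and `--profile` (device calibration JSON).

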