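# Methods

## Colorimetric model

All chromatic computation happens in the MacLeod–Boynton (MB) diagram:
`l = L/(L+M)`, `s = S/(L+M)`, luminance `L+M`. The diagram makes the
three dichromatic geometries linear: protan confusion lines converge at
the L-cone corner (1, 0), deutan lines at (0, 0), and tritan lines are
vertical (constant l). The engine never hard-codes cone fundamentals;
a `DeviceProfile` carries everything display-specific — an RGB→LMS
matrix (columns = primaries at full drive), per-channel gamma
exponents, the background chromaticity, and the chromaticity of each
confusion axis at maximum in-gamut saturation ("endpoints"). Stimulus
saturation is the fractional distance from the background to the
endpoint; the highest saturation ever displayed is 0.9.

The packaged default profile embeds published tablet calibration
endpoints — protan (0.6160, 0.0186), deutan (0.6160, 0.0157), tritan
(0.6553, 0.0033) — and takes the background l from the tritan endpoint
(vertical tritan lines force equality). When a profile omits the
background s, the loader recovers it as the intersection of the two
red-green confusion lines through their endpoints and copunctal points;
for the default endpoints this gives s = 0.01670 at l = 0.6552,
agreeing with the tritan l to four decimals — a useful internal
consistency check on the printed geometry. The default matrix and
gamma are synthetic (no display was measured here): they are
constructed so that full drive of the three primaries reproduces the
background chromaticity at unit luminance and the background sits at
60% of peak luminance, leaving headroom for luminance noise.

With this geometry, a protanope (luminance ∝ M) sees a residual
luminance contrast of `(l_w − l_t)/(1 − l_w)` in a red-green target, a
deuteranope (luminance ∝ L) sees `(l_t − l_w)/l_w`. At saturation 0.9
the largest magnitude over types and axes is 10.3% of the background —
inside the ±20% luminance masking noise. The analogous tritan leakage
budget (≈8% of background s, from cone-fundamental variation or
calibration error) is inside the ±16% binary tritan noise.
`audit_calibration_error` renders a target through a nominal profile,
"displays" it through a perturbed one, and reports the excess dichromat
luminance contrast and tritan contrast so miscalibration can be checked
against those noise amplitudes.

## Trial assembly and noise

A trial holds 11 items: one target per active axis, the rest achromatic
distractors at the background chromaticity (an inactive axis is
replaced by a distractor). Luminance factors are uniform on
[0.8, 1.2]; each item independently takes an equiprobable s shift of
±0.16·s_background; positions are a uniform permutation of the 11
slots. Noise is drawn per item, not per pixel — the item is the
smallest unit that can influence a tap. A draw that leaves the device
gamut is redrawn (up to 100 times) and finally clipped with a warning;
with the default profile the only systematically affected case is a
high-saturation tritan target with a negative s shift, which sits near
the S≈0 gamut edge by construction, so the redraw resolves it by
taking the positive shift.

## Staircase protocol

Each axis starts at saturation 0.9. Tapping a target halves that axis;
tapping a distractor multiplies every active axis by 1.5, capped at
0.9. Both events are "updates" for the staircases involved; a tap on
a different axis's target leaves this axis untouched. A staircase
retires at 35 updates within the current set; when all three are
retired, set 2 begins with counts reset and saturations carried over
(restarting at 0.9 would waste trials re-descending). The session
completes when set 2's quotas are met; a 40-trial floor is enforced
separately as a validity flag, since quota completion alone does not
guarantee it.

Pooling for fitting follows the update semantics: each update event
contributes one Bernoulli observation at that axis's presented
saturation — success if its own target was tapped, failure if a
distractor was tapped. The fitted curve is therefore the *conditional*
probability of an own-target tap given the trial ended in an own-or-
distractor tap; its guessing floor is (1/11)/(1/11 + 8/11) = 1/9,
safely below the 0.21 threshold level.

## Model-free fitting and thresholds

The psychometric curve is estimated by local-linear logistic
regression: at each of 201 grid points on log10 saturation (spanning
the lowest tested level to 0.9), a degree-1 polynomial on the logit
scale maximizes the Gaussian-kernel-weighted binomial log-likelihood.
Fitting is done on log10 saturation because staircase levels are
geometric (0.301 decades per halving), so the default bandwidth
h = 0.70 smooths over roughly two to three adjacent levels; on the raw
scale the same number would span the whole range. The solver is a
damped Newton iteration vectorized over grid points; steps are capped
in norm, the intercept is clamped at logit(1e−6) so separable
neighborhoods saturate instead of diverging, and a tiny ridge keeps
the 2×2 systems well-posed. In the large-bandwidth limit the fit
reproduces a single global logistic regression to better than 1e−3 —
the main correctness oracle for the local-likelihood machinery.

The threshold at level π = 0.21 is the largest grid saturation where
the fitted curve crosses π from below, linearly interpolated on the
log grid. A curve that never reaches π is flagged `unresolved` and
assigned the 0.9 display ceiling; a curve already above π at the lowest
tested level is flagged `floor` and assigned that level. An axis whose
data contain only one distinct saturation (a staircase pinned at the
ceiling for the whole session) cannot be fitted at all; the pipeline
then resolves it directly: observed success below π ⇒ unresolved at
0.9, above ⇒ floor at that level.

`optimize_fit_params` reproduces the discovery-style calibration: grid
search over (h, π), objective = (smallest control ratio) − (largest
CVD ratio), ties broken toward smaller h then lower π. Defaults:
h ∈ 0.10–2.00 step 0.05, π ∈ 0.05–0.50 step 0.01.

## Classification

`r = min(t_tritan/t_protan, t_tritan/t_deutan)`, with unresolved
thresholds entering at 0.9 (finite, conservative, and still yielding
r ≪ criterion whenever tritan performance is normal). CVD iff
r < 0.59 strictly; the criterion derives from cohort data as the
midpoint between the CVD maximum and control minimum. Reference-test
grouping: 0 errors → control, 1–2 → inconclusive, ≥3 → CVD;
sensitivity and specificity are computed on conclusive groups only.
`power_bootstrap` gives a simulation-based power for planned sample
sizes, defined as the probability that the estimated rate falls within
a stated half-range of the truth — one reasonable reading of a
sample-size bootstrap, not the only one.

## Synthetic observers

An observer detects each displayed target independently with
`p = 1 − exp(−(s/σ_axis)^β)`, taps uniformly among detected targets,
and taps uniformly among all 11 items when nothing is detected; with
probability `lapse` the tap is uniform regardless of the stimulus.
This is deliberately the minimal structure the analysis relies on —
monotone per-axis detectability, axis-specific deficits, intact tritan
discrimination, and a common non-visual error factor — with closed
forms for every tap probability (the test suite checks Monte-Carlo
rates against exact enumeration).

Cohort draws: a normal observer gets one base σ ~ U[0.03, 0.08] shared
by all three axes (normal discrimination is comparably good along all
confusion lines; independent per-axis draws would make tritan:red-green
ratios of healthy observers span 0.37–2.7, which no ratio criterion
could survive). CVD types follow the deutan-dominant mix 50%
deuteranomalous / 25% protanomalous / 15% deuteranope / 10% protanope.
Anomalous trichromats multiply the affected axis's σ by U[5, 20] and
the neighboring red-green axis by U[2, 6] (the two lines are close in
color space); dichromats are blind on the affected axis (σ = ∞) with
the neighbor × U[8, 30]. Lapse ~ U[0, 0.1]. Generated observers use
detection slope β = 4, steep enough that the simulated psychometric
functions rise from the guessing floor to saturation within about an
octave, as the example curves this analysis is designed around do;
shallow slopes (β ≈ 2) leave the own-tap probability hovering at the
threshold level across a wide saturation band, which makes the 0.21
crossing ill-defined for any estimator. Emulated reference-test error
counts are 0 for normals and 3–5 for CVD observers. All parameter
ranges are engineering choices for pipeline validation, not estimates
of human values.

## What the simulations do and do not show

Simulated validation cohorts (37 CVD / 117 normal observers, default
parameters) give sensitivity 1.00: every dichromat and anomalous
trichromat lands far below the 0.59 criterion, at any lapse rate —
the ratio's core design claim. Specificity comes out at 0.86–0.94
across seeds rather than 1.00, and this shortfall is a genuine property
of the modeled task statistics, not of the code: when nothing is
detectable the observer taps uniformly, so a staircase occasionally
rides a run of lucky own-target taps (probability 1/9 per update)
several octaves below the true threshold; the pooled conditional
success in that region sits at the 1/9 floor, only 0.10 below the 0.21
level, and the 0.70-decade kernel can carry a lucky cluster of chance
successes across the threshold region, producing a spuriously low
crossing on one axis. The min() in the ratio then converts any
single-axis collapse into a false positive. Real children whose
guesses are drawn toward salient distractors, or whose psychometric
functions are steeper than any fixed-β Weibull, would not show this
tail; the simulator makes no such claims. Threshold *recovery* is
nevertheless solid: for observers with known thresholds (defined by
the closed-form conditional-success crossing) the median absolute
relative error over complete sessions is ≈14%, well within a 30%
band.

A related subtlety: because observations are pooled only at update
events, a lapse inflates own-target and distractor taps almost
proportionally, so the conditional threshold itself is nearly
lapse-invariant (the true crossing rises only ≈6% at lapse 0.3). The
protocol is thus even more robust to non-visual factors than the ratio
argument alone suggests — but it also means lapse effects on estimated
thresholds are smaller than estimator noise, so robustness is asserted
through classification stability rather than threshold spreads.

## Numerical choices and limitations

- Gamut tests use a 1e−9 tolerance on [0, 1] linear RGB; the
  max-in-gamut search is bisection to 1e−6 (linear RGB is affine in
  the saturation multiplier, so the in-gamut set is an interval).
- Staircase levels are exact float products of 0.9, 0.5 and 1.5, so
  pooling by exact equality aggregates repeated levels correctly, and
  session CSVs store full-precision floats (`repr` round-trip).
- Newton iterations: at most 200, step-norm cap 4.0, ridge 1e−9,
  convergence at 1e−11; all grid points solved simultaneously.
- Problem sizes in the test suite — 154-observer validation cohort,
  99 recovery replicates, 20-seed lapse checks, 10–12k-trial
  Monte-Carlo calibrations — keep the full suite under a few minutes
  while leaving binomial error well below every asserted margin.
- Out of scope: physical display measurement, spectral data, rendering,
  gamified UI, protan-vs-deutan subtype identification (the reference
  test cannot adjudicate it), and realistic cone-fundamental shifts for
  anomalous trichromats.
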