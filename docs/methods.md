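# Methods

`wiltlag` analyses the short-term relationship between leaf wilting, scored
from time-lapse RGB images by optical flow, and stem-diameter variation
measured by a displacement sensor, in plants kept under mild water stress by
threshold-triggered deficit irrigation. This note documents the models,
parameters and numerical choices; nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Wilt scoring

For a frame pair (t−w, t), both resized to 144×144:

1. **Dense optical flow** between the two frames. The estimator is pluggable:
   `deepflow` (delegated to OpenCV's contrib implementation when `cv2` is
   importable; otherwise a capability error), `dense_reference` (scikit-image
   iterative Lucas–Kanade), and `block_match`, a built-in exhaustive
   integer-shift matcher. Block matching minimises the 9×9-window sum of
   squared intensity differences over shifts with |dy|,|dx| ≤ 4, using exact
   integer arithmetic (channel sums and integral-image box sums) and scanning
   candidates in order of increasing |dy|+|dx| with strict-improvement
   updates. Cost ties therefore resolve to the smallest shift, identical
   frames produce an exactly zero field, and results are bit-reproducible —
   the property the test suite depends on. Its limitation is integer
   quantisation: sub-pixel leaf motion rounds to the nearest pixel, which
   attenuates but does not bias the wilt score.
2. **Plant mask** by the excess-green index on chromatic coordinates,
   ExG = 2g − r − b with r = R/(R+G+B) etc., thresholded strictly at 0. The
   brightness-normalised form is used (not raw 2G−R−B) so the 0.0 threshold
   is exposure-invariant. An all-black pixel scores 0 by convention. The mask
   is taken from the **later** frame of each pair — a deterministic choice;
   union or intersection masks would also be defensible.
3. **Two-bin HOOF.** Each masked vector contributes its Euclidean magnitude
   to the downward bin when its vertical component v > 0 (row indices grow
   downward) and to the upward bin when v < 0; purely horizontal vectors
   (v = 0) contribute to neither, since horizontal motion carries no wilting
   information.
4. **Score.** Δwilt = (up − down) / masked-pixel count, in pixels per masked
   pixel. Negative values mean net downward leaf motion (wilting), positive
   mean recovery. Normalising by the masked count rather than the frame size
   makes the score independent of how much sky the camera sees.

Defaults w = 5 min and a 1-min moving stride: w is half the shortest
plausible irrigation interval, so no window can straddle two irrigations,
while still being long enough for leaf motion to exceed a pixel.

## Stem processing and irrigation control

Δstem(t) = stem(t) − stem(t−w) removes the diurnal trend and isolates the
irrigation-driven sawtooth. Gaps propagate; nothing is interpolated.

The relative stem ratio is rsr(t) = stem(t) / max(stem over the window since
the last irrigation, inclusive). It is 1 exactly at and immediately after a
reset and falls below 1 under shrinkage. The controller evaluates at the
1-min sensor cadence inside [sunrise, 19:00), where sunrise is the first
minute with PPFD ≥ 14.8 µmol s⁻¹ m⁻²; when rsr < T_rsr (default 0.9975) it
issues an event and resets the window so the next rsr is exactly 1.0000.
Strict `<` at the threshold and the half-open active window are fixed
conventions; the comparison direction at exact equality is unobservable on
real (noisy) data. No minimum-interval guard exists beyond the natural
reset. A data gap conservatively restarts the rsr window without an event.
Scattered-light sensors reporting lux are converted to PPFD by the fixed
divisor 54.

## Lagged cross-correlation

Per plant-day, on the 09:00–17:00 camera window and only for days with no
interior gaps (configurable), the cross-correlation at lag l is

    C(l) = [ (1/(n−|l|)) Σ_t Δstem(t−l) Δwilt(t) − μ_s μ_w ] / (σ_s σ_w)

with global (full-day) means and population SDs and the raw lagged product
sum divided by the per-lag overlap n − |l|. Positive l pairs Δwilt(t) with
the *earlier* Δstem(t−l), so a positive peak lag means stem variation
precedes wilting. This estimator is not a per-overlap Pearson coefficient:
at extreme lags it can slightly exceed 1 in magnitude, which is why lags with
overlap below 10 points are left undefined and the default search range
(±60 min) is small relative to n ≈ 476. The peak (R_max, l_max) is reported
both unrestricted and restricted to l ≥ 0; exact ties break to the smallest
|l|, then to the positive lag. Per-lag 99% confidence bounds use the
independent-white-noise null, z₀.₉₉₅/√(n−|l|) — correlated Δstem widens the
true null for autocorrelated *pairs*, but the null control below shows the
bound is calibrated when one series is independent noise, which is the
relevant negative control. Raw cross-correlation without pre-whitening is a
known limitation; spectral or pre-whitened variants are out of scope.

## Environmental regression

Daily predictor means (PPFD, VPD) are arithmetic means over [09:00, 19:00)
with missing minutes excluded and coverage reported. Five families are
fitted: linear, quadratic, continuous two-segment (piecewise) linear with a
fitted breakpoint, logarithmic, and exponential y = a·e^{bx} + c. The
piecewise fit is constrained continuous at the breakpoint — the standard
segmented-regression convention, and the only identifiable choice at
n ≈ 18 days; the breakpoint is profiled over midpoints between consecutive
distinct x values (closed-form least squares at each candidate) and then
refined by bounded scalar minimisation, which avoids the non-convexity of a
single-shot nonlinear fit. The exponential family is initialised from the
data (c near the response extremum on the flat side, b from the slope of the
log-shifted response); initialisation is its main failure mode and a
non-convergent family is reported as failed rather than fatal. Selection
maximises raw R² (adjusted R² is reported alongside); ties within 1e−9 go to
the family with fewer parameters, so exact lines select linear over
quadratic. Significance is an overall F test with k = predictor-side
parameters (the piecewise breakpoint counts toward k); this is a defined
convention, chosen because it reduces to the textbook regression F test for
the linear family.

## Synthetic study conditions

No public dataset accompanies this problem, so the generator is first-class,
tested code that defines the study conditions. It emulates: 1-min sampling;
cameras active 09:00–17:00 and sensors all day; a solar half-sine PPFD arc
(06:00–18:30, peak 80 µmol s⁻¹ m⁻² of *scattered* light, as measured inside
a shaded sensor box rather than direct sun) attenuated by a clipped AR(1)
cloud process; a diurnal temperature sinusoid with anti-phased relative
humidity, VPD from the Tetens relation.

Plant water status is a discrete-time reservoir chain soil → stem → leaf:

* transpiration E(t) = 0.01 · (PPFD/peak) · min(VPD, 4 kPa)/4 kPa per
  minute — the 4 kPa plateau models stomatal closure at high VPD;
* uptake replenishes half of the current stem deficit per minute, limited by
  the soil reservoir; each irrigation adds 0.05 reservoir units;
* stem diameter = 10 mm baseline + 0.05 mm/day growth + 0.5 mm per unit
  water status + N(0, 1 µm) sensor noise (laser-displacement-sensor scale);
* leaf water is stem water **delayed by D minutes** (default 2) and smoothed
  by a first-order filter with time constant τ. τ defaults to 1 min — i.e.
  effectively a pure transport delay — because a tightly converged lag with
  ±1-min scatter is only possible when leaf equilibration is fast compared
  with the delay; heavy smoothing would smear the recoverable lag. The
  brute-force latent-delay test shows the lag survives τ up to ~10 min here
  because irrigation produces sharp uptake transients;
* leaf-tip wilt displacement = 40 px · γ · max(0, −leaf water), a monotone
  non-increasing function of leaf water, with coupling gain γ (default 1).

Growth rate, noise magnitudes and the reservoir constants are plausible for
greenhouse tomato but not fitted to any measurement; the defaults produce
irrigation roughly every 8–15 min at midday under full sun, i.e. the regime
where the short-term sawtooth dominates Δstem.

The renderer draws a 144×144 scene — sky band, drifting achromatic cloud
ellipses, soil band, and a green stem with four leaf ellipses rotating
downward about their anchors by the wilt displacement — at 2× supersampling,
giving anti-aliased edges and sub-pixel motion. The palette guarantees exact
mask ground truth: any pixel with plant coverage has ExG > 0 and every
cloud/sky/soil pixel has ExG ≤ 0 (noise off). Clouds stay in the upper sky
so no matching window centred on a plant pixel can see one; this makes the
cloud-invariance property exact rather than approximate. The flow fast path
(`synth_flow_fields`) bypasses estimation entirely: masked pixels carry the
true displacement difference (plus optional iid noise with SD
`flow_noise_sd`, the generator's stand-in for flow-estimation error — 0.2 px
by default, 0 for exactness tests), off-mask pixels carry small noise.

What the generator does **not** emulate: photorealistic leaves, 3-D
geometry, leaf rolling, wind, occlusion by neighbouring plants, camera
exposure drift, or correlated sensor noise. Passing tests therefore
demonstrate that the pipeline recovers a known transport delay under
idealised imaging, not that it would do so on arbitrary field imagery.

## Verification experiments and problem sizes

The acceptance checks (mirrored in `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: 20 seeds per injected delay D ∈ {1..5} on the
flow fast path; one fully rendered day (481 frames) through block matching;
50 white-noise pairs (n = 100, ±20 lags) against a literal brute-force
implementation of the estimator; 100 zero-coupling cloudy seeds for the null
control; 100 seeds of log-law data for regression recovery; and 20 seeds per
coupling level γ ∈ {0.25, 0.5, 1.0}. The coupling sweep runs at
`flow_noise_sd` = 5 px so that measurement noise is non-negligible relative
to the weakest coupling — with noiseless flows the peak correlation is
scale-invariant in γ and the sweep would be uninformative. The regression
recovery uses 18 log-spaced predictor values over [1, 100] (equal
information per decade of a logarithmic law) and true parameters a = 3,
b = 5, keeping relative parameter error well-posed away from zero.

## Known limitations

* The cross-correlation estimator's n−|l| normalisation slightly inflates
  |C(l)| at large lags; peaks are searched within ±60 min of a 476-minute
  day, where the near-Pearson property holds to 0.02.
* Block matching cannot see motion below 0.5 px per window; very weak
  wilting on dull days scores as zero rather than small.
* The RSR controller replays deterministically from a recorded trace only
  if the trace itself was produced at 1-min cadence with the same threshold;
  gap handling (window restart) is conservative and can delay an irrigation
  after an outage.
* Regression model selection by raw R² inherently favours the piecewise
  family on small noisy samples; near-ties between log and piecewise fits
  are real and reported per family in `regression.csv`.
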