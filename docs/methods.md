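# Methods

## The normative model

For each frequency band, channel and sex stratum, the natural log of
absolute band power (µV²) is modeled as a smooth function of age plus
homoscedastic Gaussian noise:

    ln p_i = f(age_i) + eps_i,   eps_i ~ N(0, sigma^2).

`f` is a penalized cubic B-spline (P-spline). The basis uses 10 interior
knots at the age quantiles of the training cohort (quantile placement
keeps the basis well-conditioned when the age histogram is uneven) with
boundary knots at the observed age range. The roughness penalty is the
second-order *divided* difference of the coefficients taken over the
Greville abscissae, rescaled by the squared mean site spacing. On a
uniform knot grid this reduces to the familiar `[1, -2, 1]` stencil; on
non-uniform grids the divided-difference form is required for the
penalty's null space to be exactly the linear functions, so straight-line
age trends are reproduced exactly at any smoothing level (a tested
invariant).

The smoothing parameter λ is selected per component by generalized
cross-validation, GCV(λ) = n·RSS / (n − edf)², over a fixed logarithmic
grid 10⁻³…10⁴ (15 points). The grid and all sufficient statistics are
stored in the model file, so a fit is exactly reproducible and a stored λ
can be edited to obtain the consistent refit. Components share one basis
per model (the design depends only on the training ages), which makes
fitting all 114 band×channel components a single set of small linear
solves.

**Prediction interval and Z-score.** The predicted SD at age *a* is the
95% prediction-interval half-width divided by the normal 97.5% quantile
(1.959964):

    sd_pred(a) = sigma_hat * sqrt(1 + h(a)),
    h(a) = b(a)' (B'B + λP)⁻¹ B'B (B'B + λP)⁻¹ b(a),

i.e. the leverage-inclusive form that accounts for curve-estimation
uncertainty as well as residual scatter; with abundant training data
h → 0 and sd_pred → sigma_hat. `sigma_hat² = RSS/(n − edf)`. The
standardized index is z = (ln p − mean)/sd_pred; both mean and sd are
continuous in age, by construction — the property that motivates the
continuous model over age-band norms.

**Extrapolation.** Ages outside the training range are clamped to the
nearest bound and flagged (`age_clamped`), rather than extrapolating the
spline: validation subjects can legitimately exceed the normative age
span, and clamping is the conservative choice.

**Pooled model.** The sex-agnostic reference ("total") is the identical
procedure run on both sexes concatenated, with no sex covariate. Under a
true between-sex offset d its residual scale inflates to
sqrt(sigma² + d²/4), which is exactly why a stratified model scores a
same-sex anomaly more sharply — the contrast the validation module tests.

**Age-band baseline.** The rejected traditional approach is kept as a
comparison: contiguous windows of width 2×half_width (default 5-year
half-width), per-window mean/SD, each subject scored by the nearest
window; windows below 30 subjects recruit the nearest subjects by age.
Its z-scores jump at window boundaries (e.g. ages 49.9 vs 50.1 can fall
in different windows); the jump-size contrast with the spline model is
itself a tested property.

## Eligibility screening

Four gates: pre-screening history flags; cognitive function (any required
test below the 2nd percentile, or ≥3 below the 7th); emotional function
(any subdomain high-risk or ≥2 at-risk; for infants, K-CBCL
depression/anxiety percentile > 98); and a behavioral expert evaluation
for minors (modeled as a boolean flag). Instruments are age-group
specific (infants 4–6: K-WPPSI + digit span; 7–19: CNSVS; 20–49: CNSVS;
≥50: CNSVS + MMSE). Raw scores of the IQ-scaled instruments are converted
to percentiles via the normal CDF with mean 100, SD 15, which matches the
instruments' printed anchors (raw 70 ↔ ~2%, 80 ↔ ~9%, 90 ↔ ~25%,
109 ↔ ~74%). The MMSE has no percentile scale; it enters only the <7%
tally through its raw-score-25 anchor. A few boundary choices resolve
overlapping printed ranges: K-WPPSI ≤69 is "Extremely Low" (70–79
Borderline), CDI 21 is still "Normal", MMSE ≤9 is "Severe Dementia".
STAI risk bands are inclusive of both printed endpoints; the high-risk
band starts at the printed onset.

## Spectral extraction

Defaults: 250 Hz sampling, zero-phase order-4 Butterworth band-pass
1–45.5 Hz, 60 Hz mains notch (Q = 30; configurable to 50 Hz), common-
average reference, non-overlapping 4-s epochs rejected if any channel
exceeds ±100 µV, Welch PSD with 2-s Hann windows at 50% overlap (0.5 Hz
resolution), trapezoidal integration over band intervals. Amplitude-
threshold rejection is a deliberately simple artifact gate; it does not
attempt the subspace-reconstruction or ICA-based cleaning used by
commercial platforms. Band power is *absolute* (µV²); the log transform
is natural log. Bands are half-open [low, high); the integration grid
includes both edge bins so contiguous bands sum exactly to the integral
over their union. beta3 (25–30 Hz) is a sub-interval of beta, reported as
an extra feature; the edges of beta3 and gamma are conventional choices.

## The synthetic cohort generator

The generator emulates what the pipeline assumes about real cohorts, not
EEG morphology. Mean log band power follows a piecewise age trend — an
exponential-decay segment on [4.5, 20) joined continuously to a linear
segment on [20, 81] — parameterized per band so that delta/theta fall
sharply through childhood then flatten, alpha declines steadily after 20,
and the beta family rises after 20. A small deterministic regional
modulation (posterior-dominant alpha, frontal-dominant slow waves) varies
the trend across channels. Between-subject variation is Gaussian on the
log scale (default SD 0.3, so ±2 SD spans a ~3.3× power range), making
power lognormal — the right-skew that motivates the log transform. The
between-sex difference defaults to 0.15 log units on theta only, applied
±offset/2 so the pooled mixture SD is sqrt(0.3² + 0.075²). Ages are
uniform on [4.5, 81] (maximizing spline support). Screening scores are
drawn to pass every rule, except for a configurable fraction of subjects
given exactly one randomly chosen violation; the ground-truth label is
retained for oracle tests. The default fail fraction is 0 (an
all-eligible cohort); failure injection is opt-in.

Anomaly injection adds `shift × noise_sd` to the log power of chosen
band/channels, so `shift` reads directly as the target z-score against a
correctly calibrated model.

Raw EEG synthesis builds each channel as a sum over the partition bands
(delta, theta, alpha, beta, gamma) of brick-wall band-limited Gaussian
noise constructed in the frequency domain. A three-step fixed-point
calibration (i) zero-sums components across channels so downstream CAR is
a no-op and (ii) scales each component so the Welch band power of the
*filtered* composite (the same band-pass/notch the extraction stage
applies) matches the target. The synthesize→extract round trip recovers
partition-band log powers within ±0.1 for 240-s recordings (tested);
beta3 is not separately synthesizable since it lies inside beta. What
passing these tests does **not** show: robustness to real artifacts,
non-stationarity, alpha reactivity, or channel covariance — the generator
has none of these.

## Validation procedures

* **Calibration** — held-out normative subjects' z-scores pooled over all
  cells: mean ≈ 0, variance ≈ 1.
* **Effectiveness** — Pearson correlation between z-scores from the two
  in-repo models differing in age-regression method (continuous spline vs
  sliding window), per band and overall; this plays the role of a
  cross-database comparison with the age-regression method as the axis of
  difference.
* **Accuracy** — over ≥100 replicate anomalous subjects, mean |z| under
  the sex-matched stratified model ≥ mean |z| under the pooled model in
  the affected cells (the generative-model restatement of the
  stratification advantage; no claims about clinical neuroanatomy are
  made or tested).
* **Sex-difference decision tree** — Student's t if both groups pass
  Shapiro-Wilk and Levene's test (gate α = 0.05), Welch's t if only
  normality holds, Mann-Whitney U otherwise; constant groups route to
  Mann-Whitney with a note. The significance *map* threshold defaults to
  p ≤ 0.1 for display and is kept separate from the inferential α; no
  multiple-testing correction is applied by default (a Benjamini-Hochberg
  layer can be added by the caller on the returned p-values).

## Numerical choices and problem sizes

* GCV grid 10⁻³…10⁴, 15 log-spaced points; quantile knots, cubic degree.
* 97.5% normal quantile fixed at 1.959964 for PI↔SD conversion.
* Penalized systems solved by Cholesky; λ = 0 with excess knots raises an
  error advising λ > 0.
* Model files are versioned JSON of sufficient statistics (B'B, B'y, y'y
  per component), so persistence is lossless and refit-consistent.
* Test and acceptance problem sizes: 400/sex training cohorts with 200
  held-out subjects for calibration, 600/sex for parameter recovery and
  the cross-method correlation, ≥100 replicates for the anomaly contrast,
  240-s recordings for spectral checks. Trend recovery is assessed as the
  pooled RMS deviation between fitted and generative mean curves over a
  dense age grid: with 114 noisy curves the *pointwise maximum* grows
  with the number of components (boundary leverage dominates) and is not
  a stable summary at finite n, while pooled RMS directly measures the
  typical curve error (≈0.03 log units at 600/sex, tolerance 0.05).

## Known limitations

* Homoscedastic residual SD per component; no age-varying scale, no
  age×sex interaction smooths, no quantile norms.
* Eyes-closed and eyes-open are independent pipelines; no reactivity
  analysis.
* Sensor-level only; no source localization. The screening module
  classifies instrument *scores*; it does not administer or score items.
* The age-band baseline stands in for external traditional databases;
  montage/reference differences between real databases are not emulated.
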