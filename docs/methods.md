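# Methods

This note documents the models, estimators, parameter choices and known
limitations of `specsense`. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` compute.

## Recording model and protocol defaults

The analysis assumes graded-potential photoreceptor recordings digitized at
10 kHz: monochromatic isoquantal flashes from 310 to 630 nm in 10 nm steps,
4 repeats per stimulus at 1.5×10¹⁵ photons/cm²/s, a 9-level intensity
series spanning 4 log units of attenuation presented at the wavelength that
evoked the maximum response, and an optional adapting-LED condition
(534 nm, 3.2×10¹⁵ photons/cm²/s) recorded before, during and after the
background light. Each trace provides ≥500 ms of pre-flash baseline.
All protocol values are configurable (`SimExperimentSpec`,
`PipelineConfig`); the defaults above are the study conditions the
synthetic generator emulates.

## Synthetic-recording generator

`simulate_trace` is a forward model, not a biophysical one:

- **Baseline**: resting potential (default −52.7 mV) plus Gaussian white
  noise (default 0.5 mV per sample). No 1/f or line noise — a documented
  simplification; tests passing under white noise say nothing about
  recordings with strong slow drift.
- **Excitation**: amplitude `max_depol · NR(S(λ; λmax)·I)` where S is the
  cell's peak-normalized opsin template and NR the Naka–Rushton function
  (default n = 1, half-saturation 1.5 log units below the standard flash, so
  the standard flash sits at ~97% of saturation and the attenuation series
  brackets the sigmoid). `max_depol` defaults to 40 mV, above the 30 mV
  quality-control floor.
- **Kinetics**: difference of exponentials, rise τ = 10 ms, decay
  τ = 80 ms, beginning `base_latency` = 15 ms after flash onset. Kinetics
  are a design choice (the analysis nowhere depends on their exact form);
  they place half-max response durations in the tens-of-ms range typical of
  graded-potential photoreceptors.
- **Opponent inhibition**: inhibited cells receive a hyperpolarizing
  component whose amplitude follows the quantum catch of a long-wavelength
  driver template (λmax 550 nm for UV cells, 600 nm for blue cells — the
  spectral classes whose probe wavelengths are 530 and 590 nm respectively)
  scaled by `inhibition_gain` (default 0.3 of `max_depol`), delayed by
  `inhibition_delay` = 5.4 ms relative to the excitatory onset.
- **LED adaptation**: phenomenological — multiplicative amplitude
  attenuation and an additive resting-potential offset. Defaults: green
  cells 0.209 gain and +5.6 mV (the background light tonically depolarizes
  them); inhibited UV cells −5.6 mV and 0.75 gain; non-inhibited UV cells
  −1.4 mV and 0.55 gain (the larger amplitude loss without inhibition
  mirrors the observed direction). The LED also shortens the decay time
  constant (×0.6), so response durations contract under the background.
- **Flash duration** is not part of the emulated protocol's description;
  the default is 300 ms, configurable.

The seven-group experiment design (`FIG_GROUP_DESIGN`) uses the published
UV-cell sample sizes (43, 40, 18, 19, 8, 30, 22 cells over 12, 14, 9, 9, 4,
16, 10 individuals) with group inhibition probabilities equal to the pooled
observed prevalences (0.708 yellow-preferring, 0.468 no-preference, 0.167
white-preferring, 0.192 for *melpomene* males and females) and group mean
λmax values spread over the observed 345–404 nm range (SD 8 nm, truncated).

## Rhodopsin template

The Govardovskii et al. (2000) A1 alpha-band template is used with its
published constants. Two implementation choices:

- **Alpha band only.** The beta band is omitted: over 310–630 nm the alpha
  band dominates the fitted classes, and red-shifted LW cells whose tuning
  is shaped by screening pigments are classified but not modeled.
- **Peak re-centering.** The raw alpha-band expression peaks up to ~1 nm
  away from nominal λmax at short wavelengths (the `a` constant drifts with
  λmax). Evaluation rescales x by the band's argmax so the curve attains
  its maximum exactly at λmax; the shape is unchanged. This guarantees the
  peak-location contract (within half a grid step) on any grid.

## Sensitivity estimation

The V–log(I) series is fitted by unweighted least squares in
(Vmax, log₁₀K, n) with analytic-free `scipy.optimize.least_squares`,
initialized from the curve itself. Degenerate series (fewer than 5 levels,
response indistinguishable from noise, grossly non-monotone) return a
flagged failure; the per-cell analysis then substitutes a class-default
exponent (n = 1) with the protocol's top-of-sigmoid half-saturation and
flags the cell.

Mean responses are inverted through the fitted curve:
I_eq(λ) = K·(V/(Vmax−V))^(1/n), S(λ) = I_eq(λ)/I₀, peak-normalized.
Responses at or above Vmax are clamped to 0.999·Vmax and logged.
Hyperpolarizing mean responses are set to S = 0, excluded from template
fitting, and kept as an annotation — they reflect inhibition, not opsin
absorption.

λmax is estimated by a 1 nm grid scan of the sum of squared deviations
between peak-normalized sensitivity and peak-normalized template over the
search range (default 330–650 nm; ties break toward the smaller λmax),
followed by bounded scalar refinement (±2 nm bracket, tolerance 10⁻⁴ nm).
The fit is unweighted and on the linear sensitivity scale: measurement
noise is approximately additive in the mV-derived sensitivities at this
signal-to-noise ratio. A log-weighted variant was considered and not
adopted; the choice matters only deep in the tails where measured
sensitivities are near zero. Fits with r² below 0.5 are flagged
unreliable.

**Known limitation — opponent contamination.** In strongly inhibited
cells the delayed hyperpolarizing component overlaps the excitatory
response even at the peak wavelength, reducing measured amplitudes and
occasionally clamping several near-saturation bins; such cells' λmax fits
degrade and carry low r². Pipeline truth-checks therefore report λmax
agreement over reliable fits (r² ≥ 0.8) with the reliable count alongside.
Classification (class and inhibition labels) is unaffected.

## Trace features

- Baseline mean/SD: the 500 ms window ending at flash onset.
- Onset latency: first post-onset departure from the baseline mean
  exceeding 5 baseline SDs, sustained for ≥1 ms (at 10 kHz, unsustained
  single-sample 5σ crossings occur by chance in long traces). If the
  baseline SD is exactly zero (noise-free synthetic traces), a floor of
  0.05 mV substitutes. Latency is undefined (None) when no crossing
  occurs. **Estimator bias**: the crossing time trails the generative
  onset by roughly threshold/(amplitude × initial slope); ~0.1 ms for a
  ~40 mV response, growing to ~0.5 ms when attenuation reduces the
  response to a few mV. Latency *differences* between strong responses
  inherit only the differential part of this bias.
- Amplitude: signed extremum of the repeat-averaged trace within 500 ms
  after onset, relative to the baseline mean, after a 5 ms boxcar low-pass.
  Without smoothing the extremum of ~5000 noisy samples is biased upward
  by the expected maximum of the noise, which the near-saturation
  Naka–Rushton inversion amplifies drastically. Latency is always measured
  on the unsmoothed trace. Repeats are averaged before feature extraction;
  per-repeat features remain available for variance estimates.
- Half-max duration: total time above 50% of the peak depolarization,
  summing disjoint intervals, with linear interpolation at crossings.
- Adaptation deltas: resting shift (during − before), amplitude ratio
  (during/before) and recovery (after/before) at the peak wavelength;
  recovery < 80% fails quality control.
- Cell QC: maximum depolarization < 30 mV, LED recovery < 80%, or
  baseline drift > 10 mV/s (the drift bound is this package's choice) fail
  the cell; QC-failed cells are excluded from group statistics.

## Classification

λmax partitions: UV [330, 420), blue [420, 500), green [500, 580) with
template r² ≥ 0.8, redLW ≥ 580 nm. The boundaries are this package's
choice, placed with wide margins between the observed clusters (UV
345–404, blue ≈ 470, green ≈ 550, red-shifted > 600). A shape override
precedes the partition: a cell whose half-max bandwidth relative to its
λmax exceeds 1.5× the template's own relative bandwidth is labeled
broadband (blue + LW co-expression produces such curves regardless of the
fitted peak).

Inhibition: probe wavelength 530 nm (UV) or 590 nm (blue), nearest
measured wavelength used. The cell is inhibited when the repeat-mean probe
response is hyperpolarizing with magnitude above 5·SD/√n_repeats — a
one-sided criterion on the standard error of the mean response, chosen
over a t-test because 4 repeats give an unstable variance estimate. The
signed probe amplitude normalized by the peak amplitude is retained for
amplitude-based (non-binary) analyses.

## Group statistics

- Proportions carry the binomial SE √(p(1−p)/n); this estimator exactly
  reproduces the published ±SEM values for all four UV preference groups,
  so it is adopted as the study's estimator. (For the pooled blue summary
  the binomial SE gives 4.4% where 4.5% was printed; the package reports
  the binomial value.)
- Logistic GLMM: single random intercept per individual, Laplace-
  approximated marginal ML (adaptive quadrature is unnecessary for one
  random intercept at these cluster sizes; the Laplace fit matches
  `lme4::glmer` to ~10⁻³ in the test suite). Fixed-effect SEs come from
  the observed information at the optimum with the variance held at its
  estimate; Wald statistics are reported as t-statistics with a normal
  reference, and pairwise group contrasts are not multiplicity-corrected
  (per-pair thresholds are reported instead). Complete separation triggers
  a weak Gaussian penalty (prior SD 2.5 logits) and a flag. As σ → 0 the
  likelihood reduces to ordinary logistic regression, verified against
  statsmodels `Logit`.
- Linear mixed model for λmax: statsmodels `MixedLM` (ML, not REML); at
  the σ = 0 boundary, where its Hessian becomes singular, the model
  degenerates to OLS and is reported as such.
- One-sample t-tests of λmax against expected opsin tuning use Bonferroni
  correction over the declared number of comparisons.
- Half-max durations across photoreceptor types: one-way ANOVA plus
  Tukey's HSD with a compact letter display (insert-and-absorb
  construction).
- Unimodality screening of λmax distributions counts KDE modes; for
  questions at the opsin-separation scale a bandwidth of ~5 nm is
  appropriate (UV1/UV2 peaks are ~35 nm apart), while Silverman's rule is
  the default for generic use. This is a screen, not a formal dip test.

## Perception

Excitation is the trapezoidal integral ∫R(λ)S(λ)L(λ)dλ on a 1 nm grid with
a flat illuminant by default (a measured daylight spectrum can be supplied
as a file). Three normalizations are reported: the raw integral; the
adapted catch (divided by ∫S·L dλ) — the invariant quantity when asking
whether a wing drives differently tuned receptors "identically", since the
raw integral scales with template bandwidth and hence with λmax; and a
per-λmax normalization to the most excitatory wing color. No
receptor-noise color space is used: the question is single-receptor drive,
not discriminability.

Synthetic wings: white is flat (0.85 reflectance, 300–700 nm); yellow is a
logistic edge at 420 nm (width 12 nm) rising to the white level, near zero
below — the defining difference being presence versus absence of
reflectance below ~420 nm.

## Problem sizes in the shipped checks

The test suite and acceptance script use: 200 cells for noisy λmax
recovery (sensitivity-stage noise SD 0.05, matching the derived
specification of that check), 4 zero-noise cells through the full
trace-level pipeline, 50 noiseless inhibited cells for the latency delay
(20 for the intensity-stability sweep over 2 log units), 100 replicates
for Naka–Rushton noise recovery, 150 null replicates × 21 pairwise
contrasts for GLMM type-I calibration and 400 replicates for CI coverage,
and the full published seven-group design (180 cells) for the end-to-end
prevalence recovery. These sizes make the checks statistically meaningful
while keeping a full run in minutes on one core.

## What passing tests do and do not show

The generator produces white-noise, template-true, Naka–Rushton-true cells.
Passing tests demonstrate that the estimators are correct and calibrated
under the stated model — they do not certify performance on recordings
with electrode drift, non-template pigments (beta bands, screening
pigments), adaptation during the spectral series, or non-Gaussian noise.
The QC stage (amplitude, recovery, drift) is the only guard against such
violations.
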