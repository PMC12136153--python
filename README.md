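# specsense

Analysis of intracellular photoreceptor recordings from butterfly compound
eyes: spectral sensitivity estimation, rhodopsin-template tuning fits,
inter-photoreceptor (color-opponent) inhibition classification, group-level
mixed-model statistics, and wing-reflectance × opsin-absorption perception
modeling — plus a synthetic-recording generator so the entire pipeline is
testable end to end without physiological data.

## Who this is for

Sensory neurophysiologists and visual ecologists who record graded-potential
responses of photoreceptors (PRs) to monochromatic flashes and need a
reproducible path from raw time–voltage traces to per-cell tuning estimates
and population comparisons. The motivating system is *Heliconius*
butterflies, where variation in UV photoreceptor tuning and in green-driven
inhibition onto UV cells relates to divergent male courtship preferences
for white versus yellow wing color.

## The models at the core

**Rhodopsin template.** Spectral sensitivity of a photoreceptor is fitted
with the Govardovskii A1 alpha-band template

    S(x) = 1 / (exp[A(a − x)] + exp[B(b − x)] + exp[C(c − x)] + D),
    x ∝ λmax / λ,   a = 0.8795 + 0.0459·exp(−(λmax − 300)² / 11940),

with A = 69.7, B = 28, b = 0.922, C = −14.9, c = 1.104, D = 0.674, leaving a
single free parameter λmax (evaluation is re-centered so the peak sits
exactly at λmax).

**Naka–Rushton intensity–response inversion.** The V–log(I) series at the
cell's best wavelength is fitted with V(I) = Vmax·Iⁿ/(Iⁿ + Kⁿ). Isoquantal
spectral responses V(λ) are then inverted to an equivalent intensity
I_eq(λ) = K·(V/(Vmax − V))^(1/n) and the peak-normalized sensitivity
S(λ) = I_eq(λ)/I₀, which the template is fitted to by least squares.

**Opponent inhibition.** A UV or blue cell is scored *inhibited* when its
repeat-mean response at the probe wavelength (530 nm for UV, 590 nm for
blue) is hyperpolarizing beyond 5·SD/√n of the pre-flash baseline. Response
onset latency is the first sustained crossing of 5 baseline SDs; inhibitory
responses lag excitatory ones by the monosynaptic delay (~5.4 ms).

**Group inference.** Inhibition prevalences carry binomial standard errors
√(p(1−p)/n). Group comparisons use a logit-link mixed model with a random
intercept per individual butterfly, estimated by Laplace maximum likelihood
(implemented in `specsense.mixed`, cross-checked against `lme4::glmer`);
λmax comparisons use a Gaussian mixed model (statsmodels `MixedLM`).

**Perception.** Receptor drive by a wing is the quantum-catch integral
E = ∫R(λ)·S(λ)·L(λ)dλ (flat illuminant by default), reported raw, relative
to the template integral (adapted catch), and normalized across wing colors.

## Worked example

```bash
python examples/02_simulate_recording.py
```

prints

```
  380 nm: amplitude  +36.9 mV (depolarizing), latency 15.3 ms, baseline -52.7 mV
  550 nm: amplitude  -11.7 mV (hyperpolarizing), latency 21.6 ms, baseline -52.7 mV
```

— a UV cell (λmax 380 nm) resting at −52.7 mV depolarizes ~37 mV to its
preferred wavelength, while green light evokes a hyperpolarization whose
onset lags by ~5.4 ms + threshold-crossing time: the signature of
monosynaptic inhibition from long-wavelength photoreceptors. The remaining
examples (`examples/01`–`07`) walk through template fitting, sensitivity
inversion, inhibition classification, group statistics (e.g. the
yellow-preferring groups' 70.8 ± 6.6% inhibition prevalence from 34/48
cells), wing-perception sweeps, and the end-to-end pipeline.

A thin CLI mirrors the library for shell use:

```bash
specsense simulate --seed 1 --out traces/     # write synthetic trace TSVs
specsense run --traces traces/ --out results/ # extract→fit→classify→stats
```

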