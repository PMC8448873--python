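# Methods

`thetasync` re-implements, as a tested pipeline, an analysis of how
familiarity moderates the association between theta-band (4–8 Hz)
inter-electrode phase synchronization and continuously reported
music-evoked pleasantness. Because no suitable recordings are publicly
deposited, the package pairs the analysis chain with a synthetic-data
generator that plants known effects, so every stage can be verified by
parameter recovery. This note describes the models, the generator, the
numerical choices, and what the tests do and do not establish.

## The analysis chain

**Behavior.** During listening, participants hold numeric keys 1–5 for as
long as each degree of evoked pleasantness applies. A trial's index is the
hold-duration-weighted mean key value; a trial with no response before half
the excerpt has played is halted and rejected. Indices are dichotomized per
subject at that subject's median ("least"/"most" pleasant; values equal to
the median code as "most"; even counts use the midpoint of the central
order statistics). Familiarity is rated on a 7-point scale after each
excerpt; an excerpt rated above 2 in the exposure session, or in the new
condition of the experimental session, is excluded from **all** of that
subject's conditions. Simultaneous key holds (possible in raw keyboard
logs) are resolved by latest-onset-wins truncation. A halted trial removes
that excerpt entirely for the subject, the same rule as a familiar excerpt.

**EEG.** Recordings (250 Hz, 61 scalp electrodes in 10-10 positions plus
two mastoids) are re-referenced to linked mastoids, band-pass filtered
0.1–45 Hz with a zero-phase 4th-order Butterworth (forward–backward,
second-order sections), cut into whole-listening epochs, and
baseline-corrected with each channel's full-epoch mean. Epochs in which any
channel's mean absolute amplitude exceeds 100 µV are rejected. A
spherical-spline surface Laplacian (current source density) makes the data
reference-free and attenuates volume conduction; the first and last 2 s of
each epoch are then removed (this also absorbs wavelet edge artifacts: at 4
Hz a 5-cycle wavelet's half-length is 0.625 s). Instantaneous phase comes
from 5-cycle complex Morlet wavelets on a 1-Hz grid {4,5,6,7,8} Hz.

**Connectivity.** For each retained trial, electrode pair and frequency,
inter-site phase clustering over time is

    ISPC_f = | n^-1 Σ_t exp(i(φ_it − φ_jt)) |,

the resultant length of the phase-difference series; values are averaged
across the frequency grid and compressed into the open unit interval with
y′ = (y·(N−1) + ½)/N (N = observations per pair fit), applied
unconditionally so every response undergoes the same monotone map.
Averaging happens after the modulus (ISPCs are averaged, not complex
vectors). Analysis pairs are all combinations of 45 frontal/temporal/
parietal electrodes, minus pairs involving the peripheral set (Fp1/2,
FT9/10, TP9/10) and pairs closer than 6 cm. Distance is the 3-D Euclidean
chord on a spherical head model (default radius 9.2 cm, a common adult
value); whether the 6 cm rule should be chord or along-scalp distance is
ambiguous, chord is used and configurable. Electrode positions are the
idealized spherical Easycap layout (vertex at (0,0,r)).

**Inference.** Three Bayesian multilevel model families:

* *Cumulative-probit* for familiarity ratings: a unit-variance latent
  normal with six ordered thresholds; condition slopes β₁ (exposure − old)
  and β₂ (new − old) in latent-SD units, with β₂ − β₁ derived on the draws.
* *Student-t linear* for trial pleasantness: identity link, β₁ = old − new.
* *Beta regression with logit link* for ISPC: design intercept +
  pleasantness + familiarity + interaction (reference new/least);
  mean–precision parameterization with precision φ. The moderation of the
  pleasantness–synchronization association by familiarity is β₃; post-hoc
  simple effects are PH_new = β₁ and PH_old = β₁ + β₃, formed element-wise
  on the draws, never by interval arithmetic.

Every fixed effect has an independent subject-varying counterpart with its
own scale (no correlation structure), fitted non-centered (u = z·σ,
z ~ N(0,1)). Priors: normal(0,1) on coefficients and thresholds;
gamma(shape 2, rate 2) on varying-effect standard deviations; gamma(0.01,
0.01) on φ; half-student-t(scale 10, df 3) on the residual scale; gamma(2,
0.1) on the student-t normality parameter. Gamma priors are shape–rate.

Decisions use the 95% highest-density interval against a region of
practical equivalence of ±0.01: "nonzero" if the HDI lies wholly outside
the ROPE, "practically-null" if wholly inside, "undecided" otherwise (an
alternative ROPE-overlap-probability rule was considered and rejected in
favor of the crisper trichotomy). Point estimates are posterior modes
(Gaussian KDE, Silverman bandwidth, grid argmax). Pairs are fitted
independently ("mass-univariate"); multiplicity is handled only through the
HDI+ROPE rule. A pair is *reportable* when β₃ is nonzero **and** at least
one post-hoc simple effect is nonzero. Convergence is declared when
split-R-hat of every reported coefficient is ≤ 1.01; an unconverged fit is
reported as such, never silently included (after up to two automatic
retries at the full sampling budget with fresh seeds — transient warmup
failures at reduced budgets are common and benign).

## Sampling

The default sampler is a self-contained No-U-Turn sampler (dynamic
Hamiltonian Monte Carlo): slice formulation, iterative tree doubling with
checkpointed sub-tree U-turn tests, dual-averaging step-size adaptation
(target acceptance 0.8), and a three-phase warmup that estimates first a
diagonal and then a dense metric — the regularized covariance of a warmup
window, shrunk toward its diagonal — because the multilevel designs induce
strong coefficient correlations that a diagonal metric leaves behind.
All chains start exactly at the origin of the unconstrained space;
randomness enters only through momenta and tree directions, seeded per
chain, so runs are exactly reproducible. Model log-densities and their
hand-derived analytic gradients are implemented twice: a vectorized numpy
reference, and numba-compiled scalar kernels used by the sampler; the test
suite asserts float-level agreement between the two and checks the
gradients against finite differences. An affine-invariant ensemble sampler
(emcee) is available as an alternative backend and serves as an
independent cross-check of the NUTS posteriors in the tests.

Budget tiers: **full** = 5 chains × 2000 iterations (first 1000 warmup),
**desk** = 4 × 1500 (600), **smoke** = 4 × 1000 (400). The full tier
mirrors the study-scale budget; smoke is used throughout the test suite.
A practical note on the convergence rule: with ~2400 kept draws the
sampling noise floor of split-R-hat itself is ≈1.005–1.01, so occasional
threshold crossings at reduced budgets reflect diagnostic noise as much as
sampler quality — hence the automatic full-budget retry.

The HDI uses the sorted-window (shortest-interval) construction with one
refinement: the raw argmin of the noisy window-width curve converges at a
cube-root rate, so the window position is taken from the vertex of a local
quadratic fit to the width curve, restoring near-root-n endpoint accuracy
(±0.005 at 10⁶ draws) without changing the estimand.

## The synthetic-data generator

The generator emulates the study design: n subjects × (30 "old" + 30
"new") excerpts, 45 s epochs at 250 Hz (sizes configurable), continuous
key-hold pleasantness streams, 7-point familiarity ratings from a
cumulative-probit generative model, and multi-channel EEG with planted
condition-dependent theta coupling.

**Coupling mechanism.** Each designated pair carries theta oscillations at
every analysis frequency (power split across {4..8} Hz so the
band-averaged ISPC sees the coupling at each grid point). The two
electrodes share one phase process per frequency; the second electrode
adds a fixed lag (π/4) plus a von Mises(κ) offset. Because E[resultant
length] of von Mises draws is the Bessel ratio A(κ) = I₁(κ)/I₀(κ), κ is
obtained by root-finding so that A(κ) equals the inverse-logit of the
planted linear predictor β₀ + β₁·most + β₂·old + β₃·most·old + subject
deviation + trial noise. The offset is piecewise-constant in blocks
(default 1.5 s, longer than the wavelet) so the planted phase statistics
survive time–frequency smoothing; per-sample i.i.d. jitter would be
low-pass filtered away by the wavelet. Uncoupled channels receive their own
block-wise *uniform* phase offsets, so any pair involving them has
i.i.d.-uniform per-block phase differences — the κ = 0 null, whose
per-trial ISPC distribution is the resultant length of n_blocks uniform
draws. In single-oscillator configurations this law is exact (verified
against a Monte-Carlo oracle by a Kolmogorov–Smirnov test); with the
multi-component default, beating between a channel's independently-phased
band components decoheres null pairs somewhat further, which only widens
the margin between null and coupled pairs. All channels ride on 1/f
background noise (exponent 1.0) in a
physiological microvolt range; coupled sources carry a configurable
amplitude gain (default 2.5) so their local phase remains dominant through
the spatial-derivative CSD transform, which otherwise mixes in neighbours'
independent phases. Artifact trials add a large slow drift that the 100 µV
rule catches; reproducibility is guaranteed by counter-based per-trial
random streams derived from one master seed.

**Behavioral truths.** Defaults mirror the study-scale effects: a 2.34
latent-SD familiarity shift for re-exposed music, a +0.12 mean-key
pleasantness shift for old music, exposure/new ratings concentrated on
categories 1–2, and a configurable fraction (8%) of genuinely familiar
excerpts plus halting (2%) and artifact (5%) rates that together produce a
~15% rejected-trial proportion.

**What the generator does *not* emulate.** Biophysical forward modelling
(sources are planted at electrodes, not in cortex), ocular/muscle artifact
morphology beyond amplitude outliers, mains noise, inter-subject
anatomical variability, and any genuine relation between the music and the
signals. Passing tests therefore demonstrate that the *pipeline* recovers
what it assumes — not that the assumptions hold for real EEG.

## Scaled-down study conditions used by the tests

Model-level parameter recovery runs 50 replicates per family at 6 subjects
× 20 trials (8 × 30 for the ordinal model, whose cheap likelihood affords
the larger n that keeps prior shrinkage of a −1.5 latent-SD effect
negligible), checking 95% HDI coverage within 95 ± 8 points and a ≤10%
false-"nonzero" rate on a coefficient planted at zero.

The end-to-end detection study uses 6 subjects × 20 excerpts, a 17-channel
subset, 30 s epochs, 12 analysis pairs with the interaction planted at
exactly two of them. The planted β₃ is 2.0 log-odds (coupled-pair ISPC
rising from ≈0.3 to ≈0.8 between conditions): at this n the interaction
posterior carries a ≈0.4–0.5 log-odds credible half-width, and the
measurement chain attenuates planted log-odds differences (finite jitter
blocks inflate small resultants; estimation noise and residual CSD mixing
compress the top), so the study-scale effect magnitudes (~0.15) are not
detectable here by design. The whole-pipeline *coverage* property is
instead tested in the small-effect regime (β₃ = 0.5, full 45 s epochs, one
pair), where attenuation bias is small relative to posterior width; eight
replicates with a pre-registered ≥6/8 coverage bound.

## Numerical choices and degenerate inputs

* Spherical-spline Laplacian: order m = 4, 50 Legendre terms,
  regularization 10⁻⁵ (standard published values), output scaled by the
  squared head radius to µV/cm². Fewer than 16 channels is an error.
* Wavelet edge handling: samples within half a wavelet of either epoch
  edge are marked invalid per frequency and dropped from the ISPC sum
  (never imputed); with the 2 s trim no invalid sample survives anyway.
* Ordinal thresholds are parameterized as first threshold plus log
  increments, so every draw is strictly ordered by construction; a rating
  category never observed still yields finite threshold estimates through
  the prior.
* All-constant draws make split-R-hat 0/0; it is reported as 1.0 with a
  warning. A median split over identical indices codes every trial "most"
  and warns.
* Beta responses at exactly 0 or 1 raise an error pointing to the
  boundary adjustment rather than silently clamping.
* The amplitude-rejection criterion is the per-channel mean of |x(t)|
  after baseline correction (a pure offset is removed by baselining and
  does not reject).
* Independent-component artifact correction is deliberately not
  re-implemented: it targets real ocular/muscle artifacts that the
  generator does not produce; the amplitude criterion carries the
  rejection role on synthetic data.

## Known limitations

* The measurement chain attenuates planted interaction magnitudes (see
  above); absolute effect sizes recovered from synthetic EEG are
  conservative, and the attenuation grows with effect size.
* The dense-metric NUTS assumes a roughly Gaussian posterior geometry
  after warmup; heavy multimodality would defeat both the metric and the
  R-hat retry logic (not observed in these models).
* Split-R-hat at smoke budgets operates near its own noise floor; the
  1.01 rule is meaningful at the full tier and is enforced there via the
  retry path.
* The per-pair independence of the mass-univariate step ignores spatial
  correlation between overlapping pairs; that mirrors the analysis being
  reproduced and is not a statistical recommendation.
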