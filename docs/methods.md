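# Methods

This note documents the models, defaults and design choices behind
`spongesaxs`, and what the synthetic-data tests do and do not demonstrate.

## Scattering model and reduction

Momentum transfer is q = 4π·sin θ/λ with θ half the scattering angle; all q
are in nm⁻¹, wavelengths in nm, angles in radians internally.  Default
geometry: Cu Kα (λ = 0.154 nm), sample–detector distance 2507 mm, pixel
pitch 0.172 mm (Pilatus-class; the pitch is configurable since instruments
differ).

Frame correction is `(frame − dark − transmission·empty) /
(exposure_time · flatness · absorption)` with every omitted factor an
identity; full instrument calibration chains (reference samples, exposure
scheduling) are out of scope.  Azimuthal averaging uses equal-width q bins
(default 256) with the bin value at the bin centre; per-bin sigma is the
standard error of the contributing pixels, with a Poisson √N fallback for
single-pixel bins.  A flat-detector mapping (θ = ½·arctan(r/D)) is used; at
the sub-degree angles involved the small-angle error is negligible.

**Outlier screening.**  No published criterion exists for matrix-mode
replicate screening, so the package uses a robust z-score — deviation from
the median scaled by 1.4826·MAD — of total curve intensity over the fit
window (0.038–0.2 nm⁻¹), flagging |z| > 3.5 in either direction.  Low
outliers are empty positions (no feather in the beam); high outliers are
cosmic-ray artefacts.  When MAD = 0 (replicates identical), any deviation
from the median is flagged.  Spikes that land outside the screening window
do not perturb the fit and are deliberately not chased.

**Normalization and averaging.**  Replicate curves are first divided by
their mean intensity over the window; the pointwise median of these
unit-level curves is the reference, and each raw curve is scaled onto it by
the closed-form least-squares factor s = ⟨I, m⟩/⟨I, I⟩ (clamped at 0).
Using the median of *unit-mean* curves rather than raw curves makes the
result exactly invariant to rescaling any single input — the property the
normalization exists to provide.  The output is the pointwise mean of the
scaled curves with the across-replicate standard error as sigma; the
absolute intensity scale is arbitrary, which is why peak heights are always
measured relative to the fitted baseline.  Whether exposures are averaged
before or after azimuthal averaging is immaterial for these linear
operations on a shared grid; this implementation averages curves.

## Porod-space peak model

The fitted model is a constant baseline plus two Gaussians parameterized by
half width at half maximum:

    y(q) = c + a₁·exp(−ln2·(q−q₁)²/h₁²) + α·a₁·exp(−ln2·(q−β·q₁)²/h₂²)

with q₂ ≡ β·q₁ and a₂ ≡ α·a₁.  A peaked profile requires the negative
exponent and the width in the denominator; HWHM is the declared width
measure, giving y(q₁ ± h₁) = c + a₁/2 when the secondary peak is far.

The fit minimizes the unweighted sum of squared residuals over
0.038 ≤ q ≤ 0.2 nm⁻¹ (a `weighted` flag enables 1/σ weighting) using
bounded trust-region least squares (lmfit/`least_squares`, ftol/xtol/gtol
10⁻¹², max 5000 evaluations).  Bounds bracket the observed peak regions
generously: q₁ ∈ [0.038, 0.07], h₁, h₂ ∈ [10⁻⁴, 0.05], a₁ ≥ 0, α ∈ [0, 2],
β ∈ [1.3, 2.2], c ≥ 0.  α and β are fitted freely within bounds.  Initial
values are data-driven: baseline from the smoothed window minimum, primary
peak from the highest smoothed local maximum below 0.06 nm⁻¹ (lowest q wins
ties — the UV-side peak is primary; fallback 0.045 with a warning when no
maximum exists), width from the half-prominence width with a 0.007 fallback,
and canonical ratios α₀ = 0.3, β₀ = 5/3, h₂₀ = 0.012.  Non-convergence
returns the best-found parameters flagged `converged=False`.

Derived quantities: Bragg spacings d = 2π/q (nm) and amplitude transforms
ln(a + 10⁵).  The logarithm base is not standardized anywhere; the natural
log is used and recorded in the result metadata (any base is a monotone
equivalent).

## Colourimetry

Spectra are linearly interpolated onto the canonical inclusive 1-nm grid
320–700 nm.  Brightness is the grid mean; hue is the argmax wavelength
(lowest wavelength on ties; no smoothing by default, an optional boxcar flag
exists for noisy instruments).  "UV reflectance divided by brightness" is
ambiguous between band-sum and band-mean conventions; the default is
band-mean/brightness, so a flat spectrum scores exactly 1, with
band-sum/full-sum available (flat spectrum → 81/381 ≈ 0.2126).  The two
differ by a constant factor and are rank-equivalent; the convention used is
recorded in output metadata.  Replicates are averaged at the variable level
(mean of per-replicate brightness/chroma/hue), not at the spectrum level.

## Hue prediction

λ = 2·(2π/q₁)·n_avg.  The averaging rule behind n_avg is taken as the
linear volume-weighted mean of refractive indices, which reproduces the
canonical 1.33 from keratin index 1.58 at volume fraction 0.57 with air at
1.0; a squared-index (dielectric) mixing rule is available as an option.
"Density" 0.57 is interpreted as the keratin volume fraction.  Sex-specific
fractions are supported but default to the sexually uniform value.

## Cohort statistics

All p-values are two-sided; no multiplicity correction is applied.
Within-sex standardization uses the n−1 sample standard deviation.  The
variance-ratio F-test puts the larger variance in the numerator and doubles
the upper tail.  Pearson p-values use the t transform with n−2 df.

**GLMs.**  Ordinary least squares with sum-to-zero (deviation) contrasts
for categorical factors (sex, year).  Deviation coding matters: with
dummy coding and unbalanced sexes the x×sex column nearly aliases x, and
the main effect's null rejection rate inflates visibly; with deviation
coding all per-term null rates calibrate at the nominal level.  Backward
elimination repeatedly drops the least-significant removable term with
p > α (default 0.05), where a term is removable only if no retained
interaction contains it (marginality).  After convergence each dropped term
is reintroduced alone into the final model to report its F/df/p; retained
terms report their partial (type-III-style) F in the final model.  Note a
structural consequence of marginality: under a pure null, a main effect's
*retention* rate is approximately α plus the probability that its
interaction survives (~2α total), while its *reported p* remains calibrated
at α.  Year enters as an ordinary factor; no year standardization is
applied.

**Varimax orthogonalization.**  All principal components of the correlation
matrix are retained and the orthonormal eigenvector matrix is
varimax-rotated (classic iterative-SVD algorithm).  Scores are computed
from the whitened component scores, Z·V·Λ^(−½)·T, so they are exactly
uncorrelated — any orthogonal rotation of whitened scores preserves the
identity covariance — while the returned loading matrix V·T stays
orthonormal.  Rotating V·Λ^(½) instead would give the conventional
factor-analysis loadings but loses loading orthonormality; the package
prioritizes an orthonormal rotation plus exactly decorrelated scores, which
is what the downstream collinearity check needs.

**Residual dichromatism.**  The regression is fitted on males only (the
larger sample); residuals for all rows from the male coefficients are
compared between sexes with a pooled t-test.  If every residual is
numerically zero (both sexes exactly on the male line) the test is reported
as t = 0, p = 1 rather than a ratio of rounding noise.

**Paired hue comparison.**  With a two-level within factor, the
repeated-measures interaction is exactly the between-sex comparison of
difference scores (estimated − measured), implemented as a pooled t-test
(reported also as F = t²); per-sex paired t-tests and mean differences are
the post hoc summaries.  This difference-score equivalence avoids a bespoke
mixed-model engine.

**Repeatability.**  Parameters are sex-standardized within each round and
correlated across rounds.  The sex difference in repeatability is tested as
the sex × round-1 interaction in a linear model for the round-2 value, as
is conventional; because that pooled-variance slope test loses power badly
when the residual spread differs strongly between sexes (simulations at
r_M = 0.97 vs r_F = 0.74, n = 24/24 put it near 13% power while a direct
Fisher-z comparison of the per-sex correlations is near 96%), per-sex
correlations and the Fisher-z comparison are reported alongside it.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: 53 males
and 29 females; 21 matrix positions × 6 exposures per sample; triplicate
spectra.  Latent peak parameters are truncated normals by sex.  Primary-peak
positions centre on the observed ~0.045 nm⁻¹ region with male crowns more
UV-tuned (means 0.047/0.044, sd 0.002, truncated to [0.038, 0.06]); widths
use the reported ~0.007 (M) / 0.008 (F).  The remaining latent means
(a₁ = 120/90, α = 0.3, β = 5/3, h₂ = 0.012, c = 2) are package defaults
chosen once to produce Porod-space curves with the canonical two-peak
shape; they are not estimates of any real population.

Curves are the Porod-space model divided by q⁴, times a per-position
lognormal scale (σ = 0.1) — which is what makes intensity normalization
necessary — plus additive Gaussian noise with sd 2% of a₁ in Porod space.
Outliers (off by default, probability configurable) are empty positions or
single-bin cosmic spikes at a uniformly random detector position.  Frames
are isotropic renderings with Poisson counts and a beamstop disc mask.

Colour is generated from the latent structure: true hue =
2·(2π/q₁)·n_avg + δ_sex + ε with δ_M = 0, δ_F = −8 nm and ε ~ N(0, 2 nm);
the female offset injects the pattern that female realized hue falls below
the nanostructural prediction, standing in for other structural elements.
True brightness is 18 (M) / 13 (F) plus 1.5 per sd of a₁ and −1.2 per sd of
q₁, with 1.0 sd noise — increasing in the amount of coherently scattering
material, decreasing in how UV-tuned the sponge is.  Spectra are a Gaussian
reflectance peak (width 45 nm) at the true hue over a flat base (35% of
brightness), with amplitude solved so the noiseless grid-mean brightness
equals the true brightness; UV chroma then emerges from the spectral shape,
which automatically produces the positive q₁–UV-chroma link.  Replicate
noise is white with sd 0.3%.

Within-sample (among-position) variation of the sponge parameters is not
modelled (the per-position factor is a pure intensity scale); it is exposed
as a future knob rather than a default because its true magnitude is an
open biological question.

All randomness derives from numpy SeedSequences keyed by
(seed, stream, sample, position, exposure), so any subset of the cohort
regenerates bit-identically.

## What the tests show — and what they do not

The acceptance-style suites show that: the printed refractive-index
constant is reproduced exactly; the fitting chain is an unbiased
round-trip at the generator's noise level (median q₁ error < 1% from 126
replicates at 2% noise); azimuthal averaging reconstructs a known isotropic
model within counting error; the inference procedures are calibrated at
their nominal α on null data; and the qualitative structure–colour sign
pattern and the injected ±8 nm sex asymmetry are recovered at the default
effect sizes and sample sizes.

Because the synthetic generator realizes colour *through* the same Bragg
relation the analysis tests, these recoveries validate the software chain,
not the biology: they do not show that real feather spectra follow the
model, that real noise is Gaussian or position-independent, or that real
within-sample sponge variation is negligible.  Real reflectance spectra are
also not single Gaussians on a flat base, so absolute UV-chroma levels in
the synthetic cohorts should not be compared with instrument values — only
their rank structure matters to the statistics exercised here.

## Problem sizes used in the checked examples

Monte-Carlo recovery uses 100 seeded samples of 126 curves; null
calibrations use 500 simulated cohorts per procedure; sign-recovery and
offset-recovery use 200 cohorts of n = 82; the 2D round trip uses one
256×256 frame at 10⁷ counts.  These sizes give binomial/standard errors
comfortably inside the asserted tolerances.
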