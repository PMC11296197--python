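# spongesaxs

Analysis of non-iridescent structural plumage colour from small-angle X-ray
scattering (SAXS) of feather samples.

UV-blue plumage patches such as the blue tit crown get their colour not from
pigments but from coherent scattering by the *spongy layer* — a quasi-ordered
keratin–air nanostructure inside the feather barbs.  The dominant periodic
repeat distance of that sponge sets which wavelengths are reinforced, its
regularity sets how saturated the colour can be, and the amount of coherently
scattering material affects overall reflectance.  This package implements the
full measurement-to-inference chain needed to test those links on a cohort of
individuals:

1. **Reduction** (`spongesaxs.reduction`) — matrix-mode 2D detector frames
   (many short exposures on a grid of sample positions) are corrected,
   azimuthally averaged into curves I(q) with q = 4π·sin θ/λ, screened for
   outliers (cosmic-ray spikes, empty positions) with a robust z-score on
   window intensity, normalized on the intensity scale and averaged into one
   scattering curve per sample.
2. **Peak fitting** (`spongesaxs.porodfit`) — the Porod plot q⁴·I(q) flattens
   the q⁻⁴ background of large scatterers and exposes the two sponge peaks
   (near 0.045 and 0.075 nm⁻¹), which are fitted on 0.038 ≤ q ≤ 0.2 nm⁻¹
   with a constant baseline plus two Gaussians parameterized by HWHM:

       y(q) = c + a₁·exp(−ln2·(q−q₁)²/h₁²) + α·a₁·exp(−ln2·(q−β·q₁)²/h₂²)

   Peak position maps to the Bragg repeat distance d = 2π/q; widths h₁, h₂
   measure nanostructural irregularity; heights are ln(a + 10⁵)-transformed.
3. **Colourimetry** (`spongesaxs.colorimetry`) — reflectance spectra are
   summarized as brightness (mean % reflectance 320–700 nm), UV chroma
   (320–400 nm band relative to brightness) and hue (wavelength of maximum
   reflectance), averaged over replicates at the variable level.
4. **Hue prediction** (`spongesaxs.huepredict`) — λ = 2·(2π/q₁)·n_avg, with
   n_avg the volume-weighted average refractive index of the keratin–air
   composite (1.58 at volume fraction 0.57 → n_avg = 1.33).
5. **Cohort statistics** (`spongesaxs.cohortstats`) — sex t/F tests and
   within-sex standardization, Pearson matrices, general linear models with
   backward stepwise simplification and term reintroduction (marginality
   respected), varimax-rotated principal components to decorrelate
   predictors, male-line residual dichromatism tests, the paired
   estimated-vs-measured hue comparison, and between-round repeatability.
6. **Synthesis** (`spongesaxs.synthesize`) — a generator of complete
   synthetic cohorts (latent per-individual nanostructure by sex, replicate
   curves with outliers, optional 2D frames, triplicate spectra) with known
   ground truth, so every stage is testable end to end.

## Worked example

```python
import spongesaxs as sx
from spongesaxs import cohortstats as cs

cfg = sx.CohortConfig()                      # 53 males, 29 females, 21x6 matrix mode
truth = sx.draw_cohort(cfg, seed=1)[0]       # one male sample, known ground truth
curves = sx.simulate_sample_curves(truth, cfg, seed=1)
avg = sx.reduce_sample(curves)               # outlier screen + normalize + average
fit = sx.fit_curve(avg)                      # Porod transform + two-Gaussian fit

print(f"true q1 = {truth.peak.q1:.5f} nm^-1, fitted q1 = {fit.params.q1:.5f} nm^-1")
print(f"Bragg spacing d1 = {fit.d1_nm:.1f} nm")
print(f"predicted hue = {sx.predict_hue(fit.params.q1):.1f} nm  (n_avg = {sx.OpticalModel().n_avg:.4f})")

table = sx.simulate_cohort_table(cfg, seed=1)
out = cs.paired_hue_comparison(table)
print(f"female mean (estimated - measured) = {out['mean_difference']['F']:+.2f} nm, "
      f"p = {out['per_sex']['F'].p_value:.4f}")
```

prints

```
true q1 = 0.04807 nm^-1, fitted q1 = 0.04807 nm^-1
Bragg spacing d1 = 130.7 nm
predicted hue = 347.9 nm  (n_avg = 1.3306)
female mean (estimated - measured) = +7.12 nm, p = 0.0000
```

The fitted primary-peak position recovers the latent one from 126 noisy
replicate curves; the Bragg spacing is the sponge's dominant repeat distance;
the predicted hue applies the refractive-index-scaled Bragg condition.  In
the cohort comparison, females show a significant hue *overestimation* — the
generator lowers realized female hue ~8 nm below the nanostructural
prediction (a stand-in for other structural elements contributing in that
sex), and the paired analysis recovers it, while the male difference is near
zero.

The same workflow is available from the shell:

```sh
spongesaxs simulate --out cohort/ --seed 17 --curves
spongesaxs reduce --curves cohort/curves-of-one-sample/ --out avg.dat
spongesaxs fit --curve avg.dat --out fits.csv
spongesaxs predict-hue --fits fits.csv --out predicted.csv
spongesaxs colour --spectra cohort/spectra.csv --out colours.csv
spongesaxs stats --table cohort/cohort.csv --report report/
```

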