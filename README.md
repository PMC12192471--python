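# ctnps — frequency-resolved CT image-noise analysis

`ctnps` quantifies and compares the noise *texture* of CT reconstruction
methods, not just the noise magnitude.  It implements the ensemble
noise-power-spectrum (NPS) method for repeated reconstructions of the same
slices, directional and angular spectral averaging, band-wise comparison of
reconstruction methods with crossover detection, the statistical battery
used on image-quality reading tables, and dose bookkeeping.  A synthetic
generator produces CT noise ensembles with filtered-back-projection-like
(FBP, high-frequency-weighted) and iterative-reconstruction-like (IR,
low-frequency-shifted) textures, so the entire pipeline runs and is tested
without clinical data.

It is aimed at medical-physics and neuroradiology researchers evaluating
reconstruction algorithms (e.g. FBP vs. vendor IR such as SAFIRE/ADMIRE) in
non-enhanced head CT, particularly under simulated dose reduction.

## Method

**Ensemble NPS.** The same slice set is reconstructed `n` times with
identical parameters.  With ensemble mean `x̄`, each difference image
`d_i = x_i − x̄` isolates noise.  The 2D spectral estimate for one slice is

    NPS(fx, fy) = (Δ² / N_pix) · (1/(n−1)) · Σᵢ |FFT2(dᵢ)|²

where `Δ` is the pixel size (0.429 mm on the emulated 512² protocol) and
the `n/(n−1)` factor corrects the variance deficit from subtracting the
sample mean.  With this normalization, white noise of variance σ² has the
flat spectrum σ²Δ², and the per-pixel variance equals the 2D integral of
the NPS over the Nyquist square (Parseval).  The 2D map is sampled along 18
lines through DC (10°…180° in 10° steps, bilinear interpolation), the 18
directional spectra are averaged into an angle-independent curve (on
diagonals the reachable frequency exceeds the axis Nyquist 1/(2Δ) by up to
√2), and per-slice curves are averaged into a cohort spectrum.

**Method comparison.** Spectra are integrated over three frequency bands
split at 0.5088 and 1.3084 1/mm, and two methods are compared by the
relative improvement `100·(NPS_ref − NPS_test)/NPS_ref` (%); its zero
crossings are the frequencies where the methods trade places.  For the
default synthetic textures the ADMIRE-like spectrum is below the
SAFIRE-like one outside (0.5088, 1.3084) 1/mm and above it inside, and the
FBP-like spectrum dominates both everywhere.

**Synthetic ensembles.** Noise fields are white Gaussian fields spectrally
shaped by √NPS_t/Δ in the frequency domain, with target spectra from the
three-parameter family `NPS_t(f) = A·(f/f₀)^p·exp(−(f/f₀)^q)`.  Dose
reduction follows the quantum-noise model: amplitude ∝ 1/dose, implemented
by adding an independent field with variance σ²(1/fraction − 1).

**Statistics.** Lilliefors-corrected Kolmogorov–Smirnov normality screening
(Monte-Carlo null), Levene's test, one-way ANOVA (from raw groups or from
printed mean/SD/n summaries), Bonferroni pairwise comparisons with pooled-MS
confidence intervals, paired *t*, Wilcoxon signed-rank (midranks,
tie-corrected normal approximation), one-way repeated-measures ANOVA with
Greenhouse–Geisser correction, partial η² = F·df₁/(F·df₁ + df₂), and
ordinal descriptives (Mdn (IQR), mean ± SD).  Effective dose is
DLP × 0.0021 mSv/(mGy·cm) for head CT.

## Worked example

```python
import numpy as np
from ctnps import (PhantomSpec, make_head_phantom, default_method_profiles,
                   synthesize_ensemble, relative_improvement, find_crossovers)
from ctnps.pipeline import estimate_cohort_nps, trim_dc

phantom, masks = make_head_phantom(PhantomSpec(matrix_size=128, n_slices=30))
profiles = default_method_profiles(dose_fraction=1.0)
curves = {}
for name in ("SAFIRE", "ADMIRE"):
    ens = synthesize_ensemble(phantom, profiles[name], n_rep=5, seed=42)
    curves[name] = estimate_cohort_nps(ens)
rel = relative_improvement(trim_dc(curves["SAFIRE"]), trim_dc(curves["ADMIRE"]))
print([round(f, 4) for f in find_crossovers(rel)])
```

prints

```
[0.5087, 1.3085]
```

the two frequencies (1/mm) at which the ADMIRE-like and SAFIRE-like noise
curves cross: the ADMIRE-like texture has less noise below ~0.51 and above
~1.31 1/mm, the SAFIRE-like texture less in between.  The full study-shaped
run is scripted: `analysis/01_simulate_ensembles.py` through
`analysis/05_dose_summary.py` synthesize the 3 methods × 3 dose ensembles,
estimate the nine cohort spectra, integrate bands and locate crossovers,
run the image-quality statistics, and summarize dose; tables land in
`results/analysis/`.  The same chain is available as a CLI:
`ctnps full --config cfg.yaml --seed 1 --out results`.

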