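# Methods

## The estimation problem

Image noise in CT is spatially correlated, and the correlation structure —
the noise power spectrum (NPS) — differs between reconstruction
algorithms: filtered back projection (FBP) with a ramp-like kernel yields
high-frequency-weighted noise, while iterative reconstruction (IR) shifts
noise power toward lower frequencies ("blotchy" texture).  Two IR methods
can therefore be ordered differently in different frequency bands even when
their total noise is similar.  `ctnps` estimates the NPS from repeated
reconstructions, compares methods band-wise, and finds the frequencies
where two methods trade places (crossovers).

## Ensemble NPS estimator

Input is an ensemble of `n ≥ 2` reconstructions of the same slices
(`n = 5` in the emulated protocol).  Per slice:

1. subtract the ensemble mean from each repetition (removes anatomy);
2. 2D-FFT each difference image and form
   `NPS = (Δ²/N_pix) · (1/(n−1)) · Σ |FFT2(dᵢ)|²` with pixel size `Δ`;
3. sample the DC-centered map along 18 lines through DC at 10°–180° in 10°
   steps, by bilinear interpolation at steps of one axis-frequency bin
   `df = 1/(NΔ)`, out to the map boundary;
4. average the 18 directional spectra per frequency over the curves that
   reach it (`support_count` records how many); beyond the axis Nyquist
   `1/(2Δ)` only near-diagonal lines contribute, up to `√2/(2Δ)`;
5. average per-slice curves into the cohort spectrum.

Normalization conventions (the source protocol does not state its own):

- **Squared modulus.** Power is `|FFT|²`; with `|FFT|¹` the white-noise
  calibration and Parseval identity below would fail.
- **Scaling.** `Δ²/N_pix` per difference image, times `n/(n−1)`.  These
  make the white-noise closed form exact: iid noise of variance σ² gives a
  flat spectrum σ²Δ² and no systematic dependence on `n`, and the 2D
  integral of the NPS over the Nyquist square equals the per-pixel
  variance.  Units are HU²·mm².
- **Averaging order.** Each difference image is transformed and the
  periodograms averaged (averaging the difference images first would give
  identically zero, since they sum to zero by construction).
- **DC bin.** Carries residual-mean power (≈ 0, but random in sign across
  methods); it is excluded from method comparisons.
- **Interpolation.** Bilinear; nearest-neighbour aliases on diagonals.  The
  largest interpolation error is at the first 2–3 frequency bins, where the
  spectrum is steepest relative to its value (≲ 8% there, < 1% beyond).

## Band comparison and crossovers

Spectra are integrated by the trapezoid rule over `[0, 0.5088]`,
`(0.5088, 1.3084]` and `(1.3084, f_max]` 1/mm; boundary points are inserted
by linear interpolation so the three bands sum to the total integral to
machine precision.  The band boundaries are the two empirical crossover
frequencies between the IR methods and can be overridden.

Relative improvement of a test method over a reference is
`100·(ref − test)/ref` (%), positive where the test method has less noise;
frequencies with non-positive reference power are masked.  Crossovers are
zero crossings located by linear interpolation between adjacent finite grid
points of opposite sign; runs of consecutive exact zeros collapse to their
midpoint.

With pixel size 0.429 mm the axis Nyquist is 1.1655 1/mm, so the upper band
boundary 1.3084 1/mm is reachable only through the diagonal directions of
the 2D spectrum (up to 1.648 1/mm at 45°; up to ≈ 1.31 × Nyquist ≈ 1.52
1/mm for the closest sampled angles, 40°/50°/130°/140°).

## Synthetic noise textures

Noise is synthesized by spectral shaping: a white Gaussian field is
FFT-ed, multiplied by `√NPS_t(f)/Δ`, and transformed back, making the
expected NPS of each field equal the target exactly.  Projection-domain
(Poisson sinogram) simulation was rejected: it would require a
reconstruction operator that is not part of the model.

Target spectra come from the family

    NPS_t(f) = A · (f/f₀)^p · exp(−(f/f₀)^q),   f in 1/mm

which spans ramp-like (p = 1, slow decay) and low-frequency-shifted
(steeper rise/decay) textures with three shape parameters.  Defaults:

| profile     | A (HU²mm²) | f₀ (1/mm) | p    | q   | σ at full dose |
|-------------|-----------|-----------|------|-----|----------------|
| FBP-like    | 42.0      | 1.05      | 1.0  | 2.0 | ≈ 10.3 HU      |
| SAFIRE-like | 14.0      | 0.50      | 1.15 | 1.6 | ≈ 3.7 HU       |
| ADMIRE-like | solved    | solved    | 1.9  | 2.4 | ≈ 4.0 HU       |

The ADMIRE-like amplitude and f₀ (≈ 14.563, ≈ 0.6781) are solved at run
time (two-point root find on the log-NPS difference) so that the
SAFIRE−ADMIRE difference changes sign exactly at 0.5088 and 1.3084 1/mm;
the sign pattern (ADMIRE lower outside the band, SAFIRE lower inside) and
FBP dominance (≥ 1.9× both IR spectra at every frequency) follow from the
chosen shapes and are verified on a dense grid in the tests.  Absolute
spectral levels are free parameters of the emulation — set to plausible
head-CT noise magnitudes — and are not reproduction targets; only the
ordering and crossover structure are.

**Dose model.** Quantum noise only: NPS amplitude ∝ 1/dose_fraction.
Dose reduction of an existing ensemble adds an independent field with the
same spectral shape and variance σ²(1/fraction − 1), so total variance
scales as 1/fraction; fraction 1 is the identity.  Electronic (detector
read-out) noise, tube-current modulation and beam hardening are
deliberately unmodeled.

**Phantom.** A deterministic elliptical head (air −1000 HU, skull rim
900 HU, parenchyma 30 HU) with two thalamic GM ellipses (39.916 HU) and two
frontal periventricular WM ellipses (33.452 HU); the ROI masks coincide
with those ellipses, so noiseless mask means equal the tissue values
exactly.  The head outline shrinks parabolically toward the end slices.
The phantom only supplies a realistic background; all NPS estimation
operates on differences, which remove it.

## Synthetic reading-study tables

**ROI HU table.** Per cell (tissue × method × dose) a normal model with the
published cohort mean and SD (n = 21).  All methods and doses are
reconstructions of the same scan, so a subject's values share a per-subject
standard-normal offset weighted by √ICC (default ICC 0.8, a strong paired
design; the source data imply pairing but no value).  Marginal cell SDs are
preserved.

**Likert table.** For each cell the integer score multiset (1–10, n = 21)
whose sample mean and SD best match the printed values is found by
exhaustive search over multisets supported on ≤ 3 distinct values; all 45
published cells are matched within 0.05 on both moments.  Scores are
assigned to subjects in a fixed descending order, keeping ratings maximally
concordant within subject across doses — the natural structure for paired
dose comparisons.  Summaries for which no integer multiset exists produce
the nearest achievable multiset with a warning.

## Statistical conventions

- Levene's test is mean-centered (the classical variant, not
  Brown–Forsythe).
- The Lilliefors KS p-value is Monte-Carlo (default 10 000 seeded
  standard-normal samples of the same size), since parameters are
  estimated; the screening threshold is p ≥ 0.01.
- One-way ANOVA can be run from printed summaries (mean, SD, n per group);
  between- and within-group sums of squares are exact functions of these.
- Bonferroni pairwise: pooled within-group mean square, CI via
  `t(df_within)` at `α/(2m)` with `m = k(k−1)/2`, adjusted
  `p = min(1, m·p_unadj)`.  Absolute SEM/CI values depend on unrounded raw
  data and are not reproduction targets; the mean differences are.
- Wilcoxon signed-rank: zero differences dropped, midranks for ties,
  normal approximation with tie-corrected variance, no continuity
  correction (the convention of the major commercial statistics package);
  exact enumeration serves as the oracle for n ≤ 12 in the tests.  Cell
  pairs with fewer than 5 informative pairs are reported as p = 1 by the
  pipeline (no evidence), while the operation itself raises.
- The pooled subjective-score analysis is a one-way repeated-measures
  ANOVA over the 9 method × dose conditions (consistent with numerator
  df 8), with Greenhouse–Geisser ε from the doubly-centered condition
  covariance, clipped to (1/(k−1), 1]; ε multiplies both dfs (ε = 1 for
  k = 2).  Partial η² = F·df₁/(F·df₁+df₂) is invariant to the correction.
- α = 0.05 throughout.

## Problem sizes

Tests and the analysis scripts use reduced grids chosen so Monte-Carlo
error is far below the asserted tolerances: white-noise calibration at
128² with 50–200 slices (per-bin periodogram RSD ≈ 3.5% at 200 slices,
pooled before 5% comparisons), crossover recovery at 128² with 100 slices
and 5 repetitions (observed crossover jitter ≈ ±0.01 1/mm against the
±0.05 band), dose-scaling checks at 128² with 50 slices (3% tolerance,
observed error < 1%).  The default `RunConfig` keeps the full protocol
(512², 5 repetitions).

## Limitations

The synthetic ensembles are stationary, Gaussian and exactly
ensemble-reproducible; real IR noise is nonstationary (object- and
signal-dependent regularization), non-Gaussian at low dose, and correlated
with anatomy.  Passing tests therefore demonstrate the correctness of the
estimation and comparison machinery and the qualitative FBP/IR spectral
structure — not the absolute spectra of any scanner.  The dose model omits
electronic noise, so variance scaling is exactly 1/dose; on real scanners
the low-dose variance grows faster.  The phantom is not anthropomorphic,
and consensus-reading behaviour (reader bias, category correlations beyond
subject concordance) is not modeled.
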