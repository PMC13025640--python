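# Methods

This package reimplements a multiparametric quantitative-ultrasound (QUS)
radiomics pipeline for monitoring breast-tumor response to neoadjuvant
chemotherapy, validated end to end on synthetic radiofrequency (RF) phantoms
because no clinical RF data is distributable. This note records the models,
the synthetic study conditions, the numerical choices, and what the passing
tests do and do not establish.

## RF data model and B-scan formation

A frame is a real-valued `[axial x lines]` grid of beamformed RF samples with
axial sampling rate `f_s`, line pitch, sound speed (1540 m/s default),
transducer band (3–8 MHz), and focus depth. The envelope is the per-line
analytic-signal magnitude `a(z) = |r(z) + i H[r(z)]|` (axial Hilbert
transform only — `r(z)` is defined per scan line). B-scans are
`20 log10(a / max a)` clipped to a configurable dynamic range (60 dB default;
the choice only affects display and texture quantization input, and the
window-local quantization removes any global-gain dependence). Time gain
compensation, when present, is a strictly positive frequency-independent
per-depth gain; it is divided out before spectral analysis and is treated as
constant within any axial analysis window.

## Synthetic phantoms (ground truth by construction)

`synth.simulate_rf` builds frames as a 2D convolution phantom:

1. a Bernoulli scatterer grid (default 30 scatterers per resolution cell)
   with signed amplitudes drawn from a configurable law (Gaussian/Rayleigh,
   Nakagami, or Burr magnitudes);
2. a per-scatterer Gaussian footprint whose width (scale 1 ≈ 40 µm) low-passes
   the backscatter spectrum — smaller footprints leave more high-frequency
   content, which is the physical premise of H-scan imaging;
3. convolution with a Gaussian-modulated pulse (5.5 MHz center, 60%
   fractional bandwidth) whose spectrum is attenuated blockwise in depth
   (0.5 mm blocks) by `exp(-2 alpha_Np f z)` at a known slope in dB/cm/MHz;
4. a depth-dependent lateral Gaussian emulating a focal waist (frequency
   independent, so it cancels in attenuation estimation exactly like TGC),
   plus −40 dB white noise.

The default density of 30 per cell was chosen so the envelope is fully
developed: the Gaussian footprint correlates neighboring grid points and
lowers the effective independent-scatterer count, and at density 10 the
moments estimator returns m ≈ 0.83 (pre-Rayleigh) while at 30 it returns
m ≈ 1.01. Blockwise attenuation is piecewise-constant at 0.5 mm, well below
the 3 mm spectral windows downstream.

`simulate_cohort` embeds a tumor disc (radius drawn per patient) whose
scatterer density, footprint scale, echogenicity, and heterogeneity differ
from background and — through `group_effects` — between the responder-like
and non-responder-like groups at each timepoint. Per-patient substreams come
from `SeedSequence(entropy=seed, spawn_key=(group, patient, timepoint))`, so
cohorts are bit-reproducible under any generation order.

`simulate_feature_cohort` draws the assembled 174-column feature table
directly from group-shifted normal distributions (per-feature baseline +
patient random effect + unit noise; a chosen number of informative features
receives a shift of `effect_sd` noise-SDs). This is the desk-scale condition
for classifier calibration: a 30-patient null or strong-effect cohort in
milliseconds rather than re-running the RF chain per patient. What it does
not emulate: inter-feature correlation structure of real radiomics, non-Gaussian
feature marginals, and any coupling between regions — so classifier results on
it validate the *selection/validation machinery* (leakage, aggregation,
determinism), not radiomic effect sizes in tissue.

## Speckle statistics

Nakagami (`p(a) ∝ a^(2m-1) exp(-m a²/Ω)`) is fitted by the standard moments
estimator `m = E[a²]²/Var(a²)`, `Ω = E[a²]` — closed form, robust, and exact
enough (m within 5%, Ω within 2% at n = 10⁵). The Burr model
`p(a) = 2a(b−1)/λ² (a²/λ²+1)^(−b)` has no closed-form MLE; for fixed λ the
shape MLE is `b = 1 + n/Σ log1p(a²/λ²)`, so the fit reduces to a 1-D profile
likelihood in `log λ` solved by bounded Brent iteration (`fit_burr`) or, for
maps, by a golden-section search vectorized across all windows at once. Map
windows subsample every third axial sample within the window: RF samples are
correlated at the pulse scale and windows overlap 98%, so the information
loss is negligible while the map builds ~3x faster. Near-Rayleigh windows
push the Burr MLE toward its `b → ∞` boundary (the Burr family contains
Rayleigh only as a limit); the finite search bracket (+2.5 log-λ units above
the median-amplitude start) acts as the map's shape cap.

Window geometry follows the clinical setting: 109 axial samples × 9 lines
(~1.5 × 1.5 mm at 56 MHz sampling) with 98% overlap; steps round to ≥ 1
sample. Windows need ≥ 50 positive samples; edge windows are skipped, not
padded.

## Attenuation estimation (reference-frequency method)

Within each 10 mm lateral kernel (0.2 mm step), Hann-windowed periodograms
over 3 mm axial windows (95% overlap) are averaged across the kernel's
lines. The frequency slope `d(z) = ∂/∂f ln S(f, z)` is an OLS fit of
log-power vs frequency over the usable band (contiguous region within 20 dB
of the spectral peak — OLS over a band is less noise-sensitive than any
finite-difference differentiation). Differencing two depths cancels the
depth-independent pulse/backscatter term and every frequency-independent
gain (TGC, focal gain):

    alpha(z_k) = −[d(z_k) − d(z_r)] / (4 (z_k − z_r))   (Np/cm/MHz)

All reference depths `z_r ≠ z_k` in the kernel enter a single least-squares
solve; pairs closer than one window length are excluded as ill-conditioned.
The scalar bounded solution is the unconstrained LS estimate clipped to the
physical range, reported in dB/cm/MHz (1 Np = 8.686 dB) with the
negative-slope sign convention: maps lie in [−2, 0] and the magnitude is the
attenuation slope. Analysis is restricted to the pre-focal zone plus 0.8 cm
beyond the focus (the single-focus beam approximation degrades further out)
and, when masks are given, to the tumor + peri-tumor extent; the 10 mm
kernel shrinks to the masked width when a desk-scale tumor is narrower, and
the first axial window is skipped (incomplete pulse support flattens the
shallowest spectra).

Two systematic effects matter at the few-percent level and are handled
explicitly. First, the expected windowed periodogram is the true spectrum
convolved with the taper's `|W(f)|²`, which broadens the near-Gaussian
spectrum (σ² → σ² + σ_W²) while leaving the attenuation-induced centroid
shift untouched — slope differences shrink by σ²/(σ²+σ_W²). The estimator
undoes this with the analytically known taper variance and the spectrum's
own fitted log-curvature (skipped when the curvature is unusable). Second,
the validation phantom is sized (4.5 cm depth, 3 cm width, 3.5 cm focus) so
that the map mean has enough independent kernels and depth lever arm:
across 8 phantom seeds the 0.5 dB/cm/MHz truth is recovered with mean
−0.498 and worst-case error 5%, inside the 7% working tolerance the tests
assert.

## H-scan frequency imaging

The bank holds 256 Gaussian passbands with centers uniformly spanning
3–8 MHz inclusive (spacing 5/255 ≈ 0.0196 MHz) and FWHM = 0.5·fc. Filters
are applied as zero-phase transfer functions in the frequency domain; the
per-filter response is the analytic-signal envelope of the filtered RF, and
each pixel takes the center frequency of the maximal response (ties break
toward the lower frequency — deterministic and conservative toward larger
scatterers). Filters use **unit peak gain**: with unit-energy normalization
the narrowband argmax is biased low by ≈ σ_f²/(2 fc) (~0.12 MHz, six filter
spacings), whereas unit peak gain maps a pure tone exactly to its own
frequency; the scatterer-size ordering is preserved under either choice.
Before filtering, the RF is attenuation-compensated by inverting
`exp(-2|alpha| f z)` blockwise in depth using the median of the estimated
attenuation map (gain capped at the transducer band's upper edge).

## Texture radiomics

Forty features per source image, from four matrix families computed inside a
sliding 9 × 9 window (80% overlap) on the isotropically resampled grid:
GLCM (13) and GLRLM (13) at distance 1 along 0°, 45°, 135°, 270°, averaged
with inverse-distance weights (1, 1/√2); GLSZM (9) over 8-connected
equal-level zones; NGTDM (5) in the Amadasun–King formulation with a full
3 × 3 neighborhood. The 270° direction duplicates 90° co-occurrence under
symmetry; it is retained as specified, not "corrected". Intensities are
quantized to 64 levels between the window's own min and max, making every
feature invariant to affine intensity rescaling and keeping all operations
strictly within one image (no cohort statistics). Constant windows emit
analytic degenerate values (contrast 0, homogeneity 1, energy 1, correlation
0, coarseness 0 in place of its infinite limit) with a degenerate flag.
Perona–Malik anisotropic diffusion (10 iterations, conduction 20 in dB
units, step 0.15) denoises each image first. The roster is pinned in
`texture.FEATURE_MANIFEST`; an independent brute-force implementation (naive
loops, flood fill) must agree exactly on every window of a random fixture.

## Feature table and longitudinal changes

87 maps per acquisition (B-scan, 4 speckle, attenuation, H-scan frequency,
2 × 40 textures), each contributing its mean over the tumor and over the
peri-tumoral ring (3–10 mm, default 5 mm, built by Euclidean distance
transform so the ring thickness is isotropic on anisotropic grids): 174
features, 84 frequency-domain and 90 amplitude-domain. Follow-up features
are strictly within-patient relative changes `(x_t − x_pre)/|x_pre|`; the
absolute value keeps the sign meaning for negative-valued features such as
the attenuation slope. Regions with < 10 valid pixels or near-zero baselines
yield missing values with warnings rather than silent numbers.

## Selection, scoring, and nested validation

* **ICC stability**: features are re-extracted under small rigid mask shifts
  (≤ 1 mm); a two-way absolute-agreement single-measurement ICC (ICC(2,1),
  closed form from the two-way ANOVA mean squares) above 0.90 retains the
  feature. Undefined ICCs (zero between-patient variance) drop the feature.
* **SVM-RFE**: a linear SVM on z-scored training data is refit while the
  smallest-|w|² feature is removed each round; constant features are
  eliminated first by convention.
* **3D score map**: z-score → PCA (first 3 components, deterministic sign
  convention) → SMOTE (k = 5) in PC space → RBF-SVM (`gamma = 1/s²` for
  kernel scale `s`). SMOTE follows PCA so synthesis happens in the 3-D space
  where the SVM operates. The decision threshold is recalibrated to maximize
  balanced accuracy on the SMOTE-balanced training scores; candidates include
  0, so recalibration never loses to the raw cut. The signed decision value
  minus the threshold is the multiparametric score; positive predicts the
  responder group. SMOTE is implemented in-package (k-NN interpolation
  oversampling of the minority class to parity).
* **Nested CV**: outer label-stratified disjoint partitions (10, repeated);
  inside each training set, ICC → RFE → incremental combinations × a
  log-spaced hyperparameter grid (box constraint 10⁻⁴–10⁰, kernel scale
  10⁰–10¹), each cell scored by inner k-fold CV with
  bootstrap-averaged score maps and pooled held-out AUC; ties prefer fewer
  features, then the smaller box constraint and kernel scale. The winner
  retrains on the full outer-training set and scores the held-out patients.
  Per patient, only scores from models trained without that patient are
  kept; they are aggregated across folds and averaged across iterations into
  one cross-validated score, on which AUC (Mann–Whitney mid-rank), accuracy,
  sensitivity, and specificity at score 0 are computed with 2000-resample
  patient-level percentile bootstrap CIs.

The full clinical configuration (k ∈ {3,5,10} × 3 inner iterations × 5
bootstraps × 10 outer iterations × up to 15 features × 5 × 5 grid) is the
`SelectionConfig` default. The test and analysis runs use a reduced
configuration (k = 3 × 1, 2 bootstraps, 3 outer iterations, 4 features,
2 × 2 grid) — the package's desk-scale operating point, chosen so the whole
validation chain still executes with every leakage guard in place.

### Null-calibration statistics

The leakage canary evaluates the pipeline on a null cohort (zero group
effect). The aggregated AUC of any honest scoring of a 15-vs-15 null cohort
has the Mann–Whitney dispersion `SD = sqrt((n+1)/(12 n1 n0)) ≈ 0.107`
**across cohort draws**, so the calibration band [0.35, 0.65] can only be
held with high probability when the cohort is fixed and the pipeline seed
varies; that is how the calibration test and `analysis/06_classifier_cv.py`
are run. Across fresh cohort draws, roughly 84% of null AUCs fall in that
band — a property of the rank statistic at n = 30, not of the pipeline.

## Known limitations

* The convolution phantom omits diffraction-driven spectral focusing,
  nonlinear propagation, and 3D beam effects; attenuation recovery under
  those confounds is untested here.
* The Burr map cap (search bracket) is a pragmatic regularization of the
  Rayleigh-limit divergence; absolute Burr-shape values on near-Rayleigh
  tissue depend on it, though contrasts do not.
* The feature-level cohort generator draws independent features;
  selection behavior under strong feature correlation is not exercised.
* Texture windows at the image border are skipped, so maps undercover a
  half-window margin; regional means ignore this by construction.
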