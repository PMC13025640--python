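# usradiomics

Multiparametric quantitative-ultrasound (QUS) radiomics for monitoring
breast-tumor response to neoadjuvant chemotherapy (NAC) — a tested,
reusable reimplementation of the full analysis chain, from beamformed
radiofrequency (RF) frames to a cross-validated per-patient response score,
with a synthetic RF phantom/cohort generator supplying ground truth for
every estimator.

## What it computes

From one RF acquisition `r(z)` per scan line, the pipeline derives **87
parametric maps**, summarized as **174 regional features** (tumor and
peri-tumoral ring means):

| stage | model / statistic |
|---|---|
| Envelope & B-scan | `a(z) = \|r(z) + iH[r(z)]\|`, `20 log10(a/a_max)` clipped to 60 dB |
| Speckle maps | Nakagami `m = E[a²]²/Var(a²)`, `Ω = E[a²]`; Burr `(b, λ)` by profile MLE of `p(a) = 2a(b−1)/λ² (a²/λ²+1)^{−b}` |
| Attenuation (ACE) | reference-frequency method: `α(z_k) = −[d(z_k)−d(z_r)]/(4(z_k−z_r))` with `d(z) = ∂/∂f ln S(f,z)`, bounded to [−2, 0] dB/cm/MHz |
| H-scan frequency | argmax over 256 Gaussian matched filters (3–8 MHz, 50% relative bandwidth) — a proxy for scatterer size |
| Texture (×2 sources) | 40 GLCM/GLRLM/GLSZM/NGTDM features in sliding 9×9 windows, window-local 64-level quantization, anisotropic-diffusion denoising |

Longitudinal assessments enter as strictly within-patient relative changes
`(x_t − x_pre)/|x_pre|`. Classification is a nested-cross-validated "3D
score map": per training partition, an ICC(2,1) > 0.90 stability filter →
linear-SVM recursive feature elimination → incremental feature combinations
and a hyperparameter grid scored by inner k-fold CV with bootstrap-averaged
models → z-score → 3-component PCA → SMOTE → RBF-SVM, with the decision
threshold recalibrated for balanced accuracy. Each patient's score comes
only from models trained without that patient; aggregated scores give AUC,
accuracy, sensitivity, and specificity with patient-level bootstrap CIs.

Because no clinical RF data ships with the package, `usradiomics.synth`
generates linear-array speckle phantoms with known attenuation slope,
scatterer footprint size, and amplitude law, plus two-group longitudinal
cohorts with configurable effect sizes — every estimator is validated by
parameter recovery against this ground truth.

## Worked example

Recover a known attenuation slope from a homogeneous phantom:

```python
import numpy as np
from usradiomics.synth import PhantomSpec, simulate_rf
from usradiomics.attenuation import AttenuationSpec, local_spectra, estimate_attenuation

spec = PhantomSpec(depth_extent_cm=4.5, lateral_extent_cm=3.0,
                   attenuation_slope=0.5,   # dB/cm/MHz, ground truth
                   focus_depth_cm=3.5, seed=42)
frame = simulate_rf(spec)
res = estimate_attenuation(local_spectra(frame, AttenuationSpec()), AttenuationSpec())
print(f"map mean {np.nanmean(res['values']):.4f} dB/cm/MHz")
```

prints

```
map mean -0.4979 dB/cm/MHz
```

— the estimator reports the negative-slope convention; its magnitude
(0.4979) recovers the simulated 0.5 dB/cm/MHz within 0.5%, and every
estimate is constrained to the physical [−2, 0] range.

The numbered drivers under `analysis/` run the full study at desk scale and
write their tables to `results/`:

```bash
python analysis/01_simulate_phantom.py      # speckle regime + centroid drift
python analysis/02_speckle_recovery.py      # Nakagami/Burr parameter recovery
python analysis/03_attenuation_recovery.py  # slope recovery across truths
python analysis/04_hscan_scatterer_size.py  # peak frequency vs scatterer size
python analysis/05_patient_maps.py          # 87 maps / 174 features, one patient
python analysis/06_classifier_cv.py         # nested-CV null + strong cohorts
```

For example, `02_speckle_recovery.py` reports shape/scale errors of
0.2–1.0% at n = 10⁵ for both envelope models, and `06_classifier_cv.py`
shows the leakage canary (null-cohort AUC at chance) next to a
strong-effect cohort separated almost perfectly.

A `usradiomics` CLI wraps the same library calls
(`usradiomics synth|maps|run|train --help`).

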