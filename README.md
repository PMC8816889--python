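# lofisim

Simulated clinical trials for low-field MRI.

Portable 64 mT MRI scanners trade image quality for accessibility. Before
committing to a prospective trial, one would like to know: *how much
diagnostic signal survives the loss of resolution and SNR?* `lofisim`
answers this in silico. It converts standard high-field (HF, ~3 T)
skull-stripped FLAIR volumes into simulated low-field (LF, 64 mT) images
with an empirically calibrated degradation model, then measures how slice-
and patient-level lesion detection by a seeded baseline classifier changes
between the two arms — as a function of lesion size, intensity, and
contrast. Seeded synthetic brain phantoms with controllable lesions make
every experiment reproducible on one CPU without any data downloads.

It is aimed at imaging scientists and medical-device researchers who want a
desk-scale harness for virtual device evaluation, and at anyone who needs
the component pieces: a NIfTI degradation pipeline, a gradient-entropy
quality metric, DeLong ROC comparisons, or lesion-detectability phantoms.

## The model

**Domain transformation.** An HF volume is resliced to the LF acquisition
grid (1.6 × 1.6 × 5 mm) and passed through a four-parameter cascade

```
sim = G_b( v + a1 · G_0.5(eps1) ) + a2 · G_s2(eps2)
```

where `eps1, eps2` are unit-variance Gaussian white-noise fields restricted
to the brain mask, `G_0.5` is a fixed 3-D Gaussian smoother (0.5 voxel SD),
`G_b` is the main blur (SD `b` mm), and `G_s2` smooths the second noise
field (SD `s2` mm). The free parameters `(a1, b, a2, s2)` are fitted on
paired HF/LF volumes by minimizing the squared standardized differences of
the first three in-mask histogram moments (mean, SD, skewness) between
simulation and target, averaged over noise realizations, with a bounded
multi-start Nelder–Mead search.

**Quality metric.** Perceived sharpness is tracked by the gradient entropy
`F = −Σ h_ij log2 h_ij`, where `h` is the normalized absolute horizontal
difference (`[1 −1]` convolution) of the slice; volumes are scored by the
mean over axial slices. Degradation raises `F`.

**Detectability harness.** Axial slices are labeled lesion-present if at
least one ground-truth segmentation pixel lies on them, split
patient-exclusively into train/test, and scored by a pluggable classifier
(default: a fixed multi-scale Laplacian-of-Gaussian convolutional front end
with a small learned MLP head; a DenseNet-121 configuration is declared for
full-scale runs with an external backend). Evaluation covers ROC/AUC, F1
against a 1000-trial random-chance null, DeLong's test for the paired AUC
difference between arms, logistic regression of detection on lesion area
and contrast (Wald tests), LF/HF sensitivity-ratio-versus-size curves, and
sliding-window (~1.5 cm) patient-level classification with an empirically
maximized threshold.

**Contrast modulation.** Lesion intensities can be scaled per sub-label
toward per-slice isointensity (100% = original, 0% = mean lesion intensity
equals the slice's non-lesional mean) to decouple intensity contrast from
structural signal such as mass effect.

## Worked example

```python
from lofisim import (
    CohortConfig, run_two_arm_trial, quality_comparison,
)

# 60 synthetic patients (42 lesional, 18 control), both arms
trial = run_two_arm_trial(CohortConfig(), seed=1)
print("AUC  HF   :", round(trial.arms["HF"].report.auc, 3))
print("AUC  simLF:", round(trial.arms["simLF"].report.auc, 3))
print("DeLong z, p:", [round(v, 3) for v in trial.delong[2:]])
print(trial.ratio_curve[["threshold_cm2", "ratio"]])

q = quality_comparison(n_phantoms=10, seed=1)
print("gradient entropy HF -> simLF:",
      round(q.F_hf.mean(), 2), "->", round(q.F_simLF.mean(), 2))
```

Output (seed 1):

```
AUC  HF   : 0.973
AUC  simLF: 0.953
DeLong z, p: [2.48, 0.013]
   threshold_cm2     ratio
0            1.0       NaN
1            2.0  0.500000
2            4.0  0.923077
3            8.0  0.928571
4          100.0  0.955556
gradient entropy HF -> simLF: 8.43 -> 9.74
```

Reading: per-slice detection is nearly on par between arms overall (AUC
0.973 vs 0.953; on lesions ≥ 4 cm² both arms are ≥ 0.999), but the
simulated low-field arm detects only half as many sub-2 cm² lesion slices
as high field (ratio 0.50), recovering toward parity (≥ 0.95) as all sizes
are pooled — the size-dependent sensitivity loss the framework is designed
to expose. Gradient entropy rises under degradation, the expected
direction for blurrier, noisier images.

The same pipeline is scriptable from the shell:

```bash
lofisim phantom --out cohort/ --seed 1 --n-lesional 4 --n-control 2
lofisim simulate --in cohort/P000_flair.nii.gz --mask cohort/P000_mask.nii.gz \
                 --seed 2 --out sim_lf.nii.gz
lofisim quality --in cohort/P000_flair.nii.gz --out quality.csv
lofisim run --out run/          # full two-arm trial with reports
```

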