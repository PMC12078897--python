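# habitatmri

MRI-based quantification of intratumoral heterogeneity (ITH) for binary
tumour-grade prediction.

Pathological grade drives prognosis and treatment choice in liver tumours
such as intrahepatic mass-forming cholangiocarcinoma, but grading
requires invasive histology.  Habitat imaging offers a non-invasive
surrogate: the tumour volume of interest (VOI) on co-registered
T2-weighted and diffusion-weighted MRI is partitioned into intensity
"habitats" by K-means, radiomic features are computed per habitat, and
the predicted probabilities of per-habitat grading models are combined
into a patient-level ITH index.  This package implements that pipeline
end to end for researchers in quantitative imaging — together with a
synthetic-cohort generator with planted ground truth, so every stage runs
and is testable at desk scale without patient data.

## The method

For each patient with volumes $I_{T2}, I_{DWI}$ and VOI $V$:

1. **Preprocess** — multiplicative bias correction, resampling to
   1 mm³ (B-spline), two-stage decile-landmark histogram standardisation
   (landmarks frozen on the training cohort), and DWI→T2WI registration
   (mutual-information rigid stage + B-spline refinement).
2. **Habitats** — per sequence, 1-D K-means on standardised within-VOI
   intensities; $K$ chosen once per cohort by the elbow (maximum chord
   distance) of the pooled, normalised SSE curve
   $\mathrm{SSE}(K)=\sum_k\sum_{x\in C_k}(z_x-\mu_k)^2$; habitat 1 is the
   high-signal cluster.
3. **Radiomics** — per region (whole T2WI, whole DWI, four habitats):
   14 IBSI shape features plus 18 first-order and 72 texture features
   (GLCM 21, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5) on each of 21 derived
   image types (wavelet sub-bands, Laplacian-of-Gaussian, intensity
   transforms, gradient, LBP-style maps): $14 + 90\times21 = 1904$
   features per region.
4. **Selection & models** — per subregion: chi-square screen
   ($p<0.05$ on training-median splits) then LASSO (penalty by minimum
   10-fold CV deviance); logistic models per subregion; the ITH index of
   a subset $S$ is $\frac{1}{|S|}\sum_{s\in S}\hat p_s$; 13 candidate
   subsets (4 singletons + 9 cross-sequence) are scored on internal
   validation and the winner becomes the Habitat model.  Seven final
   logistic models combine the clinical/laboratory/imaging, radiomics and
   habitat blocks.
5. **Evaluation** — DeLong AUC with 95% CI and paired tests, Youden
   thresholds with sensitivity/specificity/accuracy/precision,
   calibration and decision curves, exact linear-model Shapley
   attributions, Cohen's kappa and ICC(2,1), and type-aware cohort
   comparison tests.

## Worked example

`examples/05_train_and_evaluate.py` runs a 160-patient synthetic study
(reduced feature bank, K = 2) and prints:

```
K = 2; habitat model subset: ['DWI_habitat2']
clinical covariates retained: ['cea_positive', 'ca12_5_positive', 'tumor_margin_infiltrative', 'bile_duct_dilatation', 't2wi_targetoid_sign']
radiomics features selected: 16

internal-validation performance (threshold = training Youden):
                         auc  ci_low  ci_high  sensitivity  specificity  accuracy
ClinLabImag            0.656   0.453    0.858        0.857        0.364     0.688
Radiomics              0.974   0.920    1.000        1.000        0.909     0.969
Habitat                1.000   1.000    1.000        0.952        1.000     0.969
ClinLabImag-Radiomics  1.000   1.000    1.000        0.952        1.000     0.969
ClinLabImag-Habitat    0.987   0.958    1.000        0.952        1.000     0.969
Radiomics-Habitat      0.987   0.958    1.000        0.952        0.909     0.938
Combined               1.000   1.000    1.000        0.952        1.000     0.969

top 5 Combined-model features by mean |Shapley value| (log-odds):
ith_index                                     2.723
whole_DWI|original|glcm|JointEnergy           2.147
whole_T2WI|original|glcm|SumEntropy           1.993
cea_positive                                  1.741
whole_T2WI|original|gldm|DependenceEntropy    1.348
```

Reading this: the two planted clinical effects (tumour margin, T2WI
targetoid sign) survive the univariable→multivariable screen — alongside
a few false positives, as a p < 0.05 filter on 128 training rows will
produce; the habitat block (the ITH index built from subregion-model
probabilities) separates held-out grades almost perfectly because the
generator plants grade-dependent habitat fractions and texture, while
the clinical block alone is weak by design.  The ITH index dominates the
Combined model's Shapley ranking.  AUCs carry DeLong 95% confidence
intervals; threshold metrics use the training-set Youden threshold.

Other examples cover simulation and artifacts (`01`), preprocessing and
registration recovery (`02`), habitat clustering and the SSE elbow
(`03`), the 1904-feature extraction (`04`), and reader-agreement
statistics (`06`).  A thin CLI mirrors the stages
(`habitatmri simulate|preprocess|habitat|extract|train|run-all`).

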