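# dwiresponse

Multi-b-value diffusion-weighted MRI (DWI) model fitting and prediction of
pathologic complete response (pCR) to neoadjuvant chemotherapy in breast
cancer.

In breast tumors imaged at thirteen b-values (0–2500 s/mm²), the DW signal
decay S(b) is not mono-exponential: at low b a perfusion (pseudodiffusion)
compartment dominates, and at high b intravoxel heterogeneity flattens the
tail. `dwiresponse` fits three standard decay models per voxel,

- mono-exponential: S(b) = S₀ · exp(−b·ADC), including the two-point
  standard ADC₀,₁₀₀₀ and the flow-insensitive ADC₂₀₀,₁₀₀₀ (b = 200, 1000
  s/mm² exclude the perfusion-dominated regime),
- bi-exponential (IVIM): S(b) = S₀ · [f·exp(−b·D*) + (1−f)·exp(−b·D)],
  fit over the low-b subset (0–800 s/mm²),
- stretched-exponential: S(b) = S₀ · exp(−(b·DDC)^α), fit over the high-b
  subset (0, 500–2500 s/mm²),

and turns the resulting parametric maps — together with lesion size and the
contrast-enhanced relative enhancement ratio RER = (SI_post − SI_pre)/SI_pre
× 100 — into per-patient features at pre-, mid- and post-treatment, with
Δ features (follow-up − baseline). The statistical layer provides
normality-routed group comparison (t / Wilcoxon rank-sum), chi-square /
Fisher tests, empirical ROC curves with DeLong variance, Youden-optimal
cutpoints, paired DeLong AUC comparison, Bonferroni family control, and a
backward stepwise logistic model of pCR with odds ratios, leave-one-out
cross-validation and model-vs-predictor ROC comparison.

Because patient data of this kind are not publicly deposited, the package
ships first-class synthetic generators: Rician-noise DWI phantoms with known
ground-truth maps, and three-timepoint cohorts whose group-conditional
feature distributions, biomarker rates and per-timepoint availability are
calibrated to a published 144-patient NACT cohort (pCR prevalence 37.5%).
Every downstream stage is exercised and tested against these generators.

It is intended for imaging scientists prototyping quantitative-DWI response
biomarkers and for reproducing/stress-testing the associated ROC and
regression methodology.

## Worked example

```python
import dwiresponse as dr
from dwiresponse.features import assemble_features, covariates_table
from dwiresponse.pipeline import pcr_model_pipeline

records = dr.simulate_cohort(seed=1)          # 144 patients, 54 pCR
features = assemble_features(records)         # tidy patient x timepoint x feature
covariates = covariates_table(records)        # ER/PR/HER2/Ki-67, pCR label

table = dr.analyze_cohort(features, covariates)
row = table[(table.feature == "delta_adc_200_1000") & (table.timepoint == "mid")].iloc[0]

res = pcr_model_pipeline(features, covariates)
```

Printing the key quantities of that run gives:

```
mid dADC_200,1000: pCR 0.52 +/- 0.32 vs non-pCR 0.20 +/- 0.23 (1e-3 mm^2/s)
  t p = 6.15e-08; AUC 0.801 (95% CI 0.709-0.892); Youden threshold 0.36
retained: er_negative, delta_adc_200_1000_cat, delta_size_cat, delta_rer_cat
model AUC 0.910 vs dichotomized dADC alone 0.771 (DeLong p = 0.0002)
LOOCV sensitivity 0.757, specificity 0.922, accuracy 0.861
```

Reading: in this simulated cohort the mid-treatment change of the
flow-insensitive ADC is ~0.3×10⁻³ mm²/s larger in responders, discriminates
pCR with AUC 0.80, and its Youden cutpoint (~0.36×10⁻³ mm²/s) defines the
binary imaging predictor; the multivariate logistic model (ER negativity
plus dichotomized imaging changes) raises the AUC to 0.91 and classifies
86% of patients correctly under leave-one-out cross-validation.

The same pipeline runs from the shell:

```bash
dwiresponse run-all --seed 17 --out-dir out/
```

which simulates a phantom, fits the seven parametric maps
(`_adc01000, _adc2001000, _adcall, _dstar, _f, _ddc, _alpha`), simulates a
cohort, writes the per-feature response table and the model outputs, and
records everything in `out/manifest.json`. Runs with the same seed are
byte-identical.

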