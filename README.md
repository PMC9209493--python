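# apvpipe

Multi-regional 3D radiomics and a cascaded two-stage LASSO classifier for
structural brain MRI, producing **Alzheimer's Predictive Vector (ApV)**
scores.

## The problem

Structural T1-weighted MRI carries mesoscopic texture and shape information
beyond what a radiologist reads (hippocampal volume, visual atrophy
scores).  `apvpipe` operationalizes a radiomics strategy for Alzheimer's
disease triage: given a T1w-style intensity volume and a multi-region
parcellation (e.g. a FreeSurfer-derived 115-region mask: 45 white-matter +
70 cortical regions), it extracts **656 quantitative features per region**
— 8 shape descriptors plus, for each of 9 image channels (the original
volume and the 8 sub-bands LLL…HHH of a one-level stationary 3D wavelet
transform), 18 first-order statistics and 54 texture scalars (22 GLCM,
11 GLRLM, 11 GLSZM, 5 NGTDM, 5 NGLDM).  On a 45-region mask that is
29,520 morpho-functional traits per subject.

Classification proceeds in two stages.  Stage 1 (ApV₁) separates subjects
*without* Alzheimer-related pathology (**nADrp**: healthy controls,
Parkinson's disease, frontotemporal dementia) from those *with* it
(**ADrp**: MCI due to AD, plus AD).  Stage 2 (ApV₂) separates prodromal
(MCI_AD) from late (AD) disease among stage-1 positives.  Each stage is the
pipeline

```
z-score on training statistics
  → univariate rank-sum screen, Benjamini–Hochberg FDR < 5%
  → [optionally append standardized cognitive scores (MMSE, LDELTOTAL),
     CSF biomarkers (Aβ, τ, pτ) and age — the "s" variants ApV₁ₛ/ApV₂ₛ]
  → L1-penalized (LASSO) logistic fit, λ chosen by 10-fold cross-validation
  → Youden-optimal operating threshold on the training ROC
```

The ApV score of a subject is the linear predictor

```
ApV = β₀ + Σᵢ βᵢ zᵢ ,
```

the weighted sum of the selected standardized features.  Evaluation uses
the standard diagnostic-accuracy panel (AUC, sensitivity, specificity,
accuracy, PPV/NPV, LR+, LR−, Youden index, diagnostic odds ratio, with NA
for any zero-denominator metric), plus ICC(1,1) and Bland–Altman for
test–retest repeatability.

Because the clinical imaging cohorts this kind of model is trained on are
access-restricted, the package ships a seeded **phantom generator**:
cohorts of labelled 3D volumes whose groups differ in region volume
(atrophy), mean intensity, and texture correlation length, with a truth
table of the planted signal.  All end-to-end tests run on these phantoms.

## Worked example

```python
import pandas as pd
from apvpipe import (
    default_catalogue, make_cohort, phantom_region_table, study_spec,
    cohort_feature_matrix, fit_stage, train_validation_split,
)
from apvpipe.cascade import STAGE1_CONTRAST, StageConfig

spec = study_spec(shape=(48, 48, 48))      # 3 signal regions, CN/MCI_AD/AD
cohort = make_cohort(spec, n_per_group=12, seed=11)
fm = cohort_feature_matrix(
    cohort, phantom_region_table(spec.n_regions),
    default_catalogue(channels=("original",)),
)
train, val = train_validation_split(fm, 0.7, seed=0)
model = fit_stage(train, STAGE1_CONTRAST, config=StageConfig(folds=5))
y = val.binary_labels(set(STAGE1_CONTRAST[0]), set(STAGE1_CONTRAST[1]))
report = model.evaluate(val.select_subjects(y.index), y)
print(f"selected features: {len(model.selected)}")
print(f"validation AUC:    {report.auc:.3f}")
print(f"accuracy at Youden threshold {model.threshold:+.3f}: {report.accuracy:.3f}")
```

prints

```
selected features: 7
validation AUC:    1.000
accuracy at Youden threshold +6.573: 0.727
```

— the LASSO keeps a handful of features (all lying in the three
signal-bearing phantom regions), and the held-out ROC separates the
disease supergroup perfectly.  The training-derived operating threshold is
optimistic at this tiny cohort size (it classifies 8 of the 11 held-out
subjects correctly); the acceptance experiments at 60 subjects per group
recover both a high AUC and an accurate threshold.

A command-line interface mirrors the pipeline stages:

```sh
apvpipe phantom --out cohort/ --n-per-group 10 --grid 48
apvpipe extract cohort/manifest.csv --out features.csv --region-set WM45
apvpipe train features.csv cohort/cohort.csv --out run/
apvpipe predict run/cascade_model.json features.csv --out predictions.csv
apvpipe robustness run/cascade_model.json features.csv cohort/cohort.csv --out subsets.csv
apvpipe icc repeats.csv
```

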