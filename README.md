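# tmemorph

Tumor-microenvironment (TME) morphometry from histopathology
tissue-segmentation maps, for predicting pathological complete response
(pCR) to neoadjuvant chemotherapy in HER2-positive breast cancer.

## What it does

Whole-slide H&E images are far too large to model directly. This
package works at **tile resolution**: a slide is cut into fixed-size
tiles (175 × 175 px by default), non-tissue tiles are removed with a
per-slide Otsu threshold (tiles under 20 % tissue are excluded), and a
sequential cascade of binary tile classifiers builds a
**tissue-segmentation image (TS-image)** — one compartment label per
tile over {excluded, tumor, stroma, necrosis, iTIL, sTIL}, where
iTILs/sTILs are tumor-infiltrating lymphocytes inside tumor and stroma
respectively, and TILs is their union.

From each compartment mask the package computes 8-connected components
and derives **46 morphological features** from 11 regionprops-style
descriptors (area, filled area, convex area, major/minor axis length,
eccentricity, Euler number, extent, solidity, perimeter, orientation)
under three aggregation strategies:

* **all regions (AR, 12)** — component count + descriptor means;
* **largest region (LR, 11)** — descriptors of the largest component;
* **significant regions (SR, 23)** — count, mean and standard deviation
  over components whose area strictly exceeds 5 % of the largest
  component's area.

Morphological features are fused with five clinical covariates (ER/PR
status and percentage, HER2/CEP17 ratio), standardized on the training
cohort, selected by **LASSO** (L1-penalized logistic regression, penalty
chosen by stratified ten-fold cross-validated grid search on AUC), and
fed to an **L2-regularized MLP** evaluated on a held-out cohort with
AUC, F1, PPV, recall and NPV. Univariate machinery (Mann–Whitney U,
Chi-square/Fisher, Spearman correlation with residual infiltration
size) and baseline TME metrics (tile counts; TSR, iTR, sTR, TISR, LD
ratios) round out the analysis.

Because the clinical cohorts such pipelines are built on are
restricted, the package ships a **seeded synthetic-cohort generator**:
blob-process tissue layouts with planted, configurable group
differences in sTIL component count and size, clinical covariates, and
a residual-infiltration-size outcome (0 for pCR by definition). Every
downstream stage is tested against this known ground truth.

## Worked example

```python
from tmemorph import (CohortConfig, generate_cohort,
                      assemble_cohort_table, run_compartment_model)
from tmemorph.stats import importance_report

train = generate_cohort(CohortConfig(n_patients=140, pcr_fraction=0.5,
                                     effect_size=1.5, seed=7))
evalc = generate_cohort(CohortConfig(n_patients=60, pcr_fraction=0.5,
                                     effect_size=1.5, seed=1007))
report = run_compartment_model(assemble_cohort_table(train),
                               assemble_cohort_table(evalc),
                               compartment="stil")
print({k: round(v, 3) for k, v in report.metrics.items()})
for name, w in importance_report(report.selected_features)["favorable"]:
    print(f"+{w:.3f}  {name}")
```

prints

```
{'auc': 0.916, 'f1': 0.8, 'ppv': 0.8, 'recall': 0.8, 'npv': 0.8}
+1.127  stil__ar__component_count
+0.830  stil__sr__filled_area__mean
+0.323  stil__sr__num_significant
```

The held-out AUC of 0.916 reflects the planted effect (a 1.5-SD shift
in sTIL component count and area for pCR patients), and the top
favorable LASSO weights land exactly on the planted quantities: the
number of sTIL components and their filled area.

A thin CLI mirrors the library:
`tmemorph simulate`, `tmemorph features`, `tmemorph model`,
`tmemorph univariate` (see `tmemorph --help`).

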