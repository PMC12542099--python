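# Methods

## Pipeline model

The analysis treats a slide as a grid of 175 × 175 px tiles (the tile,
not the pixel, is the unit of analysis; all areas below are in tiles).
Tissue detection uses Otsu's threshold computed once per slide on
grayscale luminance; a pixel is tissue when strictly darker than the
threshold, and tiles with tissue fraction below 20 % are excluded (the
boundary tile at exactly 20 % is retained, matching the strict
"below … excluded" rule). A constant slide has no Otsu split and is
treated as tissue-free. Partial tiles at the right/bottom edges are
dropped; the grid origin is the top-left corner, indices 0-based.

Tissue-segmentation images (TS-images) are built by a sequential
cascade of three binary tile classifiers: (1) tumor vs stroma; (2)
necrosis detection within tumor tiles — necrotic tiles are terminal
because necrosis morphologically mimics intratumoral lymphocytes and
must not enter the TIL search; (3) lymphocyte detection, relabeling
tumor tiles as iTIL and stroma tiles as sTIL. Each step uses a hard
0.5 cutoff by default (configurable). Label codes: 0 excluded, 1 tumor,
2 stroma, 3 necrosis, 4 iTIL, 5 sTIL; TILs = iTIL ∪ sTIL. Trained
CNN tile classifiers are out of scope: the cascade accepts any object
with a `predict(tile) -> probability` method, and the package ships
rule-based reference classifiers that exactly invert the synthetic
tile renderer's class encoding, plus a direct TS-image ingestion path.
The order of the necrosis and lymphocyte tests within tumor tiles, and
the per-step cutoffs, are explicit package choices.

## Morphometry

Compartment masks are decomposed into 8-connected components
(scikit-image labeling, cross-checked against a brute-force BFS oracle
in the test suite). The 11 descriptors per component are area, filled
area, convex area, major/minor axis length, eccentricity, Euler
number, extent, solidity, perimeter and orientation. Axis lengths and
eccentricity derive from the second-order central moments of the
pixel-center distribution (so a 1 × n bar has eccentricity exactly 1);
convex area uses the diamond-offset pixel extent with boundary centers
included; the Euler number pairs 8-connected foreground with
4-connected holes, while hole *filling* (filled area) treats the
background as 8-connected — the complementary-connectivity pairing
each operation conventionally uses.

Aggregation strategies: all-region = component count + per-descriptor
means (12 values; the mean was chosen as the aggregate since only "all
components are analyzed" is specified); largest-region = the 11
descriptors of the largest component; significant-region = count, mean
and population standard deviation (ddof 0; a single significant
component yields std 0, not missing) over components whose area
**strictly exceeds** 5 % of the largest component's area. The strict
inequality and the threshold are configurable; thresholds of 1–10 %
are exercised by `threshold_sweep`, which re-extracts features per
threshold and re-runs the full model. An absent compartment yields NaN
for all 46 features; imputation happens later from training medians
only. Exact feature identities beyond those named in the source
material (four of the eleven descriptors — extent, solidity,
perimeter, orientation — are standard regionprops additions chosen to
reach the printed cardinalities 12/11/23) are configuration, isolated
in one module constant.

Baseline TME ratios are defined as TSR = stroma/(tumor+stroma),
iTR = iTIL/(tumor+iTIL), sTR = sTIL/(stroma+sTIL),
TISR = TILs/(tumor+stroma+TILs), LD = TILs/(informative tiles); the
exact historical denominators are not published, so these definitions
are the package's own, kept in a single function for easy revision.

## Modeling

Features are standardized to zero mean and unit (population) standard
deviation using training rows only; NaNs are imputed with training
medians before scaling and zero-variance columns map to 0. LASSO is
realized as L1-penalized logistic regression (liblinear), with the
inverse penalty C chosen from a log grid (10⁻²…10², 9 points) by
stratified ten-fold cross-validation maximizing mean AUC; ties prefer
the stronger penalty. Nonzero coefficients at the chosen penalty are
the selected features and reported weights. The predictor is a
single-hidden-layer MLP with L2 weight decay (lbfgs, 500 iterations,
fixed seed), hidden size ∈ {4, 8, 16} and α ∈ {10⁻³, 10⁻², 10⁻¹} tuned
on the same folds; ties prefer the smaller network and stronger decay.
If LASSO selects nothing the pipeline degrades to a constant 0.5
predictor (AUC exactly 0.5). The decision cutoff for F1/PPV/recall/NPV
is 0.5. AUC is computed by rank concordance with half credit for ties
(the Mann–Whitney formulation); undefined ratios (e.g. NPV with no
negative predictions) are NaN. When a cross-validation request exceeds
the minority-class count, folds are reduced with a warning.

The learning-curve experiment subsamples training rows with
stratification at each fraction while the CV/MLP seed stays fixed, so
fraction 1.0 reproduces the full-pipeline run bit for bit and
replicates differ only through the subsample.

## Univariate statistics

Continuous variables: two-sided Mann–Whitney U — exact when both
groups have ≤ 20 untied observations, tie-corrected normal
approximation otherwise. Categorical variables: Chi-square, or
Fisher's exact for 2 × 2 tables when any expected cell count is ≤ 5
(Fisher is validated in the tests against exhaustive hypergeometric
enumeration of all tables with total ≤ 40). Spearman correlations
against residual infiltration size (RIS) use midranks; pCR patients
enter as a tied block at RIS = 0 by definition. All tests are
two-sided at the 0.05 level with no multiplicity correction; reports
carry the number of tests performed.

## Synthetic cohorts

The generator emulates the structure of a neoadjuvant-chemotherapy
cohort: by default 85 patients, 42 % pCR, 48 × 48 tile grids, non-pCR
median RIS 1.35 cm. Layout: two smoothed Gaussian noise fields are
thresholded at exact per-slide quantiles to carve out ~10 % excluded
tiles and a 50/50 tumor/stroma split of the tissue, giving irregular
blob geometry. Necrosis (Poisson mean 2 components of 2–7 tiles) and
iTILs (Poisson mean 3 components of 1–5 tiles) are grown inside tumor
regions, group-independently. The planted signal acts on sTIL
morphology: component count ~ round(N(6 + 1.5·effect·…, 2)) — i.e. the
pCR group's mean count (baseline 6, SD 2) and mean component area
(baseline 7 tiles, SD 2.5) are both shifted upward by `effect_size`
standard deviations. sTIL blobs grow with a one-cell buffer from each
other so the planted count survives 8-connected labeling. Clinical
covariates: ER positive with probability 0.65; PR positivity has
baseline log-odds 0.2 shifted by `clinical_effect` for pCR patients;
percentages are uniform on [10, 100] when positive and 0 otherwise;
HER2/CEP17 is lognormal with median 3.2. RIS is 0 for pCR and
lognormal (σ = 0.8) with median `ris_scale` for non-pCR, damped by
0.3 × the standardized planted sTIL burden so heavier lymphocyte
infiltration tracks smaller residual tumors. Everything is
reproducible bit for bit from the seed.

What the generator does **not** emulate: pixel-level H&E texture,
nucleus-scale structure, classifier noise (the reference classifiers
are exact by construction), spatial correlation between clinical and
morphological covariates beyond the planted effects, and cohort-level
batch effects. Passing tests therefore demonstrate the correctness of
the measurement and modeling machinery under known ground truth — not
clinical performance on real slides.

For feature-selection experiments a second, feature-level generator
produces 51 independent columns (matching 46 morphology + 5 clinical)
with 3 planted informative columns shifted by the effect size; this
makes "informative" well-defined, whereas the image-level generator's
planted effects spread over correlated columns.

## Experiment sizes and numerical choices

The shipped experiments use 140 training / 60 evaluation patients on
48 × 48 grids with effect size 1.5, 20 replicates for selection
recovery, 3 replicate null cohorts (the mean held-out AUC of a null
pipeline is compared against chance; a single 60-patient split has
sampling SD ≈ 0.075, so the replicate mean is the meaningful check),
and 10 replicates at fractions 0.2/1.0 for the learning curve — sizes
chosen so the full suite runs in minutes on one CPU while keeping
Monte-Carlo error well inside the asserted bands. Degenerate inputs
are defined throughout: empty masks yield empty component lists,
all-excluded grids yield NaN ratios, constant vectors yield flagged
NaN correlations, and unknown label codes or receptor statuses raise
errors naming the offending value.

## Known limitations

Tile-resolution morphometry ignores sub-tile structure; the 46-feature
list reproduces printed cardinalities but not necessarily the original
feature identities; the relative-metric denominators are best-effort
reconstructions; and synthetic performance numbers (e.g. the 0.916
held-out AUC of the worked example) characterize the planted effect,
not any clinical cohort.
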