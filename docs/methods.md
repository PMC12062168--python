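# Methods

`sirtomics` implements a complete tumor-response-prediction pipeline for
⁹⁰Y selective internal radiation therapy (SIRT): voxel-level dosimetry from
SPECT count maps, biologically effective dose (BED), dose-volume-constraint
(DVC) extraction, radiomic/dosiomic feature engineering, and a
nested-cross-validated machine-learning harness. Because clinical SIRT
cohorts cannot be redistributed, the pipeline ships with — and is validated
on — a seeded synthetic SPECT/CT phantom generator with known ground truth.

## Synthetic phantom cohort

Each case is built from spherical primitives: a whole liver (default radius
70 mm at the full 64³/4 mm study geometry), a perfused lobe (54 mm) tangent
to its boundary, and a tumor (17 mm) concentric with the lobe. Normal
structures are derived by subtraction: NPL (normal perfused liver) = lobe −
tumor, WNL (whole normal liver) = liver − tumor, so the mask algebra
|NPL| + |tumor| = |lobe| holds exactly by construction.

Activity uptake is a smooth lognormal texture field (Gaussian-smoothed white
noise, correlation length 8 mm) normalized per structure so that the mean
tumor-to-NPL uptake ratio equals the configured TNR *exactly* before noise —
this makes the dosimetric ground truth analytic. Liver tissue outside the
perfused lobe carries a 0.3 relative uptake floor, mimicking the background
that scatter-uncorrected bremsstrahlung reconstruction spreads over the
organ. Counts are scaled to an expected total (default 2×10⁶) and Poisson
noise is applied per voxel; `noise_model="none"` disables it for recovery
tests. The MAA (pre-therapy surrogate) and ⁹⁰Y (post-therapy) SPECT channels
share one activity field with independent noise draws; an optional
`maa_mismatch` knob (default 0) blends the MAA tumor contrast toward uniform
uptake, modelling imperfect surrogacy.

CT is piecewise-constant HU with mild texture: air at −1000 HU, a
soft-tissue body shell ≈ 20 HU, liver parenchyma ≈ 55 HU, tumor ≈ 40 HU.

Defaults emulate the study conditions the pipeline targets: 17 cases with
5 responders / 12 non-responders, ≈ 2.8 GBq administered activity, TNR 2.5,
lung shunt fraction 0.05. With these choices the default mean tumor dose is
≈ 380 Gy and mean NPL/WNL doses ≈ 150/95 Gy — inside the range where the
fixed dosiomics clip caps (below) are meaningful. The responder
`class_effect` multiplies tumor uptake by 1.5 and the uptake-texture
correlation length by 2 (responders show higher, smoother dose deposition);
setting it to `{}` yields a null cohort in which responders and
non-responders are statistically indistinguishable. Clinical covariates
(9 continuous + 5 binary = 14 columns; sex and extrahepatic metastasis are
excluded up front for extreme class imbalance and never generated) are
simulated with a configurable label association, default 0 (pure noise).

What the phantom does *not* emulate: projection/reconstruction physics
(no OSEM, collimator or scatter modelling), registration error, anatomical
shape variation, and multi-focal disease. Passing tests therefore
demonstrate correctness of the computational pipeline and of its statistical
behaviour under known ground truth — not clinical performance on patients.

## Dosimetry

The local deposition method (LDM) assumes each voxel's emitted β energy is
absorbed locally. Counts are converted to dose by self-calibration: the
counts summed over a calibration region (default: whole liver; the whole
body is a config option) are equated to the full administered activity, so

    dose_v = counts_v / Σ_cal counts × A [GBq] × E [J/GBq] / m_v [kg].

E defaults to 49.67 J/GBq, the total β energy emitted per GBq of ⁹⁰Y
(mean β energy 0.9337 MeV × number of decays A/λ); it is a config field, not
a hard-coded constant. Voxel mass defaults to uniform density 1.0 g/cm³; a
CT-density mode (ρ = 1 + HU/1000) is available. An optional flag deducts the
lung shunt fraction from the administered activity before calibration
(default off). Both choices are deliberate config switches because either
convention is defensible and the in-house codes used clinically do not agree
on them. Consequences tested: energy is conserved over the calibration
region to 1e−10 relative; the dose map is invariant to global count
rescaling (acquisition duration cancels); dose is linear in activity; and on
a noiseless phantom the mean tumor dose matches the analytic truth to
< 0.1 %.

BED uses the linear-quadratic model for permanent implants:

    BED = D · (1 + D/(α/β) · T_rep / (T_rep + T_phys)),

with α/β = 10 Gy for both tissue classes, repair half-time T_rep = 1.5 h
(tumor) / 2.5 h (normal liver), and T_phys = 64.2 h (⁹⁰Y). Tumor voxels are
transformed with tumor parameters, all non-tumor liver with normal
parameters, everything else is zeroed. BED ≥ D always, BED/D → 1 as D → 0,
and BED(100 Gy) = 122.831 / 137.481 Gy for tumor / normal parameters (hand
arithmetic, frozen in tests).

## DVH and the DVC catalogue

All DVH metrics are computed from raw voxel doses (exact at voxel
granularity); the binned cumulative curve (default 0.1 Gy bins) exists only
for export. D_x uses the descending-sorted voxel convention without
interpolation — D_x is the dose of the coolest voxel among the hottest x% —
because it is exact, matches treatment-planning exports, and is trivially
checkable against a sort-and-count oracle. V_x counts voxels at or above the
threshold, reported in both ml and %, with the two consistent to 1e−12.
D_max/D_min are raw extrema.

The per-case record covers, for each structure (tumor, NPL, WNL) × channel
(MAA, ⁹⁰Y) × dose kind (Dose, BED): volume, D_mean/max/min, D5, D50, D70,
D95, D98, and V120/V205/V400 (plus V20/V30/V50/V70/V90 for NPL and WNL),
each V in ml and %; plus the tumor homogeneity index HI = D5/D95, TNR vs NPL
and WNL, the lung shunt fraction and the injected activity. Column names are
deterministic (`<structure>_<channel>_<kind>_<metric>`), giving a fixed
schema of 274 constraints per case. The V-threshold list is applied
identically to Dose and BED maps.

## Feature extraction

Preprocessing is channel-specific: CT is resampled to 1.5×1.5×1.5 mm³
(linear; masks nearest-neighbour) and clipped to [−500, 500] HU; SPECT is
clipped between 0 and its own 99.9th percentile (bremsstrahlung images carry
sparse very hot voxels); dose and BED maps are clipped at fixed
per-structure, per-channel caps — MAA: 650.34 / 158.02 / 127.08 Gy and ⁹⁰Y:
416.25 / 133.16 / 123.08 Gy for tumor / NPL / WNL — so the gray-level range
is identical across cases. Discretization uses fixed bin widths: 50 counts/s
(SPECT), 20 HU (CT), 1 Gy (dose/BED). SPECT and dose maps keep their native
grid.

Each (structure, channel) pair yields 107 features — 18 first-order,
14 shape-3D, 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM — the
default-enabled set of the standard IBSI-conformant extractors, implemented
here directly in NumPy/SciPy/scikit-image and guarded by hand-computed
first-order values and brute-force texture-matrix oracles in the test suite.
(Extractor documentation sometimes lists larger per-family catalogues — 19
first-order, 17 shape-3D, 10 shape-2D — but those sum past 107; this package
fixes the 107-feature schema, which is the one consistent with
321 = 3 × 107 columns per channel.) Texture conventions: 26-connectivity
(13 unique directions at distance 1), symmetric GLCM, per-direction features
averaged over directions, matrices indexed by the gray levels present.
Degenerate flat ROIs return natural limits (GLCM correlation 1, NGTDM
coarseness capped at 10⁶) instead of NaN; any NaN that still arises is
median-imputed inside training folds only. Shape features are computed from
the mask alone — marching-cubes mesh for surface/volume/sphericity
(voxelization inflates the mesh surface of a sphere by ≈ 10 %, a known
artifact reflected in test tolerances), PCA axis lengths, convex-hull
maximum diameters — and are therefore duplicated across channels sharing a
grid; the duplication is left to Spearman redundancy pruning.

Dosiomics is this same extractor applied to dose/BED maps (dose caps + 1 Gy
bins); there is no separate math path. A channel table is 3 × 107 = 321
columns named `<family>_<feature>_<structure>`; cases with missing or empty
structures are excluded with a log entry.

## Modeling harness

The experiment grid is 6 categories — {MAA, ⁹⁰Y} × {radiomics, dosiomics,
DVH} — × 6 input mixes (radiomics: CT, SPECT, CT+Clinical, SPECT+Clinical,
CT+SPECT, CT+SPECT+Clinical; dosiomics/DVH: Dose, BED, Dose+BED,
Dose+Clinical, BED+Clinical, BED+Dose+Clinical) = 36 strategies, crossed
with 5 feature selectors × 8 classifiers = 1440 models. Merged tables
prefix columns by source so identical feature names from different channels
stay distinct.

Evaluation is threefold nested CV, with everything that learns from data fit
inside training folds only: per outer fold, features are z-scored with
training statistics (sample sd, ddof = 1; zero-variance columns dropped),
pruned so no pair retains |Spearman ρ| ≥ 0.90 (keep-rule: better training
ANOVA F, ties lexicographic), and the inner threefold loop grid-searches the
classifier hyperparameters together with the number of selected features
k ∈ {5, 10, 15}. SMOTE (k = 5 neighbours, reduced when the minority is
smaller) balances the training folds after feature selection — the order
prune → FS → SMOTE → fit is the default because selection statistics on real
rather than interpolated samples are better behaved at n ≈ 11; a
`smote_before_fs` switch provides the other order. The refit model predicts
the untouched outer test fold; metrics (AUC, ACC, SEN, SPE; positive class =
responder) are pooled over outer-test predictions and also reported per
fold. ROC confidence intervals use 1000 case-resampling bootstraps
(single-class resamples skipped and counted). AUC pairs on the same cases
are compared with the DeLong test (fast midrank algorithm), cross-checked
in tests against an exact paired swap-permutation oracle at n = 10 and the
AUC–Mann-Whitney-U identity.

Feature selectors: ANOVA F and Kruskal-Wallis H (univariate filters); MRMR
as the classic greedy mutual-information MID scheme (quantile-binned MI for
both relevance and redundancy — MI puts both on one scale, so duplicates of
selected features are properly penalized, which F-statistic/correlation
hybrids fail to do); binary ReliefF with 5 nearest hits/misses; RFE on a
logistic model eliminating 20 % per step. Classifiers: scikit-learn
DT/LR/MLP/NB/RF/SVM, XGBoost, and GLMB — boosting of a generalized linear
model — realized as component-wise gradient boosting of univariate linear
base learners under the logistic loss (a glmboost-style sparse linear
ensemble), since no reference implementation pins the variant. Default
hyperparameter grids are small published-convention ranges recorded in
`modeling.classifiers.DEFAULT_GRIDS`.

Univariate screening uses the Mann-Whitney U test (continuous) and Fisher's
exact test (categorical) with Benjamini-Hochberg adjustment at q = 0.05,
reporting significance before and after adjustment.

Determinism: a master seed drives cohort generation, fold shuffling, SMOTE,
bootstraps and every classifier; per-model seeds are derived arithmetically
from the master seed, so the full grid is bit-reproducible.

## Problem sizes and numerical choices

The test suite and the reproduction script use a compact 48³ / 4 mm phantom
geometry (tumor ≈ 230 voxels, WNL ≈ 9000) that preserves every structural
property of the full 64³ geometry while keeping single-case feature
extraction sub-second and the reduced 2 FS × 2 ML × 36-strategy smoke run in
minutes; the full 1440-model grid is enumerated and count-verified without
training, and can be trained with `run_experiment` on the full classifier
set when wall-clock time is no constraint. Tolerances follow the quantity's
nature: exact equality for counting/sorting results (DVH vs oracle),
1e−10 relative for energy conservation, 0.1 % for phantom dose recovery,
hand-value precision (5e−4 Gy) for BED points, and distributional bands
(±0.15 around AUC 0.5 over 20 replicates) for stochastic nulls.

## Known limitations

- Shape features on near-identical organ masks are (near-)constant across a
  synthetic cohort; they are dropped by the zero-variance rule inside folds,
  as they would be for any degenerate real cohort.
- The GLMB and Relief variants are package choices among several published
  ones; results for those selectors/classifiers are internally consistent
  but not comparable to a specific external implementation.
- SVC probability outputs use Platt scaling on tiny training sets; ranking
  (AUC) is reliable, calibrated probabilities are not.
- The phantom's label effect operates through uptake scale and texture
  only; CT shape differences between classes are not simulated, so
  CT-radiomics strategies on default phantoms carry little signal — by
  design, mirroring a null rather than optimistic scenario.
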