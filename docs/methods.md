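# Methods

`ftvmorph` implements a DCE-MRI morphology analysis for early prediction
of poor pathologic response to neoadjuvant chemotherapy, end to end:
functional tumor volume (FTV) segmentation, mask conditioning, 3D shape
features, feature-table assembly with forest imputation, and
nested-resampling evaluation of four learners. Because the clinical
imaging such an analysis runs on cannot ship with a software package,
a seeded phantom generator provides cohorts with the statistical
structure the analysis assumes; everything downstream of the generator
is the same code a real cohort would flow through.

## Enhancement maps and FTV

Each exam holds three aligned T1-weighted volumes: pre-contrast
`S_pre`, early post-contrast `S_early`, late post-contrast `S_late`.
Two voxelwise kinetic maps are derived:

    PE  = 100 * (S_early - S_pre) / S_pre        (percent enhancement)
    SER = (S_early - S_pre) / (S_late - S_pre)   (signal enhancement ratio)

Voxels with a near-zero denominator (relative tolerance 1e-6 of the
intensity scale) are marked invalid rather than produced as infinities.
The FTV mask is the set of valid voxels inside the radiologist-style
VOI box with PE strictly above 70% and SER inside a configurable band;
by default no SER cut is applied (`[0, inf)`), since only the PE
threshold is integral to the segmentation — SER bands are primarily a
display convention (washout above ~1.1, plateau near 1, persistent
below). Both thresholds are config-exposed. FTV is the voxel count
times the voxel volume; the longitudinal summary is FTV_R = FTV(T1) /
FTV(T0). A zero T0 FTV makes the ratio undefined; it is treated as
missing and routed to imputation, never given a sentinel value.

## Mask conditioning

Four steps in a fixed order, applied to the raw FTV mask before any
shape measurement:

1. **Resample** to 1 mm isotropic voxels, nearest neighbor, voxel-center
   aligned (SimpleITK).
2. **Close** with a ball of 5 mm physical radius (a 515-voxel digital
   ball on the 1 mm grid), filling small holes. The input is padded by
   the ball radius so the result equals the unbounded-domain closing.
3. **Anti-alias** the binary image: min/max curvature flow first removes
   voxel-scale spikes and pits while preserving larger structure, then
   an RMS-bounded level-set fit (SimpleITK `AntiAliasBinary`, 50
   iterations, max RMS 0.01) smooths the staircase; the zero level is
   re-binarized. Volume change is below 5% for smooth solids of radius
   >= 8 mm.
4. **Remove small components**: 26-connected components of <= 100 voxels
   are deleted (the boundary is inclusive: exactly 100 goes, 101 stays).

Component connectivity and every numeric parameter are config-exposed;
the defaults above are the analysis constants. The pipeline records
per-step voxel counts in a provenance log, and a mask emptied by the
size filter is a legitimate degenerate result (missing features), not
an error.

## Shape features

Seventeen 3D shape features are computed per conditioned mask, the
standard mesh/PCA family of exactly that cardinality: mesh volume V,
voxel volume, surface area A, surface-area-to-volume ratio A/V,
sphericity `(36 pi V^2)^(1/3) / A`, compactness1 `V / (sqrt(pi)
A^(3/2))`, compactness2 `36 pi V^2 / A^3`, spherical disproportion
(the reciprocal of sphericity), maximum 3D diameter, three maximum 2D
diameters (one per axis-aligned projection plane), three PCA axis
lengths (`4 sqrt(lambda)` from the voxel-center coordinate covariance
eigenvalues), elongation `sqrt(lambda_2 / lambda_1)` and flatness
`sqrt(lambda_3 / lambda_1)`.

Numerical choices that matter:

- The surface is triangulated by marching cubes at iso-level 0.5 on the
  one-voxel-padded mask, then relaxed by **shrink-free Taubin
  lambda/mu smoothing** (10 iterations, lambda 0.5, mu -0.53). Raw
  staircase meshes overstate the area of a digitized sphere by ~9%;
  Taubin relaxation brings area within ~2% and volume within ~1% of
  the closed forms while being scale-invariant, so the scale laws
  (V ~ s^3, A ~ s^2, A/V ~ 1/s) hold across sizes. Mesh volume is the
  divergence-theorem sum of signed tetrahedra.
- **Maximum diameters are measured on surface-voxel corner points**,
  not mesh vertices: marching cubes bevels corners, which would
  understate a cube's space diagonal by ~6%; corner points recover it
  exactly. Largest pairwise distances are taken over the convex hull.
- Masks of fewer than 8 voxels cannot support a meaningful surface;
  their entire feature vector is flagged missing (NaN) and flows to
  imputation. This mirrors how real degenerate post-treatment masks
  produce missing shape data.

The longitudinal morphology variables are the 17 elementwise T1/T0
feature ratios; a ratio is missing when either endpoint is missing or
the T0 value is zero. With the T0 and T1 vectors this gives the 51
shape variables of the modelling table.

## Feature table and imputation

The modelling table has one row per patient: 51 shape variables, FTV_R,
age, one-hot-encoded race / menopausal status / HR-HER2 subtype (largest
observed category as the dropped reference; "Unknown" retained as a
level), and a binary outcome. Three dichotomizations of the residual
cancer burden (RCB) class are supported — pCR (RCB-0 vs rest), RCB-0/I
vs II/III, and RCB-III vs rest; the headline endpoint is RCB-III, the
poor-response class. Cohort filters drop records flagged for missing
pathology, missing clinicopathologic data, missing imaging, or poor
imaging quality, counting each record once under the first flag in that
precedence order.

Missing entries are imputed by an iterative random-forest scheme in the
style of missForest: initialize missing numerics at column medians,
sweep columns in order of increasing missingness fitting a
`RandomForestRegressor` of observed-on-others and predicting the
missing entries, and stop when the mean-square change between sweeps
stops decreasing or after 10 sweeps. Observed entries are never
altered, the outcome column is never used, and the fitted per-column
forests can be applied to held-out rows, which allows the leakage-safe
placement: by default imputation is fit inside each outer training set
and applied to its test set. Whole-table imputation before resampling
(the simpler, likely-original placement) is config-exposed
(`imputation: whole_table`).

## Evaluation

Four learner families (scikit-learn): elastic-net logistic regression
(saga solver behind a standardizer), CART, random forest, and gradient
boosting. Nested resampling: 20 outer stratified train/test splits
(test fraction 0.25, split i seeded `base_seed + i`), inner stratified
5-fold grid search on the training part only, winner refit and scored
on the held-out part with rank-based (Mann-Whitney) AUC, ties at 1/2.
Performance is the mean +/- SD of the 20 outer AUCs; the optimal family
is the highest mean (ties: lower SD, then a fixed family order).
Paired model comparison uses the two-sided Wilcoxon signed-rank test
with zeros dropped and midranks for ties; for up to 25 nonzero pairs
the exact null distribution is computed by dynamic programming (exact
even under tied |differences|), beyond that the normal approximation.

Tuning grids (config-exposed; `paper` preset): elastic net, mixing
{0.1, 0.5, 0.9, 1.0} x 10 log-spaced penalty values; CART, depth
{2, 3, 4, 6} x min leaf {5, 10, 20}; forest, 500 trees x
variables-per-split {sqrt(p), p/3, p/5} x min leaf {1, 5, 10}; GBM,
trees {100, 300} x depth {1, 2, 3} x learning rate {0.01, 0.1}. A
reduced `fast` preset (2-4 configurations per family, 100-tree forests)
is used by the bundled analyses, the tests, and the acceptance script
to keep single-CPU runtimes in minutes; the evaluation machinery is
identical under both presets.

Variable importance: for the random forest, the classic per-tree
out-of-bag permutation importance — mean decrease in accuracy (%) of
each tree on its OOB rows after permuting one variable. In-sample
ensemble-level permutation was rejected for the forest because a
fully-fit forest memorizes the table (decreases become single-sample
noise) and ensemble redundancy masks correlated variables. CART and
GBM use ensemble-level permutation accuracy at the 0.5 threshold over
50 seeded shuffles; the elastic net reports standardized-coefficient
magnitudes (|coefficient| x SD), numeric variables only. Subgroup
analyses rerun the full with/without-shape comparison inside one
HR/HER2 stratum and emit an omission notice instead of results when the
stratum has fewer than 8 events.

Univariate reporting uses the unpaired Mann-Whitney rank-sum test for
numeric group contrasts (the outcome groups are independent samples;
the signed-rank test is reserved for paired AUC vectors), Fisher's
exact test for categoricals — implemented for 2 x c tables by exact
enumeration over the margin-constrained lattice (verified against R's
`fisher.test`; seeded Monte Carlo beyond ~2e6 tables) — and Spearman
correlation for FTV-vs-shape associations.

## The phantom generator

Tumors are star-convex solids `r(theta, phi) = R (1 + a P(theta,
phi))` with `P` a fixed real spherical harmonic (order 3 by default)
normalized to unit peak, so one amplitude knob controls surface
irregularity — and hence SA:V — independently of the volume scale.
Intensities: flat pre-contrast at 100; per-voxel tumor PE drawn from a
normal (mean 120%, SD 15%) truncated at +/-3 SD so tumor/background
separation holds by construction; background PE 10%; tumor SER normal
(1.1, 0.3) clipped below at 0.2; additive Gaussian noise (SD 2 by
default). Solving `S_early` and `S_late` from the drawn PE and SER
makes noise-free phantoms segment back to the generating mask
voxel-for-voxel, which is the segmentation oracle used in tests.

A cohort draws per patient: HR/HER2 subtype, race, menopausal status
and age from margins emulating a large multicenter neoadjuvant trial
population; an RCB class from margins (0.346/0.140/0.359/0.155); a T0
radius (normal 12 +/- 3 mm, clipped to [6, 18]); a T0 lobulation
amplitude (uniform 0.05-0.25); and the treatment effect — a linear
shrink factor s and a lobulation-amplitude change, both class-
conditional. Default effect distributions give responders strong
shrinkage (RCB-0 s ~ 0.45) plus roughening (+0.15 amplitude) and
RCB-III near preservation of both (s ~ 0.90, +0.00), reproducing the
direction of the observed group contrasts (responders' SA:V ratio
higher; poor responders retain size and shape). The magnitudes are a
stylization: no published effect sizes link shape change to RCB class,
so defaults are calibrated to direction only. With probability 0.05 a
T1 tumor is collapsed below the shape-computable size, exercising the
missing-data path; complete responders whose residual falls under the
100-voxel floor add further natural degeneracy. Each patient is seeded
from `(cohort_seed, patient_index)`, so cohorts are bit-reproducible
and patients independent of iteration order.

What the generator does **not** emulate: pharmacokinetics, coil/scanner
artifacts, motion, multi-site batch effects, non-mass-like enhancement,
infiltrative or multifocal morphologies, and any coupling between
covariates and outcome (subtype and outcome are drawn independently,
unlike real cohorts). Passing tests therefore certify the pipeline's
measurement and inference machinery — segmentation fidelity, geometry
recovery, calibration, leakage-freedom, and the ability to detect a
shape-borne outcome signal — not clinical performance on trial data.

## Degenerate inputs and edge rules

- PE exactly at the threshold is excluded (strict `>`, "above 70%").
- Empty FTV masks are allowed (FTV 0); an all-missing FTV-ratio column
  aborts assembly with a stage-and-patient-tagged error.
- The stage field of a mask enforces the conditioning order at the type
  level; composing steps out of order raises.
- Wilcoxon comparison of identical AUC vectors returns p = 1 (all-zero
  differences).
- Subtype strata with fewer than 8 events return an omission notice
  rather than unstable estimates.

## Known limitations

- The 17-feature list is fixed to the canonical shape family of that
  cardinality; an original appendix enumeration was not available, so
  the exact membership is an assumption (documented, config-stable).
- Tree-family (CART/GBM) importance is in-sample and coarse for
  near-separable tables; the forest's OOB measure is the one to trust.
- Among algebraically linked morphology-change variables (SA:V,
  sphericity, compactness, disproportion ratios all deterministic
  functions of the same V and A changes) importance necessarily spreads
  by the learner's internal preferences; rankings within that family
  are exchangeable and should be read as a family-level signal.
- Evaluation at desk scale uses the `fast` grids and cohorts of a few
  hundred phantoms; absolute AUCs on such cohorts reflect the
  generator's chosen effect sizes, not clinical effect sizes.
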