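# ftvmorph

Tumor morphology from DCE-MRI for early prediction of poor response to
neoadjuvant chemotherapy.

Women with locally advanced breast cancer receive chemotherapy before
surgery; at surgery the residual cancer burden (RCB) classifies the
response from RCB-0 (pathologic complete response) to RCB-III
(extensive residual disease, the worst outcome). The functional tumor
volume (FTV) — the volume of voxels whose contrast-enhancement
kinetics exceed thresholds inside a volume-of-interest box on dynamic
contrast-enhanced MRI — is a standard imaging biomarker of response,
summarized longitudinally as the ratio FTV_R = FTV(T1)/FTV(T0) between
a 3-week early-treatment exam and baseline. But FTV is a pure size
measure: a tumor that shrinks moderately while keeping its shape
(a poor-response pattern) and one that shrinks the same amount while
fragmenting and roughening (a good-response pattern) can have the same
FTV_R. `ftvmorph` quantifies that missing morphology channel: it
segments the FTV mask by percent-enhancement thresholding
(PE = 100·(S_early−S_pre)/S_pre > 70%), conditions the mask (1 mm
isotropic resampling, 5 mm morphological closing, anti-aliasing,
removal of components ≤ 100 voxels), extracts 17 3D shape features per
exam — surface area, mesh/voxel volume, surface-area-to-volume ratio
A/V, sphericity (36πV²)^⅓/A, compactness variants, maximum diameters,
PCA axis lengths, elongation, flatness — and forms the 17 T1/T0 shape
ratios, 51 shape variables in all. It then asks whether those
variables add predictive value for RCB-III over FTV_R and
clinicopathologic covariates, using nested resampling (inner
stratified 5-fold grid search, 20 outer stratified subsamples) of four
learners — elastic net, CART, random forest, gradient boosting — with
rank-based AUC, Wilcoxon signed-rank model comparison, and
out-of-bag permutation variable importance.

Real trial imaging cannot ship with a package, so a seeded phantom
generator (`ftvmorph.synthetic`) produces DCE exams of lobulated
star-convex tumors with controllable size, surface irregularity,
enhancement kinetics and noise, plus cohort-level covariate/outcome
margins and a class-linked treatment effect (responders shrink and
roughen; RCB-III tumors keep size and shape). Every downstream stage
is exercised on those phantoms exactly as it would be on clinical data.

## Worked example

The numbered drivers under `analysis/` run the study pipeline on a
simulated cohort and write their tables under `results/`. On a cohort
of 200 phantoms whose outcome is linked to shape change but not to
volume change (`python analysis/05_evaluate_models.py`):

```
without shape: elastic_net AUC 0.60 +/- 0.08
   with shape: random_forest AUC 0.98 +/- 0.03  (Wilcoxon p = 1.9e-06)
top-ranked variable: compactness2_ratio
```

The without-shape model (FTV_R + covariates) hovers near chance because
the volume channel carries no outcome signal by construction; adding
the 51 shape variables lifts the optimal model far above it, and the
importance ranking is headed by a T1/T0 shape-change ratio from the
sphericity/compactness family — the morphologic-change signal, with
2·2⁻²⁰ ≈ 1.9e-06 the smallest p-value 20 uniformly signed paired
differences can produce. The feature-level drivers print physical
sanity numbers along the way, e.g. `analysis/02_segment_ftv.py`
reports a median T0 Dice of 1.000 between segmented and generating
masks, and `analysis/04_assemble_table.py` prints the group contrast
`SA:V ratio, RCB-III 1.08 vs others 1.72 (rank-sum p = 2.8e-11)` —
poor responders keep their shape, so their surface-to-volume ratio
barely moves.

A single patient can be pushed through the stages from the shell:

```
ftvmorph simulate --n 5 --seed 1 --out cohort/
ftvmorph ftv --exam-dir cohort/P0000 --out out/      # FTV + ratio JSON
ftvmorph prep --mask out/ftv_mask_T0.nii.gz --out clean.nii.gz
ftvmorph shape --mask clean.nii.gz --out features.csv
ftvmorph pipeline --n 60 --seed 1 --out run/         # end to end
```

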