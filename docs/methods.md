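# Methods

This note documents the models, numerical conventions and design choices
behind `myelotype`, in the spirit of a methods appendix: what each
component assumes, which knobs matter, and what the synthetic layer does
and does not emulate.

## Segmentation

T1-hypointensity segmentation is a pure intensity rule referenced to
cortical grey matter: a voxel is lesional when its T1 intensity is
*strictly below* `mean(GM) − k·SD(GM)`.  Conventions that the published
description leaves open, pinned here for reproducibility:

* **GM statistics** are computed over the GM mask after binary erosion
  (default 1 voxel) to suppress partial-volume voxels at the CSF and WM
  boundaries; SD uses the population convention (divisor *n*), recorded on
  the returned stats object.  At realistic GM mask sizes the sample/
  population difference is negligible, but it must be fixed.
* **Search region** defaults to `T2 mask ∩ WM`: the classifier's second
  metric is the proportion of T2 lesion occupied by T1 lesion, which
  implies T1 lesions are scored inside T2 masks.  Scoring across all of WM
  is available via `search_region="whole_wm"`.
* **Boundary and connectivity**: strict `<` at the threshold;
  26-connectivity for components; components under `min_component_voxels`
  (default 3) are removed.  The threshold formula is scale-free: rescaling
  the volume by any positive constant and re-deriving GM stats yields an
  identical mask.

The T2 fallback segmentation (phantoms only; real pipelines supply their
own T2 masks) thresholds FLAIR above `median(WM) + z·1.4826·MAD(WM)`
(default z = 3).  A robust location/scale is used deliberately: with tens
of ml of hyperintense lesion inside the WM mask, mean/SD statistics are
contaminated enough to miss the lesions they are supposed to find, while
the median/MAD reference stays anchored to normal-appearing WM.

## ROC, Youden cutpoints and the k sweep

MCMS is the positive class and *lower* metric values indicate positivity
(the decision rule uses `<` cutoffs).  ROC curves enumerate every distinct
observed score plus sentinels; tied scores share one operating point.  AUC
is the trapezoidal area, identical (including tie handling) to the
Mann–Whitney concordance probability — the test suite checks this against
an exhaustive pair-counting oracle.  Youden's J = sens + spec − 1 is
maximized with ties broken toward higher specificity, then smaller cutoff.
AUC confidence intervals use a stratified percentile bootstrap (default
2000 replicates, seeded); the original analysis does not name its CI
method, so this is a package choice.

The k sweep re-measures every subject's T1 volume and T1/T2% at each k in
1.0…2.0 (step 0.1) and computes Youden cutpoints per metric per k.  How
the two metrics' performance should be combined into "the" optimal k is
not specified anywhere, and in the published sweep no single row dominates;
the default criterion is the mean of the two cutpoint accuracies, ties
broken by higher T1/T2% specificity and finally by taking the **median of
the still-tied k values** — the center of the optimal plateau, farthest
from both failure modes of the threshold.  The criterion is configurable
(`ratio_accuracy`, `t1vol_accuracy`).

## Classification and validation

All printed inequalities are strict; a subject at exactly 2.0 ml of T2
load is LOW_T2 (in vivo) or ineligible (postmortem), and both MCMS
criteria must hold jointly.  In-vivo mode reports low-T2 subjects as a
third class; postmortem mode excludes them (plus donors aged ≥ 65) before
validation metrics, matching how the two cohort types are handled.
Partition percentages are reported over the full cohort, rounded to the
nearest integer.  One reporting quirk: the reconstructed validation
confusion matrix (tp 6, fp 1, fn 1, tn 28) gives specificity 28/29 =
96.55%, which the source prints as 96.5 — a truncation rather than a
rounding; the tests accept the computed value to within half of the last
printed digit.

## Calibration

The FLASH→MPRAGE conversion is least squares through the origin
(`slope = Σxy/Σx²`), because the published equation has no intercept.
Whether the original fit minimized vertical residuals or used an
errors-in-variables regression is unstated; OLS through the origin is
assumed.  A free-intercept OLS is provided purely as a diagnostic and is
never used in the pipeline.

## Probability maps

Inputs are binary masks in one shared space; nonlinear registration to a
template is upstream infrastructure and out of scope, replaced by the
contract that all masks share one geometry.  The map is the per-voxel
subject fraction; smoothing is a separable Gaussian with sigma in mm
(divided per-axis by voxel size), reflective boundaries, output clipped to
[0, 1].  The blurring kernel width used originally is unstated; the
default here is 2 mm and configurable.

## Axon gradients

Analysis is 2-D (a stitched confocal-montage analogue).  Bins are
half-open `[lo, hi)` at 750 µm from the ventricular surface; axons beyond
the last bin go to a flagged overflow bin rather than being dropped, so
counts are conserved.  Density = count / analyzed area per bin (supplied
by the caller, since per-case analyzed areas are not fully specified).
The synthetic generator draws an inhomogeneous Poisson point pattern by
thinning, with linear density in distance and a caller-supplied diameter
mean function; per-axon diameter noise is Gaussian (SD 0.15 µm, floored at
0.05 µm).

## Cohort statistics

`compare_groups` reproduces the gated testing policy: Shapiro–Wilk per
group at α = 0.05 (the original normality assessment is unnamed; this is
the package's choice and the gate is fully overridable via
`TestPolicy(force=...)`), then a two-sided F-test on variances choosing
pooled vs Welch t, otherwise Mann–Whitney U with midrank tie correction.
All p-values are two-sided; no multiple-testing correction, matching
per-comparison reporting.  Chi-square is Pearson without continuity
correction.

## Synthetic phantoms

The phantom emulates exactly the features the pipeline consumes, nothing
more: four tissue classes (background, CSF/ventricle, cortical GM ribbon,
WM) on an ellipsoidal brain; ventricles as a fixed analytic template (two
mirrored curved tubes joined by an anterior bridge, widening posteriorly
as an occipital-horn analogue — no atlas download needed); a
periventricular lesion grown from a horn-tip seed by posterior-weighted
distance ordering, so it is a single confluent component contiguous with
the ventricular surface that expands posteriorly; optional focal WM
lesions placed ≥ 8 mm from the ventricles with a 2-voxel separation
buffer.  Realized T2 voxel counts hit the target volume exactly (rounded);
the T1 core is the ventricle-nearest fraction of the T2 mask, so the
realized core fraction is exact to rounding.

Intensities are arbitrary units — only GM-referenced contrasts matter.
Contrast offsets for lesion tissue are expressed in units of the
*effective* GM SD (tissue texture ⊕ additive noise, `√(gm_sd²+noise_sd²)`),
so a core at offset 1.7 sits exactly at the published threshold.  Noise is
additive Gaussian; Rician magnitude bias is ignored as irrelevant at the
simulated contrast separations.  Not emulated: cortical folding, bias
fields, multi-coil artifacts, longitudinal change.  Consequently, passing
phantom tests demonstrates correctness of the *computations* (thresholds,
volumetry, sweep logic) under controlled contrast, not robustness to real
acquisition artifacts.

Cohort tables match published per-group summaries: median/IQR summaries by
a log-normal (volumes are positive and right-skewed; the true family is
unreported, and the stand-in is flagged in the `CohortSpec.metadata` field), and
mean/SD summaries by a zero-truncated normal.  A two-parameter log-normal
matches the median and quartile *ratio* exactly; asymmetric quartiles are
individually matched only approximately.  To prevent impossible records
(T1 > T2), each group draws T2 volume plus either the T1/T2% ratio (T1
derived as the product) or the T1 volume (clipped to T2).

## Experiment design (study conditions)

Two frozen phantom-cohort conditions drive the end-to-end experiments,
each 20 phantoms per group with log-normal T2 volumes around 12 ml and
core fractions of 8–25% (TMS-like) vs 0–2% (MCMS-like):

* **classification**: cores at offset 2.5 effective SDs, faint rim (0.3),
  gm_sd 8 / noise_sd 6.  At the published cutoffs the phenotypes separate
  cleanly; the experiment checks the whole image→label chain.
* **kgrid**: cores at offset ~N(1.7, 0.05) — the generative optimum —
  rims at ~N(0.8, 0.25), gm_sd 9.8 / noise_sd 2.  Sharp voxel noise makes
  core capture collapse quickly once k exceeds the core contrast: the
  within-core capture probability falls below the 26-connectivity
  percolation threshold, the minimum-component filter erases the scattered
  remainder, and group separation dies.  Permissive k (< ~1.3) admit
  highly variable rim volume instead.  Accuracy therefore peaks around the
  generative contrast, and the sweep recovers k within ±0.2 of 1.7 across
  seeds.

Problem sizes throughout (default 72×88×72 grids at 1 mm, 20 phantoms per
group, 100 axon fields, 2000-subject cohort draws for distribution checks)
were chosen so the full suite and the acceptance script each complete in
well under a minute while keeping Monte-Carlo margins comfortable.

## Known limitations

* The phantom's two-class lesion interior (rim/core at fixed offsets)
  ignores partial-volume gradients at lesion borders; segmentation
  accuracy on real data will be worse than on phantoms.
* Synthetic development-cohort AUCs (n = 22) are noisy by construction and
  drawn from summary-matched marginals, not the real joint distribution;
  they are reported as descriptive outputs, not reproductions.
* The cohort generator draws group marginals independently per variable
  pair; real T2/T1 volumes are more strongly coupled, so derived-variable
  summaries (e.g. T1 medians when parameterized via the ratio) deviate
  from printed values by design.
* Interfaces are Python-first (library + examples); there is no CLI.
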