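# Methods

This note documents the models, numerical choices and known limitations of
`ioradiomics`. It is written for users who need to understand exactly what the
pipeline computes and what the synthetic validation does and does not show.

## Image preprocessing

CT volumes are resampled to isotropic 1 mm voxels (trilinear interpolation for
intensities, nearest-neighbour for masks; SimpleITK backend), then
intensity-standardized by a Z-score over the whole volume — the standardization
uses the full image rather than the ROI, so tumour features remain comparable
across subjects whose tumours differ in brightness. Resampling precedes
standardization; the order is exposed in the API (both operations are plain
functions).

Wavelet decomposition is single-level, separable 3D, Haar by default (the
family is an argument). Each of the 8 subbands (LLL … HHH; L/H per axis in
x, y, z order) is materialized as the inverse transform of that coefficient
band alone, so all nine images share the original grid and masks need no
resampling. Because the subbands are projections onto orthogonal subspaces,
they sum exactly to the input and satisfy Parseval energy conservation for
even axis lengths (symmetric boundary padding adds coefficients on odd axes).
The internal coefficient arrays have the usual half-band shape ceil(n/2).
Note a consequence of decimation: subband intensities are invariant under
even-voxel translations only; the extractor aligns its internal crop to even
indices so results are independent of where the tumour sits on the grid.

## Intratumoral features (593)

Per image set (original + 8 subbands): 14 histogram statistics, 22 GLCM, 11
GLRLM and 17 LBP features (64 × 9 = 576), plus 17 mask-only geometry features.
Intensities are quantized to a fixed bin count (64) over the ROI min–max
range — with standardized intensities a fixed bin *width* is ill-defined.
GLCM: distance 1, the 13 unique 3D directions, counts symmetrized and merged
across directions before normalization. GLRLM: run matrices per direction,
averaged. LBP: no canonical 3D formulation exists, so the code is the count of
the 26 neighbours exceeding the centre voxel (rotation-invariant by
construction), pooled onto 16 histogram bins; the 17th feature is the code
entropy. Degenerate conventions chosen to avoid NaN propagation: skewness and
excess kurtosis of a constant region are 0, GLCM correlation of a single-cell
matrix is 1.

Geometry: surface area comes from a marching-cubes mesh of the mask after a
0.8-voxel Gaussian pre-smoothing — on a binary mask the raw mesh overestimates
a digitized ball's area by ~8%, and the smoothing removes that bias (a
single-voxel mask falls back to the raw grid). The maximum 3D diameter is
measured between voxel *corners* (a single voxel has diameter equal to its
diagonal). Axis lengths are PCA axes of the voxel-centre cloud
(4·sqrt(eigenvalue)).

## Peritumoral-vasculature features (91)

Vessel segmentation: Frangi-type multi-scale Hessian vesselness (α = β = 0.5,
scales {1, 1.5, 2, 3, 4} mm, bright-tube convention). The structure-norm term
uses a single γ = half the maximal Hessian norm across **all** scales; with a
per-scale γ the responses are not comparable across scales and the per-voxel
argmax scale no longer tracks tube radius. Thresholding is Otsu's method on
the positive responses (256 bins), followed by binary opening (1 mm ball) and
removal of components under 27 voxels. Vessel voxels are restricted to
(lung mask ∩ peritumoral cube) minus the tumour; the cube extends the tumour
bounding box by 25 mm per side per axis, clipped to the grid. Vesselness is
computed on the full volume and cropped afterwards.

Centerlines: distance-ordered medial-axis thinning (skimage `skeletonize`);
the skeleton graph is partitioned into branches at junction voxels (≥ 3
skeleton neighbours); the radius estimate at each point is the Euclidean
distance to the vessel surface. A pathological corner case — a perfectly
even-symmetric digital tube has no uniquely medial voxel and thinning can
annihilate it — is handled by a one-voxel symmetry-breaking erosion retry.

Branch geometry: the voxel polyline is smoothed with a parametric cubic
spline (smoothing scale 1 mm), resampled at 2 mm arc steps, and differenced
with discrete Frenet frames: curvature = turning angle per arc length,
torsion = signed dihedral angle between consecutive osculating planes per arc
length. Two numerical decisions matter here. First, analytic spline torsion
(third derivatives) is hopeless on digital skeletons — the staircase noise of
a *straight* tube produced |τ| ≈ 0.24 /mm, swamping any signal; the coarse
discrete estimator recovers an analytic helix (a = 5, b = 2 mm) to ~3%.
Second, torsion is undefined where a curve is straight, so it is set to 0
wherever local curvature falls below 0.04 /mm (the binormal there is pure
noise). Length and straightness (chord/arc ∈ (0,1]) are measured on the
smoothed curve for the same reason.

The 91 features are: {mean, SD, skewness, kurtosis, median} over branches of
12 per-branch quantities (mean/max curvature, mean/max |torsion|, length,
mean radius, straightness, within-branch skewness of curvature and of
torsion, inflection count, total-curvature and total-|torsion| integrals)
= 60, plus total vessel volume = 61 morphology; 5 count/density scalars
(branch count, junction count, branch and junction density per cm³, tip
count) plus the same 5 aggregators over 5 per-branch spatial quantities
(nearest-branch centerline distance, orientation angle to the tumour-centre
ray, within-branch orientation dispersion, distance to the tumour surface,
local branch spacing) = 30 organization. An empty tree yields all-zero
features plus an explicit `empty_tree` flag column (not one of the 91).

Outlier filter: per feature, mean and SD are estimated on the *reference*
rows (the training split) and the fraction of all rows beyond 3 SDs is
counted over the whole dataset; features strictly exceeding 20% are removed.
The reference/count split is forced by arithmetic: more than 20% of a sample
beyond 3 SDs of its own mean/SD is impossible (Chebyshev gives ≈ 11%), so the
rule is only meaningful with reference statistics from a subset.

## Feature selection and the survival network

Cohorts are split 55/15/30% (train/validation/test) by simple random sampling
with largest-remainder rounding (206 subjects → 113/31/62). Screening:
univariate Cox (Newton iterations on the Breslow partial likelihood,
|Δβ| < 1e-8, steps clipped at 5; monotone likelihood flagged with an
infinite-HR sentinel) for continuous features; Pearson chi-squared without
continuity correction against the progression-event indicator for categorical
features; the gate is p < 0.05 with **no** multiplicity adjustment — noise
features pass at roughly the nominal rate by design. SFS greedily adds the
candidate maximizing the validation concordance of a linear Cox model fitted
on the training split (scikit-survival, Breslow ties, ridge 1e-6 so exact
duplicates remain fittable and show zero gain); ties break by lower screening
p-value, then candidate order; stopping is the first non-improving step
(patience 1), capped at 15 features. The linear inner model keeps selection
tractable and consistent with the Breslow loss used downstream.

The survival network is a numpy MLP (default 2 × 32 SELU units, dropout 0.2,
weight penalty 1e-4) trained full-batch with Adam (lr 1e-2, ≤ 500 epochs) on
the event-averaged negative Breslow partial log-likelihood, with early
stopping on validation concordance (patience 20) and best-weight restoration.
At cohort scale (hundreds of subjects, ≤ 15 features) full-batch gradients
are exact, training takes well under a second, and runs are bit-reproducible
from the seed. Features are standardized with training-split statistics only.
Grid search evaluates every configuration; exact validation-C ties break by
shortest recorded training time, then grid order. A configuration with no
hidden layers and identity activation reduces to linear Cox (rank correlation
1.0 with the scikit-survival fit in the validation suite).

Risk stratification: low risk iff predicted S(3.3 months) > 0.5 (the
boundary goes to high risk); 3.3 months is the generator's baseline median
PFS, matching the advanced-lung-cancer setting the cohort emulates.

## Evaluation

Concordance follows the pairwise definition: a pair is evaluable iff the
shorter observed time carries an event and the times differ; concordant iff
that subject has the higher predicted risk; tied risks credit 0.5. Note this
differs from some library conventions for tied *times* (scikit-survival also
counts certain tied-time pairs); the implementation is checked against
exhaustive enumeration, and against scikit-survival on tie-free data.
Time-dependent ROC is cumulative-cases/dynamic-controls with IPCW weights
from the Kaplan-Meier estimate of the censoring distribution (an unweighted
variant is a switch); operating points are reported at the Youden-optimal
threshold; CIs are bootstrap percentiles. Model comparison bootstraps
subjects 100 times and applies a paired t-test to the per-replicate AUCs;
degenerate replicates (no cases or controls at a horizon) are redrawn and
counted. Kaplan-Meier and log-rank go through lifelines. Shapley attributions
use Monte-Carlo permutation sampling against the training-mean background;
the efficiency identity (attributions + background = score) holds to
Monte-Carlo tolerance and is tested.

## Synthetic cohort

Phantoms: lungs are a low-intensity (−1) ellipsoid in a zero background; the
tumour is a bright (+1) sphere with additive band-limited Gaussian texture
scaled by the `heterogeneity` parameter; vessels are bright (+1) tubes of
configurable radius rasterized around analytic centerlines; white noise of SD
`noise_sd` is added globally. Branches radiate outward from just off the
tumour surface as circular helices. The `tortuosity` parameter is a **turn
rate** (1/mm): helix radius = pitch = 1/t, so true curvature = torsion = t/2
and both grow monotonically with the parameter — an amplitude parametrization
with fixed pitch would make true torsion non-monotone (τ = b/(a²+b²) peaks at
a = b), which would make "more tortuous" ambiguous. Default 0.2 /mm, i.e.
κ = τ = 0.1 /mm, a realistic bend scale for pulmonary vessels at CT
resolution; the cohort sweeps 0–0.35.

Clinical table: categorical variables (sex, smoking, stage, histology, total
protein, mean corpuscular volume) are drawn independently from configurable
marginals whose defaults match an advanced-lung-cancer immunotherapy cohort
(e.g. 56.8% smokers, 58.7% stage IVB, 98.1% high total protein); age is
normal with median 62.2 and IQR 12.8 years. Marginals must sum to 1 (± 1e-9).

Survival: event times are Weibull proportional hazards,
S(t|x) = exp(−(t/λ)^k e^{lp}), defaults k = 1.2, λ = 4.48 months so the
baseline median PFS is 3.3 months. Censoring is an independent uniform window
[0, c_max] with c_max calibrated by bisection so the expected event fraction
equals 1 − censoring_rate (default 0.25). The true log-hazard is a linear
combination of standardized phantom parameters — tumour radius (β = 0.7),
heterogeneity (0.5), vessel tortuosity (0.7) — and two lab indicators
(total-protein normal, MCV high; 0.7 each), i.e. hazard ratios ≈ 2 per SD
for the imaging drivers, chosen once as a clearly detectable but not extreme
prognostic signal at cohort sizes of ~200. Ten pure-noise features are
appended so screening has something to reject. Every generator is a pure
function of its spec including the seed.

## What the synthetic validation shows — and does not

The tabular cohort validates the statistical pipeline (split → screen → SFS →
network → stratification → log-rank) at n = 200 over 20 seeds in seconds; the
image pipeline (phantom → 593 + 91 features → model) is validated end-to-end
at small n and per-stage against analytic ground truth (helix Frenet
closed forms, mask Dice, brute-force texture-matrix enumeration). Problem
sizes used by the test suite and acceptance script: 64³–96³ phantom grids,
cohorts of 120–206, 20 stratification seeds, 1000 null replicates — sizes at
which every check runs on one CPU in about a minute.

Phantoms do not emulate CT physics (beam hardening, dose modulation, scanner
variability), respiratory motion, lesion-shape irregularity, or correlated
clinical covariates; the clinical variables are sampled independently, which
real cohorts are not. Passing tests therefore demonstrate the *correctness*
of the computational pipeline and its ability to recover known effects — not
clinical performance on real patients. The pre-trained deep-learning lung
segmenter used in clinical practice is out of scope; a threshold-based
fallback handles phantoms, and user-supplied lung masks short-circuit it.
Mortality as a competing risk for PFS is not modelled.
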