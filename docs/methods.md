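# Methods

This note documents the models implemented in `painfusion`, the parameters
that matter, the synthetic study the package is validated on, and the
numerical and design choices made where the procedure left room.

## The prediction problem

Each subject has a laser pain threshold *y* (Joules) measured behaviourally,
and four blocks of imaging features: voxel-wise regional homogeneity (ReHo)
and ROI-pair functional connectivity (FC) from resting-state fMRI, and
voxel-wise fractional anisotropy (FA) and ROI-pair structural connectivity
(SC) from diffusion MRI. The pipeline estimates *y* out of sample with
leave-one-individual-out cross-validation (LOOCV): for each fold, one
subject is held out; features of one type are screened on the remaining
n−1 subjects by the two-sided p-value of their Pearson correlation with
the training thresholds (exact t transform, n−2 df); surviving columns are
z-scored with training statistics; a regressor is fitted and the held-out
subject predicted. Nothing computed from the held-out subject enters the
fold (the test suite asserts bit-identical predictions under held-out label
perturbation).

Multi-type models are decision-level fusions: the fused prediction is the
unweighted arithmetic mean of the constituent single-type predictions, so
fusion never interferes with each constituent's feature screening or fit.
The nine standard configurations are the four single-type models, the
regional (ReHo+FA), connectivity (FC+SC), fMRI (ReHo+FC) and DTI (FA+SC)
pairs, and the four-type fused model. Default per-type settings: ReHo —
linear SVR at p < 0.001; FA — RBF SVR at p < 0.01; FC — linear SVR at
p < 0.001; SC — RBF SVR at p < 0.001. SVR uses C = 1, ε = 0.1 (RBF γ =
1/(d·var)); PLSR uses min(5, rank) components; random forests 500 trees.
These hyperparameters are conventional defaults, exposed in the estimator
constructors. A screening grid over {0.05, 0.01, 0.001} × four back-ends is
available (`run_model_grid`) but is optimistically biased when the same
LOOCV predictions are reused for reporting, so the default suite pins the
per-type settings instead.

## Feature extraction

**Temporal fMRI chain** (order fixed: discard → regress → bandpass → ReHo →
smooth → equalize). The first 10 volumes are discarded. Nuisance regression
uses the Friston-24 expansion of the six rigid-body motion parameters
(parameters, one-frame lags, both squared) plus one spike regressor per
scrubbed frame; scrubbing marks frames whose Power framewise displacement
(Σ|Δtranslation| + 50 mm · Σ|Δrotation|) exceeds 0.2 mm strictly. Spike
regression rather than frame deletion preserves the sampling grid for the
ideal-mask frequency-domain bandpass (0.01–0.1 Hz, DC removed).

**ReHo.** Kendall's coefficient of concordance W of each voxel's series with
its 3×3×3 neighbourhood (27, 19 and 7-voxel variants), computed from time
ranks: W = 12 S / (K²(n³−n)) with S the variance of rank sums over time.
Ties get average ranks; the tie-correction term is off by default (matching
common ReHo implementations) and available by flag. Neighbourhoods truncate
at the mask; voxels with fewer than 4 contributing series are set to 0. The
map is then smoothed (Gaussian, 6 mm FWHM, mask-renormalised) and equalized
by division by the in-mask mean (z-standardisation available as an
alternative). The implementation is vectorised (spatial correlation of rank
volumes) and is tested to 1e−12 against a brute-force rank-sum oracle.

**FC.** ROI time courses are unweighted means of in-mask voxel series;
pairwise Pearson correlations are Fisher z-transformed with r clipped to
±(1 − 1e−7) so collinear courses stay finite; the diagonal is stored as 0
and the strict lower triangle (R(R−1)/2 features; 4005 at R = 90) enters
prediction.

**FA.** FA = √½ · √(((λ₁−λ₂)² + (λ₂−λ₃)² + (λ₃−λ₁)²)/(λ₁²+λ₂²+λ₃²)) from
the eigenvalues of each voxel's tensor; scale-invariant, 0 for isotropic
diffusion, 1 in the single-axis limit. Tensors failing positive
semi-definiteness beyond 1e−8 (relative) are rejected with the voxel named.

**SC.** Probabilistic tractography on the single-tensor field: each fiber
starts at a seed-voxel centre and is tracked in both directions; at each
step of half the smallest voxel size the direction is drawn from a von
Mises–Fisher perturbation of the local principal tensor axis (concentration
κ, ∞ = deterministic), sign-aligned with the previous step; propagation
stops at mask exit, FA < 0.15, a turn beyond 45°, or 500 steps. The
connectivity probability from ROI i to j is the number of fibers seeded in
i that pass through j divided by the total fibers seeded in i
(samples-per-voxel × voxel count). Counting is once-per-ROI by default;
first-hit-only counting (which bounds row sums by 1) is a flag. The matrix
is asymmetric in general; the symmetrized average (A+Aᵀ)/2 is vectorized
like FC so both connectivity blocks share a 4005-feature layout. The
orientation-distribution tractography of full diffusion models is out of
scope — the propagator works on single-tensor fields — but the probability
definition above is preserved exactly, and estimates are binomial
proportions, so test properties are phrased in binomial standard errors and
hold at any sample count (defaults 5000/voxel; desk-scale runs use 10–50).

## Evaluation

The primary metric is the Pearson correlation (PCC) between predicted and
measured thresholds across subjects; MAE = (1/N) Σ|ŷₙ−yₙ| is reported as
mean ± sample sd of the per-subject absolute errors. Absolute errors of two
models are compared with a paired t-test (degenerate zero-variance
differences return p = 1 with a warning). Because all models' PCCs share
the measured thresholds, PCC differences use the Meng–Rosenthal–Rubin
z-test for dependent correlations sharing one variable:
z = (z_A − z_B)·√((n−3)/(2(1−r_AB)h)), h = (1 − f·r̄²)/(1 − r̄²),
f = min(1, (1−r_AB)/(2(1−r̄²))), with z_A, z_B Fisher transforms and
r̄² the mean squared correlation with y. Identical prediction vectors
short-circuit to (z, p) = (0, 1); correlations at ±1 are rejected as
degenerate. Monte-Carlo calibration at n = 210 keeps the type-I rate at
α = 0.05 within [0.035, 0.065].

*Numerical behaviour of the comparison test.* A per-subject A/B
sign-exchange permutation test is the natural nonparametric analogue. Its
null distribution conditions on the observed data while the z-test is
asymptotic and unconditional, so their p-values differ per dataset by
O(n^(−1/2)): about 0.03–0.08 at n = 100, shrinking to permutation
resolution by n ≈ 2000 (both behaviours are asserted in the test suite).
Per-dataset agreement much tighter than that at small n is not achievable
for any asymptotic test and should not be expected of this one.

## Stability of selection

For each single-type model the per-fold selected column sets are logged and
each feature's selection frequency is its fold-count ratio. "Common
predictive features" are those selected in strictly more than half of the
folds; retained regional features are mapped to their parcellation region
and connectivity features to order-normalised ROI-pair names, with
per-region counts. For fused models stability is reported per constituent
(selection only ever happens inside single-type models).

## The synthetic study

No public dataset accompanies this design, so the generator is a
first-class, tested module whose defaults define the study conditions.

**Thresholds.** Latent threshold = 2.445 J + planted linear signal +
residual noise, observed through an ascending staircase that starts at 1 J
and rises in 0.25 J steps: each of two simulated measurements is the latent
value plus N(0, 0.1²) measurement noise snapped *up* to the next grid level
(ascending method of limits; the reported threshold is the mean of the two
and hence lies on the 0.125 J grid). Snapping up adds ≈ half a step of
positive bias, so the latent mean sits 0.125 J below the 2.57 J population
target; with latent sd 0.52 J the reported distribution lands at
≈ 2.57 ± 0.53 J (verified at n = 1000). The test–retest sd of the two
measurements is not identifiable from published summaries; 0.1 J is a
conventional choice and a config parameter.

**Feature tables.** Four blocks (two regional of 500 columns, two
connectivity of 4005 — the lower triangle of a 90-ROI matrix — at 210
subjects by default). Block b carries a standard-normal signal component
s_b = √ρ·z₀ + √(1−ρ)·z_b: the redundancy knob ρ ∈ [0,1] moves the blocks
from fully complementary (ρ = 0, independent components) to fully redundant
(ρ = 1, one shared component). Ten planted columns per block equal
s_b + N(0, 0.25²); the latent threshold weights the four s_b equally, with
the weight set so the planted signal explains the full latent variance at
any ρ — i.e. each block's effect explains 25% of the variance in the
complementary case, making per-block recovery well-posed. Non-planted
columns are not white noise: they share 12 latent factors carrying 90% of
each column's variance. This mirrors real feature blocks — smoothed
regional maps are spatially autocorrelated and ROI-pair matrices are
low-rank functions of R time courses — and it matters statistically:
fold-wise correlation screening is *anti-selective* on near-threshold null
columns (a column enters exactly in the folds whose held-out subject
weakens its correlation, so its out-of-fold contribution anti-correlates
with y). With thousands of independent null columns this artifact can
erase a genuine 25%-of-variance signal; with realistically correlated
backgrounds the effective number of independent borderline nulls is small
and recovery is stable. The same mechanism makes the out-of-fold PCC of a
pure-noise table *negatively* biased — the test suite asserts absence of
positive skill, not symmetry around zero.

**Images.** Parcellations are grown from random seeds by multi-source
breadth-first search, so every ROI is one face-connected component. BOLD
voxels mix an ROI-level latent series (covariance across ROIs is the
configurable `roi_cov`) with iid noise via a per-ROI `local_coherence`
weight — the two knobs that ReHo and FC respectively measure. Motion is a
smoothed Gaussian walk rescaled so a configurable fraction of frames
crosses the 0.2 mm scrubbing threshold. Tensor fields solve the axially
symmetric eigenvalue problem in closed form — λ₁ = T/3(1+2δ),
λ₂ = λ₃ = T/3(1−δ), δ = FA/√(3−2FA²) — so emitted tensors reproduce the
requested FA to 1e−10 at the requested trace (FA = 1 exactly is rejected);
straight corridors between ROI centroids get elevated FA and a principal
axis along the corridor, giving tractography a geometric ground truth (the
corridor seed fraction lower-bounds the connectivity probability in the
deterministic limit).

**What the generator does not emulate.** No hemodynamics, k-space physics,
spatial registration error, crossing fibers, or physiological noise
structure; anatomical feature lists (which regions host stable features)
are grid-dependent and carry no anatomical meaning. Passing tests therefore
validate the statistical machinery — leakage-free selection, fusion
identities, calibrated tests, recoverability under known signal — not
claims about real cohorts, whose effect sizes this package does not attempt
to reproduce.

## Problem sizes used in the shipped checks

The calibrated synthetic study runs at 210 subjects with 500/4005-column
blocks over 20 fixed seeds; the dependent-correlation calibration uses
2000 null replicates at n = 210; the tractography phantom uses 50
samples/voxel on a 12×5×5 two-ROI grid; the end-to-end demonstration
(`configs/tiny.json`) uses an 8×8×8 grid, 6 ROIs, 40 subjects, 90
timepoints and 10 samples/voxel with a suite-wide screening threshold of
p < 0.05 — at 40 subjects the stringent per-type defaults would select
nothing. These sizes were chosen as the smallest at which each property is
statistically meaningful.

## Known limitations

- The tractography propagator is a single-tensor sampler; fanning and
  crossing geometries are outside its model class.
- The LOOCV + fold-wise screening procedure is faithful to common practice
  but statistically fragile: its out-of-fold correlation is negatively
  biased under the null and noisy near screening thresholds. The package
  measures and documents this rather than correcting it.
- `selection_p` interacts strongly with cohort size; the per-type defaults
  assume n in the hundreds.
- NIfTI affines are honoured only for voxel size; inputs are assumed
  co-registered and no reorientation is attempted.
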