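# Methods

This note records the models, conventions and design choices behind
`connvar`, in the order the pipeline runs them, together with what the
synthetic-data generators do and do not emulate.

## Synthetic study design

The generators in `connvar.synthdata` define the study conditions every
downstream stage is tested against. Defaults are desk-scale: 100 parcels in
7 networks, a 60 + 240 two-group cohort (preserving a roughly 1:4
imbalance between a smaller group A and a larger comparison group), and
2 runs × 300 frames per subject. All generators are pure functions of
(config, seed): repeated calls are bit-identical. Seeds fan out to
independent sub-streams via `numpy.random.default_rng([seed, stream])`.

**Geometry.** Parcel centroids are Fibonacci lattices folded onto each
hemisphere of the unit sphere (x < 0 left, x > 0 right), giving the
near-uniform coverage the spin null relies on. The synthetic
sensorimotor–association axis is the polar angle from (0, 0, 1),
rank-normalized to span [0, 1] exactly; networks are contiguous quantile
bins of that rank, which makes network identity smooth along the axis — a
deliberate simplification of real network topology.

**Cohort.** Group membership is thresholded from a latent standard normal;
each lifestyle score is a Gaussian-copula mixture ρz + √(1−ρ²)ε with ρ
solved analytically so the point-biserial correlation with the binary group
label hits its target exactly in expectation (defaults: education −0.15,
income −0.23, substance use −0.08, sleep +0.11, physical activity −0.18,
social −0.08). Families of size 1–3 are nested within group so the
family-aware split constraint actually binds. Ages are uniform on 22–37;
mean framewise RMS is |N(0.08, 0.02)| mm.

**Time series.** Each subject's latent covariance is a shared rank-5 factor
model L Lᵀ + I plus, for group-A subjects, an axis-aligned rank-1 component
s·vvᵀ with v = axis_rank − 0.25 and s the effect strength (default 0.6).
Adding the component only to one group keeps every covariance positive
definite without eigenvalue surgery; the asymmetric offset in v keeps the
two poles of the axis sign-opposed in the edgewise effect while leaving the
regional (row-mean) effect map well-conditioned. Subject identity enters as
Gaussian jitter of the factor loadings (sd 0.08). Frames are i.i.d. draws
from the subject's correlation matrix; RMS traces hover near the subject's
mean motion with spikes above 0.2 mm at rate 0.03/frame.

**Planted ground truth.** `planted_connectivity_effect` returns the
population-level group difference of exactly the quantity the preprocessing
stage estimates: the Fisher-z correlation matrix of the global-signal-
regressed process. The global-signal projection is applied analytically
(for i.i.d. frames the regression of x on the global mean g and its
backward-difference derivative has a closed-form residual covariance), and
the expected diagonal inflation from the loading jitter (k·sd² I) is
included. Defining the oracle this way keeps recovery tests honest: they
compare the estimator against the true value of the estimand, not against a
convenient intermediate.

**Morphometry, mediation, expression.** Morphometric features are smooth
spatial base profiles plus a group shift proportional to the regional
planted map (so structural and functional group effects are co-localized by
construction) plus subject noise. The mediation dataset plants
mediator = a·group + covariates + ε and brain = c′·group + b·mediator +
covariates + ε; the indirect effect is exactly a·b (default 0.5 × 0.4 =
0.20) and is invariant to the z-normalization the fitting stage applies to
the mediator. Gene expression fields are Gaussian-process samples on the
sphere (squared-exponential kernel in chordal distance, scale 0.5); 10% of
genes additionally load (±1 sign, strength 1) on the z-scored effect map.
Pseudo-donors observe the shared field plus donor-specific smooth noise;
the acceptance study uses 3 donors with donor noise at twice the shared
amplitude so the differential-stability filter has something to do.

**What the generators do not emulate.** No hemodynamics, autocorrelated
noise, scanner drift, surface geometry, vertex-level data, or realistic
morphometric covariance; families share a fold label but not correlated
brains. Passing recovery tests therefore demonstrates the *estimators*
are correct and calibrated under the stated model, not that real effect
sizes resemble the planted ones — real-data effect magnitudes were never a
calibration target.

## Preprocessing conventions

- Censoring: spike = RMS > 0.2 mm; the 1 preceding and 2 following frames
  are censored with it ("immediately preceding" read as exactly one frame);
  any uncensored segment shorter than 5 frames is then censored; a run is
  invalid when more than half its frames are censored. The rule is
  idempotent on the surviving frames.
- Global-signal regression: regressors are the across-parcel mean, its
  backward difference (first element 0), and an intercept, fitted on
  uncensored frames only; censored frames pass through untouched and are
  excluded from all later estimation.
- Fisher z: |r| clipped at 1 − 10⁻⁷ before artanh (the transform diverges
  at ±1); the diagonal is excluded from vectorization and set to 0.
- Principal gradient: PCA of the column-centered connectivity matrix with
  rows as observations; variance explained = first eigenvalue / trace of
  the centered covariance. PCA leaves the sign arbitrary, so loadings are
  aligned to a reference map (first subject, or caller-supplied) by
  non-negative correlation. The sparsified variant keeps the top fraction
  of entries per row and re-symmetrizes by elementwise max.
- Label-map utilities: Dice is averaged over labels present in either map;
  fusion takes the per-vertex modal label with ties to the lowest label id;
  cross-group agreement is the per-vertex fraction of label-sharing pairs
  over all |A| × |B| pairs.

## Prediction

The kernel is the Pearson correlation between vectorized upper-triangle
connectomes — prediction is a regularized similarity-weighted average of
training targets, α = (K + λI)⁻¹y. The λ grid {0, 0.1, 1, 10, 100, 1000}
spans under- to over-regularized on the correlation-kernel scale; the inner
5-fold loop scores classification by accuracy and regression by Pearson r,
mirroring the outer metrics. After covariate deconfounding the training
kernel is structurally rank-deficient (residuals lie in the orthocomplement
of the covariate span), so λ = 0 is treated as infeasible when the solve
fails rather than as an error — the grid search simply skips it.

Classification encodes targets ±1 with decision threshold 0; an exact 0
falls back to the training majority class. Permutation p is the strict
proportion of null accuracies exceeding the true accuracy (it can be 0,
matching the proportion definition); a `conservative` flag applies
(k+1)/(n+1). Group-classification permutations swap labels within matched
pairs with probability ½, preserving the matched design under the null.

All target-independent computation (per-fold deconfounding and kernels,
inner-fold kernels) is cached in `CVEngine`, so a 1,000-permutation null
costs only small linear solves per permutation. A leakage audit test
poisons held-out rows and asserts the training-side artifacts are
unchanged.

The permutation-p calibration study uses a regression target: a
classification accuracy at small n is heavily tied, and under the strict
proportion definition ties alone push the null p off uniform, which would
test the tie structure rather than the machinery. Regression accuracy is
continuous, so exchangeability makes the null p exactly uniform on its
grid.

## Morphometry and regional models

MSN edges correlate 5-vectors (cortical thickness, gray matter volume,
surface area, Gaussian and mean curvature), z-normalized per feature across
regions *within subject* — with 5 points per correlation the edges are
intrinsically noisy, and |r| = 1 from collinear vectors is a legitimate
value, not an error; regional row-means restore stability. Regional models
are weighted least squares with subject weights 1/(group size), which
equalizes the groups' total leverage under imbalance; with equal group
sizes this reduces exactly to OLS. Binary covariates enter as 0/1;
continuous covariates are z-scored before forming any product term
(age × sex, education × income, group × factor). Partial R² for a term is
t²/(t² + df). The BH step-up is implemented per its defining formula and
cross-checked against statsmodels.

## Spatial inference

Rotations are Haar-uniform on SO(3) (scipy's `special_ortho_group`); the
left-hemisphere rotation's x-mirrored conjugate M R M applies to the right
hemisphere. Each parcel takes the value of the nearest rotated parcel
within its hemisphere; a source parcel may serve several targets
(duplication allowed — the standard spin-test dialect). Parcels flagged
missing drop out of each null correlation pairwise. p is the strict
proportion with |r_null| > |r_observed|, two-sided by construction.

## Mediation

The "structural equation model" for this three-variable structure with
shared covariates is saturated, so the two OLS equations give the same
estimates a general SEM optimizer would; the package fits OLS directly.
The mediator, RMS, ICV and lifestyle factors are z-normalized before
fitting to keep coefficients comparable across models; a·b is invariant to
the mediator's scaling, and the identity c = c′ + a·b holds to machine
precision on every dataset. Inference is a nonparametric subject-resampling
bootstrap: per-path p = 2Φ(−|estimate/SE|) with BH-FDR across the model's
paths, and a bias-corrected (BC, no acceleration term) percentile interval
for a·b — significance means the interval excludes zero. The brain
composite averages the z-scored gradient values of the top-15 regions most
correlated (|r|, ties to the lower parcel id) with the factor; because
selection reuses the factor, the composite–factor correlation is
optimistically biased — this mirrors the procedure it implements and is
documented rather than corrected. Region selection happens outside the
bootstrap loop (fixed region set) by default.

## Transcriptomics

Differential stability is the mean over donor pairs of the Spearman rank
correlation of a gene's regional profile; genes with DS > 0.1 are retained
(0 and 0.2 as sensitivity alternates). For a univariate response the first
PLS component has a closed form — gene weights ∝ Xᵀy for column-z-scored X
and z-scored y — which removes algorithmic ambiguity; sklearn's PLS is the
independent cross-check in the tests. Variance explained is the squared
correlation between the response and the PLS1 scores (an identity in the
univariate case, asserted at runtime precision). Scores correlate
non-negatively with the response by construction. Significance spins the
response map; per-gene error is a parcel-resampling bootstrap whose
components are sign-aligned to the full-sample solution before the SE is
taken — without that alignment the Z-scores would be meaningless under
component sign flips. Z > 5 / Z < −5 define the signed gene sets.

## Problem sizes and numerical choices

The acceptance script runs the headline study at the generator defaults
(300 subjects, 100 parcels) with 20 split replicates, a 199-permutation
prediction null, 1,000 spin rotations, and 1,000 bootstrap resamples;
calibration suites use 200 null datasets at 99 permutations and 100 null
mediation simulations at 200 bootstrap resamples. These sizes were chosen
once as a desk-scale design point — large enough that every recovery and
calibration check is well-powered, small enough to run interactively.

Degenerate inputs fail loudly and early: empty RMS traces, zero-variance
parcels (named in the error), constant maps, rank-deficient covariates,
collinear designs (aliased columns listed), single-donor DS, one-class
folds. Bootstrap resamples with a constant response are redrawn with
bounded retries. Ties are broken deterministically everywhere (lowest label
id in fusion, lower parcel id in composite selection, training majority at
a zero decision score).

## Known limitations

- The synthetic axis confounds network identity with hierarchy position;
  network-level Haufe blocks inherit that smoothness.
- Frames are temporally white; censoring-related estimator bias under
  autocorrelated noise is untested.
- The spin test's nearest-neighbor dialect duplicates source parcels;
  variogram-matched surrogate nulls are out of scope.
- Mediation assumes linear paths with homoscedastic errors; no latent
  variables or fit indices.
- MSN edges from 5 features are noisy by design; the package documents
  rather than alters that recipe.
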