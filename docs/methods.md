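# Methods

This note documents the statistical model behind `lamorph`, the design
choices that were genuinely open, the synthetic-data generator's
assumptions, and the numerical conventions. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Shape spaces and Procrustes alignment

A landmark configuration is a k × 3 matrix of endocardial point
coordinates in mm. Generalized Procrustes Analysis (GPA) superimposes a
sample by translation and rotation on its evolving mean; in **shape
space** (SS) configurations are additionally rescaled to unit centroid
size, in **size-and-shape space** (SSS) sizes are left untouched. The
pipeline deliberately works in SSS for atrial shapes: chamber size is a
biological attribute of atrial function, not a nuisance. A practical
consequence of the SSS construction is that aligned configurations live
in a (locally) Euclidean tangent region at the Grand Mean, so PCA can be
applied to the aligned coordinates directly, without the spherical
projection the SS requires.

Numerical conventions:

- Rotations come from the Kabsch SVD solution with the determinant
  correction, so reflections are always excluded (det = +1): anatomical
  landmark clouds must not mirror.
- GPA convergence: Frobenius change of the mean < 1e-10, at most 200
  iterations; non-convergence emits a warning and flags the result
  rather than failing silently. The objective (summed squared distance
  to the mean) is recorded per iteration; the tests assert it never
  increases.
- SS-mode scaling rescales each configuration to unit centroid size once,
  before the rotation iterations (the classic convention).
- PCA is computed by SVD of the centered data matrix, numerically stabler
  than forming the covariance. Component signs are fixed by making the
  largest-magnitude loading entry positive, so runs are bit-reproducible.
- `shape_pca(..., center_on=<vector>)` supports centering on an external
  reference instead of the sample mean; the deformation PCA uses this to
  decompose about the Grand Mean mannequin.

## Temporal homology

Subjects are acquired at different frame rates and cycle lengths, so
frames are not comparable across subjects. Three annotated
electromechanical events anchor each cycle — the ECG R peak (t_R), the
time of maximal LA volume (atrial end-diastole, t_ED), and the P peak
(t_P) — and three equally spaced times are inserted into each of the
three inter-event intervals. The closing R peak of the next cycle is
excluded, leaving exactly 12 homologous times with the strict events at
positions 1, 5, 9 (1-based). The grid is equivariant under affine changes
of the time axis.

Shapes at homologous times are reconstructed, not picked from nearest
frames: one pooled SSS GPA + PCA over all observed frames of all subjects
turns each cine into per-component score traces; the traces are
interpolated at the grid times (natural cubic splines by default,
piecewise-linear as an option) and mapped back through the loadings. With
all components retained the reconstruction is exact at observed times.
Interpolation never extrapolates; the generator provides two cycles so
the twelfth time always lies inside the observed span.

Two open choices were decided here. First, the alignment is a *single
pooled* GPA over every frame of every subject (a per-subject mode exists
for sensitivity analysis): inter-subject comparability of the score
traces requires a common frame, and the linear shift subsequently removes
the inter-individual offsets that pooling leaves in. Second, splines
rather than linear interpolation are the default because score traces of
a smoothly deforming chamber are smooth; the choice is a config switch
and the tests cover both.

## Linear-shift parallel transport

Pooled GPA + PCA on cyclic series mixes two variance sources: stable
inter-individual anatomy and within-cycle deformation. The linear shift
(LS) is the tangent-space form of parallel transport: with x̄ the
subject's mean over its 12 homologous shapes and GM the Grand Mean of all
subjects' homologous shapes, each shape is transported as

    x̃_t = GM + (x_t − x̄).

Every transported trajectory then has mean exactly GM, so between-subject
mean differences vanish identically and the PCA of transported shapes
about GM ("deformation PCA") captures pure deformation. Using GM as the
mannequin — rather than the end-systolic frame, the convention of
device-derived strain — makes both end-systole and end-diastole visible
as deformed states.

Choices: the subject reference is the mean of its 12 homologous shapes
(an alternative `first_frame` reference is provided); the shift is a
plain vector operation in the pooled SSS coordinates, with no per-subject
re-rotation; and GM is computed over the 12-time reconstructions, not
over raw frames, since the reconstructions are what the deformation
analysis consumes. The exact Riemannian parallel transport on Kendall
shape space is a non-goal: for near-identical alignment frames the
tangent-plane shift is an adequate and much simpler approximation.

## Trajectory analysis

The first q = 3 deformation PC scores at the 12 homologous times form a
12 × q configuration per subject — the trajectory treated as a shape. A
second-order GPA in SS aligns these configurations, but translation,
scale and rotation are estimated **from the three anchor landmarks only**
(1 = R peak, 5 = end-diastole, 9 = P peak); the nine interpolated times
are passively carried along. This keeps imperfectly estimated in-between
times from biasing the superimposition: the tests assert the fitted
transform is invariant to arbitrary perturbation of passive landmarks.
The anchor sub-configuration also defines the scale (its centroid size),
since all three similarity components are estimated from the anchors.
Three anchors in q = 3 determine the rotation only up to reflection about
their plane; reflections are excluded and ties resolved by the
least-squares fit over anchors.

Trajectory attributes:

- **shape**: PCA scores of the vectorized aligned trajectories;
- **size**: centroid size of the raw (pre-scaling) trajectory
  configuration;
- **orientation**: the two-argument-arctangent angles, in degrees on
  (−180°, 180°], of the landmark-1 → landmark-5 vector projected on the
  (PC1, PC2) and (PC1, PC3) planes.

q defaults to 3 and is configurable upward; the trajectory machinery is
dimension-agnostic (a 12 × 10 hyper-shape is tested). The trajectory
MANOVA uses the first 10 trajectory-shape PCs by default
(`n_pcs_traj_manova`); 5 is a defensible alternative and is exposed in
the run configuration rather than resolved here.

## Volumetrics

The ring/apex grid is closed into a surface by stitching adjacent rings
with triangles, capping the open base ring with a fan around its centroid
(a documented convention for the mitral plane), and closing the last ring
onto the apex. Volume is the divergence-theorem sum of signed origin
tetrahedra, orientation-corrected, in ml. On an analytically known solid
the discretization error at 36 × 36 resolution is below 1% and decreases
monotonically with resolution (tested).

Phasic indicators from the 12-point volume curve, with v_max read at the
end-diastolic grid position (the global maximum wins, with a warning, if
it exceeds that reading by ≥ 5%), v_min the curve minimum, v_preA the
volume at the P-peak position:

    ef_global    = 100 (v_max − v_min) / v_max
    ef_reservoir = 100 (v_max − v_min) / v_min     (expansion index)
    ef_conduit   = 100 (v_max − v_preA) / v_max
    ef_booster   = 100 (v_preA − v_min) / v_preA
    booster_abs  = v_preA − v_min

Denominator conventions vary across the clinical literature; the
reservoir denominator is switchable (`v_min` default, `v_max` optional)
and every formula is stated here so users can audit. A curve with v_preA
outside [v_min, v_max] is flagged, not fatal.

Surrogate "classic global parameters" — per-meridian longitudinal strain
and per-ring circumferential strain, both in % versus the minimum-volume
(end-systolic) frame, plus volume — provide the baseline against which
deformation-score classification is compared.

## Permutation inference

Group tests report R² = between-group SS / total SS; the multivariate
version uses the trace of the between-group cross-product over the trace
of the total cross-product on the Euclidean embedding (a Goodall-type
statistic — the geometric-morphometric convention, and well-behaved when
variables outnumber subjects). P-values are permutation estimates,
p = (1 + #{R²_perm ≥ R²_obs}) / (1 + n_perm), with n_perm = 999 by
default, so the smallest attainable p is 1/(n_perm + 1). All tests are
seeded and exactly reproducible; binary-group permutations are evaluated
by vectorized group-sum algebra, which is what makes univariate filtering
inside every cross-validation fold affordable. Tests are two-sided (on
R², which is direction-free); no multiplicity correction is applied to
per-PC, per-time scans by default, with Benjamini–Hochberg available.

Spearman correlations use midranks for ties and a seeded permutation
p-value (two-sided on |rho|). The within-subject correlation utility
centers each subject's series on its own mean before pooling, removing
between-subject level differences.

## Classification

Univariate association filtering (UAF) keeps features with two-group
permutation-ANOVA p below alpha (0.05 default); an RBF-kernel SVM with
C = 1 and the `scale` gamma heuristic (gamma = 1 / (n_features · feature
variance) — the kernel width the data's own scale implies) is fit on
standardized features. Reported per run: in-sample accuracy, sensitivity
and specificity (disease group positive), AUC from the decision function,
and the leave-one-subject-out cross-validation (LOOCV) error. In-sample
metrics and LOOCV are deliberately reported side by side and labeled:
only LOOCV estimates generalization. Standardization **and** UAF are
re-fit inside every LOOCV fold so the held-out subject never influences
selection (a `--uaf-once` style global filter is available via
`uaf_alpha=None` plus external selection, but refitting is the honest
default). An empty UAF selection falls back to the full feature set with
a warning. On balanced null data LOOCV error sits above 0.5 on average —
the familiar pessimistic bias of leave-one-out with adaptive pipelines —
which the tests acknowledge with an asymmetric acceptance band.

## The synthetic cohort generator

No per-frame LA landmark dataset is publicly available, so the generator
produces the study conditions the pipeline is designed for: 46 controls
vs 22 disease-like ("HCM") subjects by default, each a two-cycle cine of
1297-landmark clouds at 18–30 Hz with cycle lengths of 700–950 ms.

Per subject: a half-ellipsoid cup template (radius 20 mm, depth 26 mm,
base ring open at the mitral plane); a smooth random linear + quadratic
displacement field as static inter-individual anatomy (RMS 1.5 mm
default); a per-frame diagonal anisotropic scaling — long-axis exponent
0.4, the remainder circumferential — whose determinant tracks a phasic
volume program *exactly* (a linear map scales the mesh volume by its
determinant, so the generated volumes are analytically known); a
depth-graded twist about the long axis proportional to instantaneous
contraction (peak 10° controls, 4° cases); and i.i.d. Gaussian landmark
noise (0.3 mm) per frame.

The volume program encodes the three atrial phases with closed-form
segments: a sin² reservoir rise from v_R = v_min + 0.05 (v_max − v_min)
to v_max at t_ED; a conduit fall V = v_preA + (v_max − v_preA) h(s) with
h(s) = (1−s)^(2b+1)((2b+1)s + 1) — b is the **bend amplitude**, b = 0
gives a plateau-free quadratic fall and b = 1 an early drop with a flat
approach to the P peak (the healthy conduit-to-booster transition); and
a booster drop to v_min at the phase midpoint (exactly homologous grid
position 11) with recovery to v_R. Events sit at 45% (t_ED) and 82%
(t_P) of the cycle with ±2% jitter; v_max is log-normally scattered
(CV 12%) around 50 ml for controls and 2.2 × 50 ml for cases; global EF
targets are 55% (controls) vs 35% (cases) with booster EF 25% in both,
so the case conduit EF (≈13%) is depressed and the absolute booster
volume rises with dilation while the booster EF does not — the intended
disease signature. Group contrasts are therefore: ~2× dilation, reduced
global/reservoir/conduit EF, bend present only in controls, damped
twist.

What the generator does **not** emulate: tissue biomechanics (the
deformation field is low-order kinematics, not physics), speckle texture
or segmentation error structure (noise is i.i.d. Gaussian), regional wall
heterogeneity, arrhythmic cycle-to-cycle variability, and realistic
magnitudes of inter-subject anatomical variation (defaults are tuned only
to produce the qualitative group contrasts above). Passing tests
therefore demonstrate that the *pipeline* recovers known generative
structure — not that clinical effect sizes would match: the synthetic
group separation is far cleaner than clinical data would be, which is why
classification metrics saturate near 1.0 on default cohorts.

All generator output is a pure function of (spec, seed); the default seed
is 20161007. Two cycles are generated; analysis consumes the first, the
second guarantees interpolation support at the cycle boundary.

## Problem sizes

The unit and acceptance tests run the pipeline on spatially reduced grids
(8 × 8 rings ≈ 65 landmarks) and cohorts of 8–68 subjects with permutation
counts of 99–999 — sizes chosen so the full suite completes in well under
a minute while every structural property (alignment invariants, EF
recovery, calibration bands, bend localization) is independent of grid
resolution. `scripts/acceptance.py` runs the full default configuration
(46/22 subjects, 1297 landmarks, 999 permutations) end to end.

## Known limitations

- The linear shift assumes all subjects lie in a common, nearly flat
  region of SSS; grossly misaligned or wildly dissimilar shapes would
  violate the tangent-plane approximation silently.
- Event annotations are inputs; no ECG processing is provided.
- The mesh volume assumes a star-shaped-enough cavity; self-intersecting
  grids produce a best-effort signed volume with a warning.
- Trajectory orientation is undefined for subjects whose R-peak and
  end-diastolic deformation states coincide (degenerate, but possible on
  null cohorts with tiny deformation).
- Single-cycle processing: multi-cycle averaging is out of scope.
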