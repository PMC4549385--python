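# Methods

This note documents the models, algorithms and numerical choices behind
`gmvrec`, what the synthetic generators do and do not emulate, and the
limitations a user should keep in mind.

## Behavioural model and response-feature analysis

Motor performance on a timed dexterity task is expressed as a z-score
against healthy-control norms, sign-flipped so that negative values mean
impairment (`z = -(score - mu)/sigma`); performance within `0 +/- 2.5`
z-units counts as normal. Recovery over the ten visits (day 7 after
stroke plus nine monthly examinations, days 30-270) is summarized per
subject by the best of three nested trajectory models:

* linear `m = I + beta t` (no plateau within the observation window),
* exponential `m = I exp(-beta t)` (deficit decaying to zero),
* exponential with offset `m = I exp(-beta t) + c` (chronic deficit `c`).

`I` and `c` are in z-units, `beta` in 1/day, `t` in days since stroke.
The default subgroup parameterizations are the reference cohort's point
estimates: fast `I = -0.9, beta = 0.005`; slow `I = -5.9, beta = 0.023`;
impaired `I = -23.4, beta = 0.031, c = -5.5`.

**Fitting.** For fixed `beta` both exponential models are linear in the
remaining parameters, so `beta` is profiled: a closed-form least-squares
solve inside a bounded scalar minimization (`beta` in [0, 1]/day) started
from a 5-point log-spaced grid. This makes the fits deterministic and
immune to the usual nonlinear-fit initialization lottery. A constant
series is fitted exactly by the offset model (`I = 0`, `c` = the
constant, `beta` irrelevant) — a known degeneracy; the parsimony rule
below keeps such data from being over-labelled.

**Selection.** Models are compared by small-sample AIC,
`AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)`, with `k` counting mean
parameters plus one for the residual variance (so linear and pure
exponential have k = 3, the offset model k = 4). The minimum wins, but
any model within 2 AICc units of the minimum that is *simpler* replaces
it. Simplicity is ordered by `(k, model order linear < exp <
exp_offset)`: models inside the 2-unit band are statistically
equivalent (the standard reading of AIC differences), so the package
always returns the most parsimonious member of that band. The explicit
ordering also covers the equal-k case (linear vs pure exponential),
where "fewer parameters" alone cannot decide; treating linearity as the
simpler hypothesis is this package's convention. RSS is floored at
1e-30 so exact (noise-free) fits compare by complexity rather than by
`ln 0`.

**Classification.** Linear best fit → *fast* (a negative slope still
classifies as fast, by model class, but emits a warning); exponential →
asymptote 0 → *slow*; offset model → asymptote `c`, *poor* iff
`c <= -2.5`, else slow.

**Continuous score.** The subjects-x-visits z matrix is column-centred
and decomposed by SVD; the first right singular vector gives the visit
loadings, and subjects' projections on it are the recovery scores. The
sign is oriented so higher scores mean worse recovery (negative
correlation with final-visit z; ties broken toward a positive loading
sum). Scores are therefore defined up to that convention and invariant
to subject order.

**Task ranking.** Candidate tasks are ranked by the rank-sum of three
criteria: Friedman-test p across visits (the named longitudinal test is
this package's choice; the criterion is only "strongest longitudinal
effect"), mean within-subject variance, and the fraction of subjects
with `z <= -2.5` at the final visit; ties break by impaired fraction,
then task id. Missing interior visits (at most two) may be linearly
interpolated; subjects with more gaps, or gaps at the first/last visit,
are excluded.

## Tensor-based morphometry

The longitudinal signal is carried by the displacement field `u` with
`y(x) = x + u(x)` mapping the early image onto the late image.

* **Rigid stage** — 6 parameters (mm, radians about the volume centre)
  maximizing normalized mutual information `(H1 + H2)/H12` of a 64-bin
  joint histogram built with partial-volume interpolation; optimized
  with Powell's direction-set method (derivative-free), trilinear
  resampling. NMI of an image with itself is exactly 2.
* **Nonlinear stage** — minimizes
  `E(u) = sum r^2 / sigma_n^2 + lambda * sum ||Du||^2`, with
  `r = I_early(x+u) - I_late(x)` and `D` the forward-difference
  gradient (membrane energy). `sigma_n^2` is the noise variance of the
  residual image, estimated robustly by the median absolute deviation
  (deformation mismatch occupies a minority of voxels, so the median
  tracks the noise); weighting the data term this way makes `lambda`
  dimensionless, and a fixed discretization constant (calibrated once on
  phantoms with analytic truth fields) puts the default `lambda = 4` at
  the operating point where planted deformations are recovered while
  noise-driven spurious warps are suppressed. Optimization is
  a demons-style preconditioned proximal gradient: a voxel-wise
  Gauss-Newton step (force `-r grad I / (|grad I|^2 + alpha)`) followed
  by the exact membrane proximal map, solved per component in DCT space
  (Neumann boundaries), with a backtracking line search that guarantees
  the objective never increases across the 8 outer iterations of each
  pyramid level (asserted on every run). Two pyramid levels by default.
  Validation against planted radial-bump fields on default phantoms
  yields JD correlations of 0.95-0.98 in grey matter.
* **Jacobians** — `JD = det(I + du/dx)` with central differences on
  interior voxels, one-sided at boundaries, step = voxel size.
  Non-positive determinants (folding) are logged and clamped to 1e-6.
* **GMV change** — `(JD - 1) * GM` per voxel: dimensionless local GMV
  change relative to the early image (JD is defined on the early grid,
  so >1 means local expansion from 3 to 9 months; the sign convention is
  stated here because verbal descriptions of "per mm^3 at which time
  point" are easy to invert). Smoothing uses a separable Gaussian,
  `sigma = FWHM/(2 sqrt(2 ln 2))` per axis (12-mm default), reflective
  boundaries (sum-preserving to ~1e-6).
* **Lateralization** — left-lesion cases are reflected about the
  mid-sagittal voxel plane with the affine composed accordingly; group
  analyses re-express flipped volumes on the common grid.
* **Analysis mask** — averages of grey-matter maps and lesion masks are
  binarized at the threshold (100 quantile-spaced candidates) maximizing
  the Pearson correlation between the binary mask and the continuous
  average; the final mask is the GM mask minus the lesion mask.
* Spatial normalization of real brains to a standard template is out of
  scope: synthetic subjects share one grid by construction, and the
  manifest input path expects pre-aligned volumes.

## Voxel-wise inference

Per in-mask voxel an OLS model is fitted with mean-centred nuisance
covariates; the one-sample analysis tests the intercept, the regression
analysis the recovery-score column; `t = c'b / sqrt(s^2 c'(X'X)^-1 c)`.
TFCE integrates `e(h)^E h^H dh` over 100 midpoint height steps from 0 to
the map maximum (E = 0.5, H = 2, 26-connectivity — standard defaults,
all configurable), positive and negative excursions separately. FWE
p-values use the permutation distribution of the maximum in-mask TFCE
score: sign-flipping of reduced-model residuals for the one-sample
design (exact enumeration with a warning when the requested permutation
count exceeds the 2^n distinct sign patterns), Freedman-Lane permutation
of reduced-model residuals for regression; the add-one estimator
`p = (1 + #{null >= score})/(n_perm + 1)` bounds the smallest attainable
p at `1/(n_perm+1)`. Each tail is tested against its own max-null at
alpha = 0.05, mirroring separate expansion/contraction reporting. For
efficiency the permuted maps are enhanced in batches: maps are stacked
with a one-voxel zero gap and labelled once per height on a shared
height grid, which is exactly equivalent to per-map TFCE with a common
maximum height (verified in the test suite). Null calibration: on
pure-noise cohorts (200 replicates, 500 permutations) the familywise
rejection rate is consistent with the nominal 5%.

## ROI statistics

The maximum-probability map assigns each voxel to the area with the
highest atlas probability (ties to the lowest area index, logged;
voxels below probability 0.01 stay unassigned). Cluster-area overlap is
reported as a percentage of cluster voxels (areas above 10% are marked
as reportable; all areas plus the unassigned remainder are retained and
sum to 100%). The central-tendency ratio divides the mean area
probability inside the cluster by the mean over the area's support
(voxels with probability > 0); averaging over the whole grid instead is
selectable but off by default, because it makes the ratio scale with
brain size. ROI values are confound-adjusted by residualizing the
subject-by-voxel matrix on the mean-centred nuisance covariates (with
the intercept added back) and averaging within the complete MPM area —
not just the cluster overlap — to avoid circularity.

Subgroup comparisons use midrank Kruskal-Wallis and Mann-Whitney tests;
both group-specific U statistics are always reported (U_x + U_y = n1*n2)
because reporting conventions differ between sources. The group-x-site
analysis is a classical mixed two-way ANOVA — between factor recovery
group, within factor effect site — with the interaction tested against
the site-by-subject-within-group error, `F((g-1)(s-1), (N-g)(s-1))`;
`eta^2 = SS_int/SS_total` and `partial eta^2 = SS_int/(SS_int+SS_err)`
(with these conventions partial eta^2 >= eta^2; published values that
order them the other way use a different total). Values are first
transformed by shift-then-square-root, the shift being the magnitude of
the smallest negative value in the data at hand (data-derived rather
than a hard-coded historical constant); Levene and Kolmogorov-Smirnov
checks run before/after the transform and are reported. The
implementation is cross-checked against `pingouin.mixed_anova` in the
test suite.

## Quality control

The cohort SD map is the voxel-wise sample SD (ddof = 1) of the GMV
change maps, summarized as mean SD inside a 2-voxel perilesional ring
versus outside. The partial-volume check estimates a grey-matter
fraction by deterministic two-tissue linear unmixing of image intensity
between neighbouring tissue-class means (CSF-GM or GM-WM segment,
clamped to [0, 1]) — a deliberately simple, prior-free estimator that
exercises the ratio contract — and compares the count of fraction > 0.8
voxels within a cluster against the count from the reference hard
segmentation at the same threshold. Both `N_pve/N_hard` and
`|1 - ratio|` are reported, since the published "relative PVE error"
does not pin down one formula. Subjects beyond 3 cohort SDs (or with an
undefined ratio) are flagged as outliers.

## Synthetic data: what it does and does not emulate

Behavioural cohorts are the subgroup models evaluated at the visit
schedule plus i.i.d. Gaussian noise (default 0.3 z-units); other tasks
are attenuated copies of the index-task trajectory (severity factors
0.25-1.0), mimicking the empirical ordering in which precision-grip
tasks are most affected. Raw seconds are reconstructed through a toy
norm table (PSO mean 5.7 s; the control SDs are not published, so
sigma = 0.7 s and the other tasks' SDs are fixture parameters chosen as
roughly range/4). Demographics mirror the reference cohort's marginals
(age ~ N(64.7, 11.6), 24:4 m:f, 16:12 R:L, lognormal lesion volumes with
subgroup medians 5.9/3.6/42.8 cc).

Phantoms are concentric smooth tissue shells (WM core, GM shell, a deep
GM nucleus standing in for the thalamus, CSF rim, hard skull boundary at
1.28 brain radii) with a mild smooth texture for registration contrast;
the brain occupies ~34% of the grid radius so a 10% global scaling stays
in the field of view. The late volume is the early volume pulled back
through the truth field (trilinear) plus Gaussian noise (default 1% of
WM intensity). Deformations are identity, global affine scaling, or a
sum of Gaussian radial bumps `u = a exp(-||x-x0||^2/2s^2)(x-x0)` with
the Jacobian computed from the analytic gradient; amplitudes are bounded
(|a| < 0.5) to keep the map diffeomorphic. The toy atlas is a set of
Gaussian-profile probability volumes with distinct (optionally pinned)
peaks, scaled so per-voxel sums stay at or below 1.

Not emulated: real anatomy, MRI physics, Rician noise, bias fields,
motion, scanner drift, and real segmentation error. Passing tests
demonstrate the correctness of the numerics and the statistical
calibration of the inference chain under these idealized conditions —
not robustness to the artefacts of clinical MRI.

## Problem sizes and defaults

Defaults are chosen so the whole validation suite runs on one CPU in a
few minutes: phantoms 24^3 voxels (1 mm), two pyramid levels, demo
pipeline 12 subjects at 16^3 with 200 permutations and 50 TFCE steps,
type-I calibration 200 replicates x 500 permutations on 8^3 grids, and
parameter-recovery simulations with 100 trajectories per subgroup.
Production-scale settings (10,000 permutations, 100 TFCE steps, larger
grids) are plain configuration changes.

## Known limitations

* The nonlinear registration is an analogue of high-dimensional warping,
  not a re-implementation: amplitudes of recovered fields are shrunk by
  regularization (validation is correlation-based), and large
  deformations (> ~1 voxel per iteration) rely on the pyramid.
* The permutation floor `1/(n_perm+1)` limits attainable significance at
  small permutation counts.
* The PVE estimator is intentionally simple; it is a QC instrument, not
  a segmentation method.
* The demo pipeline's subgroup contrasts at n = 12 are illustrative; the
  statistical power claims are established by the module-level
  simulations at proper sample sizes.
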